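"""Figures: presence/absence heatmaps and UpSet-style intersection plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from wha.cohort import CohortMatrix, SubsetIntersection


def plot_presence_heatmap(cm: CohortMatrix, path: str | Path, title: str = "") -> None:
    """Blue (detected) / white (not detected) locus × sample heatmap."""
    mat = cm.matrix.astype(int)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(mat.columns) + 2), max(3, 0.3 * len(mat.index) + 1.5))
    )
    ax.imshow(mat.to_numpy(), cmap="Blues", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
    ax.set_title(title or cm.cell_type)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_intersection(inter: SubsetIntersection, path: str | Path) -> None:
    """UpSet-style bar chart of subset membership pattern sizes."""
    counts = inter.counts
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, 1.2 * len(counts) + 2), 4.5),
        sharex=True, height_ratios=[3, 1],
    )
    x = np.arange(len(counts))
    ax_bar.bar(x, counts["count"], color="0.3")
    for xi, c in zip(x, counts["count"]):
        ax_bar.text(xi, c, str(c), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("loci")
    for yi, label in enumerate(inter.labels):
        for xi, pattern in enumerate(counts["pattern"]):
            member = label in pattern.split("&")
            ax_dot.scatter(xi, yi, s=60, c="0.2" if member else "0.85", zorder=3)
    ax_dot.set_yticks(range(len(inter.labels)), inter.labels, fontsize=8)
    ax_dot.set_xticks(x, counts["pattern"], rotation=30, fontsize=7)
    ax_dot.set_ylim(-0.5, len(inter.labels) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
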