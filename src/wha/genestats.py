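"""Host-gene window/depth quantification and group comparison.

Reads are realigned to a host gene's reference sequence with the same
identity filter and window tiling used for HERV loci; per sample, the
usable-window count and the gene-wide mean per-base depth are recorded.
Groups (e.g. healthy PBMC controls vs patients, or lavage samples
stratified into HERV-positive/negative subsets) are compared per metric by
one-way ANOVA followed by Tukey's HSD test. Depths are raw (no library
size normalisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from wha.core import (
    DEFAULT_IDENTITY_THRESHOLD,
    DEFAULT_MIN_DEPTH,
    FilteredAlignment,
    Read,
    align_and_filter,
    compute_window_coverage,
)
from wha.loci import HervLocus

METRICS = ("usable_windows", "mean_depth")


@dataclass(frozen=True)
class GeneWindowStats:
    """Per-sample window/depth summary for one host gene."""

    gene_id: str
    sample_id: str
    group: str
    usable_windows: int
    mean_depth: float


def gene_window_profile(
    reads: Iterable[Read],
    gene: HervLocus,
    window_size: int,
    min_depth: float = DEFAULT_MIN_DEPTH,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    sample_id: str = "",
    group: str = "",
) -> GeneWindowStats:
    """Realign reads to a gene reference and summarise its window profile.

    Reuses the locus aligner, window tiling and coverage computation;
    ``mean_depth`` is total aligned bases over gene length (a per-sample
    scalar), ``usable_windows`` counts windows at or above ``min_depth``.
    """
    if gene.length < window_size:
        raise ValueError(
            f"gene {gene.locus_id} ({gene.length} bp) shorter than one "
            f"window ({window_size} bp)"
        )
    alignments = align_and_filter(reads, [gene], identity_threshold)
    return profile_from_alignments(alignments, gene, window_size, min_depth, sample_id, group)


def profile_from_alignments(
    alignments: list[FilteredAlignment],
    gene: HervLocus,
    window_size: int,
    min_depth: float = DEFAULT_MIN_DEPTH,
    sample_id: str = "",
    group: str = "",
) -> GeneWindowStats:
    """Window/depth summary from already identity-filtered alignments."""
    cov = compute_window_coverage(alignments, gene, window_size, sample_id=sample_id)
    total_bases = sum(
        min(a.end_offset, gene.length) - max(a.start_offset, 0) for a in alignments
    )
    return GeneWindowStats(
        gene_id=gene.locus_id,
        sample_id=sample_id,
        group=group,
        usable_windows=int(np.count_nonzero(cov.depths >= min_depth)),
        mean_depth=total_bases / gene.length,
    )


def stats_to_frame(stats_list: Iterable[GeneWindowStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "sample_id": s.sample_id,
                "group": s.group,
                "usable_windows": s.usable_windows,
                "mean_depth": s.mean_depth,
            }
            for s in stats_list
        ],
        columns=["gene_id", "sample_id", "group", "usable_windows", "mean_depth"],
    )


@dataclass
class GroupComparison:
    """One-way ANOVA plus Tukey-HSD pairwise comparisons for one metric.

    ``pairwise`` has one row per unordered group pair with the Tukey
    adjusted p-value, mean difference and a significance flag at
    ``alpha``. When every observation is identical the F statistic is
    undefined; the comparison is then reported as non-significant with a
    warning.
    """

    metric: str
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, significant
    alpha: float = 0.05

    @property
    def significant_pairs(self) -> set[frozenset[str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return {frozenset((r.group1, r.group2)) for r in sig.itertuples(index=False)}

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA on {self.metric}: F = {self.anova_F:.4g}, "
            f"p = {self.anova_p:.4g} (alpha = {self.alpha})",
            "Tukey HSD pairwise comparisons:",
        ]
        for r in self.pairwise.itertuples(index=False):
            star = "*" if r.significant else "ns"
            lines.append(
                f"  {r.group1} vs {r.group2}: diff = {r.mean_diff:+.4g}, "
                f"p_adj = {r.p_adj:.4g} [{star}]"
            )
        return "\n".join(lines)


def compare_groups(
    stats_df: pd.DataFrame, metric: str, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA followed by Tukey's HSD across sample groups.

    ``stats_df`` needs columns ``group`` and the chosen metric
    (``usable_windows`` or ``mean_depth``); every group must have at
    least two samples.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    groups = stats_df.groupby("group")[metric]
    if groups.ngroups < 2:
        raise ValueError("need at least two groups to compare")
    sizes = groups.size()
    if (sizes < 2).any():
        small = sorted(sizes.index[sizes < 2])
        raise ValueError(f"groups with fewer than two samples: {small}")
    arrays = [np.asarray(vals, dtype=float) for _g, vals in groups]
    labels = list(groups.groups)

    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        warnings.warn("all observations identical; F undefined, reporting non-significant")
        pairs = [
            {"group1": g1, "group2": g2, "mean_diff": 0.0, "p_adj": 1.0, "significant": False}
            for i, g1 in enumerate(labels) for g2 in labels[i + 1:]
        ]
        return GroupComparison(metric, float("nan"), 1.0, pd.DataFrame(pairs), alpha)

    f_stat, p_val = stats.f_oneway(*arrays)
    tukey = pairwise_tukeyhsd(
        endog=stats_df[metric].astype(float).to_numpy(),
        groups=stats_df["group"].to_numpy(),
        alpha=alpha,
    )
    tk = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    pairwise = pd.DataFrame(
        {
            "group1": tk["group1"],
            "group2": tk["group2"],
            "mean_diff": [float(m) for m in tukey.meandiffs],
            "p_adj": [float(p) for p in tukey.pvalues],
            "significant": list(tukey.reject),
        }
    )
    return GroupComparison(metric, float(f_stat), float(p_val), pairwise, alpha)
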