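"""Cohort-level filtering and prioritisation of positive HERV loci.

Implements the control-exclusion rule (any detectable identity-filtered
signal in any healthy control removes the locus from consideration, a
deliberately weaker trigger than the positive-call criterion), detection
frequency ranking across patient samples with top-N selection,
presence/absence matrices per cell type, and set intersections of the
loci detected in different cell subsets (e.g. CD14+ vs CD16+ monocytes).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from wha.core import LocusCall
from wha.loci import parse_locus_id

CALL_COLUMNS = ["locus_id", "sample_id", "cell_type", "usable_windows", "status", "raw_read_count"]


def calls_to_frame(calls: list[LocusCall]) -> pd.DataFrame:
    """Tabulate locus calls as a DataFrame with the standard call columns."""
    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "sample_id": c.sample_id,
                "cell_type": c.cell_type,
                "usable_windows": c.usable_windows,
                "status": c.status,
                "raw_read_count": c.raw_read_count,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def locus_sort_key(locus_id: str) -> tuple:
    """(chromosome, start) ordering key; numeric chromosomes sort numerically."""
    chrom, start, _end = parse_locus_id(locus_id)
    core = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(core)) if core.isdigit() else (1, core), start


@dataclass
class ControlSignalIndex:
    """Per-locus record of detectable signal in any control sample.

    ``table`` is indexed by locus_id with columns ``signal`` (bool) and
    ``control_reads`` (supporting retained-read count). A locus absent
    from the table has no control signal.
    """

    table: pd.DataFrame

    def has_signal(self, locus_id: str) -> bool:
        if locus_id in self.table.index:
            return bool(self.table.loc[locus_id, "signal"])
        return False

    def loci_with_signal(self) -> set[str]:
        return set(self.table.index[self.table["signal"]])


def build_control_index(
    alignment_counts: pd.DataFrame,
    control_sample_ids: list[str],
    calls: pd.DataFrame | None = None,
    trigger: str = "signal",
) -> ControlSignalIndex:
    """Index loci by detectable signal in control samples.

    ``alignment_counts`` has columns locus_id, sample_id and
    retained_reads — retained (identity-filtered) alignments pooled over
    all cell types and runs of each sample. With the default
    ``trigger="signal"``, one retained control read suffices to mark a
    locus; ``trigger="call"`` instead requires a positive consensus call
    in a control sample (pass ``calls``). Raises if the cohort has no
    control samples, since the exclusion filter is then undefined.
    """
    if not control_sample_ids:
        raise ValueError("control exclusion is undefined without control samples")
    ctrl = alignment_counts[alignment_counts["sample_id"].isin(control_sample_ids)]
    reads = ctrl.groupby("locus_id")["retained_reads"].sum()
    if trigger == "signal":
        signal = reads > 0
    elif trigger == "call":
        if calls is None:
            raise ValueError("trigger='call' requires the calls table")
        pos = calls[
            calls["sample_id"].isin(control_sample_ids) & (calls["status"] == "positive")
        ]["locus_id"]
        signal = pd.Series(False, index=reads.index)
        signal.loc[signal.index.intersection(set(pos))] = True
        extra = set(pos) - set(reads.index)
        if extra:
            signal = pd.concat([signal, pd.Series(True, index=sorted(extra))])
            reads = pd.concat([reads, pd.Series(0, index=sorted(extra))])
    else:
        raise ValueError(f"unknown exclusion trigger {trigger!r}")
    table = pd.DataFrame({"signal": signal, "control_reads": reads}).sort_index()
    table.index.name = "locus_id"
    return ControlSignalIndex(table)


@dataclass
class CohortMatrix:
    """Presence/absence of loci across the patient samples of one cell type.

    ``matrix`` is boolean, loci × samples, containing only loci that
    survived control exclusion; rows are ordered by detection count
    descending, ties by (chromosome, start).
    """

    cell_type: str
    matrix: pd.DataFrame

    @property
    def detection_count(self) -> pd.Series:
        return self.matrix.sum(axis=1).astype(int)

    @property
    def loci(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)


def _sort_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    counts = matrix.sum(axis=1)
    order = sorted(matrix.index, key=lambda lid: (-counts[lid], locus_sort_key(lid)))
    return matrix.loc[order]


def filter_patient_loci(
    patient_calls: pd.DataFrame,
    control_index: ControlSignalIndex,
    patient_ids: list[str],
    cell_type: str = "",
) -> CohortMatrix:
    """Patient-cohort presence matrix after control exclusion.

    Keeps loci positive in at least one patient sample *and* free of any
    control signal; every column is a patient, rows carry detection
    counts implicitly via the row order.
    """
    calls = patient_calls[patient_calls["sample_id"].isin(patient_ids)]
    if cell_type:
        calls = calls[calls["cell_type"] == cell_type]
    pos = calls[calls["status"] == "positive"]
    keep = [
        lid for lid in pos["locus_id"].unique() if not control_index.has_signal(lid)
    ]
    matrix = pd.DataFrame(False, index=keep, columns=list(patient_ids))
    for row in pos.itertuples(index=False):
        if row.locus_id in matrix.index:
            matrix.loc[row.locus_id, row.sample_id] = True
    matrix.index.name = "locus_id"
    return CohortMatrix(cell_type, _sort_matrix(matrix))


def rank_and_select_top(cm: CohortMatrix, n: int = 10) -> CohortMatrix:
    """The ``n`` most frequently detected loci (fewer if the matrix is smaller).

    Deterministic: detection count descending, ties broken by
    (chromosome, start) ascending.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return CohortMatrix(cm.cell_type, _sort_matrix(cm.matrix).head(n))


@dataclass
class SubsetIntersection:
    """Membership of positive loci across cell subsets, UpSet-style.

    ``membership`` maps each positive locus to the frozenset of subset
    labels it is detected in (positive in >=1 sample of that subset);
    ``counts`` tabulates the distinct membership patterns. Every positive
    locus belongs to exactly one pattern, so pattern counts sum to the
    number of positive loci.
    """

    labels: list[str]
    membership: dict[str, frozenset[str]]
    counts: pd.DataFrame  # columns: pattern, count, loci

    def pattern_count(self, *labels: str) -> int:
        want = "&".join(sorted(labels))
        hit = self.counts[self.counts["pattern"] == want]
        return int(hit["count"].iloc[0]) if len(hit) else 0


def intersect_subsets(matrices: dict[str, CohortMatrix | pd.DataFrame]) -> SubsetIntersection:
    """Exhaustive membership patterns of loci across >= 2 subsets."""
    if len(matrices) < 2:
        raise ValueError("need at least two subset labels to intersect")
    labels = sorted(matrices)
    detected: dict[str, set[str]] = {}
    for label in labels:
        m = matrices[label]
        mat = m.matrix if isinstance(m, CohortMatrix) else m
        detected[label] = set(mat.index[mat.any(axis=1)])
    membership: dict[str, frozenset[str]] = {}
    for lid in sorted(set().union(*detected.values()), key=locus_sort_key):
        membership[lid] = frozenset(l for l in labels if lid in detected[l])
    rows = []
    for r in range(len(labels), 0, -1):
        for combo in combinations(labels, r):
            pat = frozenset(combo)
            loci = sorted((l for l, m in membership.items() if m == pat), key=locus_sort_key)
            if loci:
                rows.append(
                    {"pattern": "&".join(sorted(pat)), "count": len(loci),
                     "loci": ",".join(loci)}
                )
    counts = pd.DataFrame(rows, columns=["pattern", "count", "loci"])
    return SubsetIntersection(labels, membership, counts)


def cross_celltype_summary(matrices: dict[str, CohortMatrix]) -> pd.DataFrame:
    """Patient-detection counts per locus across cell types.

    Rows are loci detected in at least one cell type; one integer column
    per cell type plus an ``exclusive_cell_type`` column naming the cell
    type when a locus is detected in exactly one (empty string otherwise).
    """
    cell_types = sorted(matrices)
    all_loci = sorted(
        set().union(*(set(m.matrix.index) for m in matrices.values())),
        key=locus_sort_key,
    )
    out = pd.DataFrame(0, index=all_loci, columns=cell_types)
    for ct in cell_types:
        counts = matrices[ct].detection_count
        out.loc[counts.index, ct] = counts
    out = out[out.sum(axis=1) > 0]
    nonzero = out.gt(0)
    out["exclusive_cell_type"] = [
        row.idxmax() if row.sum() == 1 else ""
        for _lid, row in nonzero.iterrows()
    ]
    out.index.name = "locus_id"
    return out
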