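"""Synthetic cohort generator with planted locus-expression ground truth.

Emulates the situation the pipeline is built for: a cohort of patient and
control samples, several annotated cell types per sample, a subset of HERV
loci transcribed only in one cell type of patients, substitution
sequencing error, and duplicate technical runs per sample. Reads are
simulated directly from the locus sequences (the pipeline operates only on
the locus reference, so flanking genome context adds nothing testable) and
carry their cell barcode in the read name — the contract starts after
barcode-based extraction, so 10x chemistry is not emulated.

Everything is deterministic under a fixed seed, and the generator returns
a truth table of exactly which (sample, cell type, locus) triples were
planted deeply and broadly enough to be called positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from wha.core import DEFAULT_MIN_DEPTH, DEFAULT_MIN_USABLE_WINDOWS
from wha.io import (
    DEFAULT_CELL_TYPES,
    CellAnnotation,
    Sample,
    SampleSheet,
    write_annotations,
    write_locus_reference,
    write_sample_sheet,
)
from wha.loci import HervLocus, format_locus_id

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the pipeline targets: 12 patients vs 30
    healthy controls, seven PBMC cell types, duplicate runs per sample,
    ~8-10 kb near-full-length proviral loci tiled in 500 bp windows, and
    90 bp reads with a low substitution error rate (0.001, so that at the
    default read length >90% of reads carry no error and survive the
    strict >99% identity filter in expectation).
    """

    seed: int = 0
    n_patients: int = 12
    n_controls: int = 30
    cell_types: dict[str, int] = field(
        default_factory=lambda: {ct: 10 for ct in DEFAULT_CELL_TYPES}
    )
    read_length: int = 90
    substitution_error_rate: float = 0.001
    window_size: int = 500
    n_loci: int = 12
    locus_length_range: tuple[int, int] = (8000, 10000)
    duplicate_runs: int = 2
    tissue: str = "PBMC"

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "read_length", "window_size",
                     "n_loci", "duplicate_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if any(n < 1 for n in self.cell_types.values()):
            raise ValueError("cells per type must be >= 1")
        lo, hi = self.locus_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid locus_length_range")


@dataclass
class ExpressionPlan:
    """Planted expression: per (group, cell type, locus) depth and extent.

    ``loci`` maps (group, cell_type, locus_id) to (expected per-window
    depth, expressed fraction of the locus in (0, 1]); absent keys are
    silent. An expressed fraction below 1 covers only a prefix of the
    locus, which lets tests plant exactly k covered windows. ``genes`` is
    the per-group analogue for host genes, keyed by (group, gene_id).
    """

    loci: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    genes: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (depth, frac) in {**self.loci}.items():
            if depth < 0:
                raise ValueError(f"negative depth for {key}")
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"expressed fraction for {key} must be in (0, 1]")

    def entries_for(self, group: str) -> dict[tuple[str, str], tuple[float, float]]:
        """(cell_type, locus_id) -> (depth, fraction) for one sample group."""
        return {
            (ct, lid): df for (g, ct, lid), df in sorted(self.loci.items()) if g == group
        }

    def control_silent_loci(self) -> set[str]:
        """Loci with no expression entry in any control plan."""
        expressed_in_controls = {
            lid for (g, _ct, lid), (depth, _f) in self.loci.items()
            if g == "control" and depth > 0
        }
        all_loci = {lid for (_g, _ct, lid) in self.loci}
        return all_loci - expressed_in_controls


def default_expression_plan(locus_ids: list[str], depth: float = 10.0) -> ExpressionPlan:
    """The study-condition plan for a cohort reference of >= 5 loci.

    One locus expressed in every sample's classical monocytes (exercises
    control exclusion), three loci expressed only in patients' CD14+
    monocytes (the cell-type-exclusive signal of interest), one locus
    expressed in patients' CD14+ and CD16+ monocytes (a shared-subset
    locus); the remainder silent everywhere.
    """
    if len(locus_ids) < 5:
        raise ValueError("default plan needs at least 5 loci")
    plan: dict[tuple[str, str, str], tuple[float, float]] = {}
    for group in ("patient", "control"):
        plan[(group, "CD14_Mono", locus_ids[0])] = (depth, 1.0)
    for lid in locus_ids[1:4]:
        plan[("patient", "CD14_Mono", lid)] = (depth, 1.0)
    plan[("patient", "CD14_Mono", locus_ids[4])] = (depth, 1.0)
    plan[("patient", "CD16_Mono", locus_ids[4])] = (depth, 1.0)
    return ExpressionPlan(loci=plan)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_reference(config: SimConfig) -> list[HervLocus]:
    """Random-sequence HERV loci with lengths uniform over the configured range.

    Deterministic given the config seed. Loci are placed on successive
    chromosomes at arbitrary (non-overlapping per chromosome) coordinates.
    """
    lo, hi = config.locus_length_range
    if lo < config.window_size:
        raise ValueError(
            f"locus_length_range {config.locus_length_range} is below one "
            f"window ({config.window_size} bp)"
        )
    rng = np.random.default_rng([config.seed, 0])
    loci = []
    for i in range(config.n_loci):
        length = int(rng.integers(lo, hi + 1))
        chrom = f"chr{(i % 22) + 1}"
        start = int(rng.integers(100_000, 50_000_000))
        loci.append(
            HervLocus(
                locus_id=format_locus_id(chrom, start, start + length - 1),
                chrom=chrom,
                start=start,
                end=start + length - 1,
                sequence=_random_sequence(rng, length),
            )
        )
    return loci


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Apply i.i.d. substitution errors to a uint8 base array."""
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return out


def _planted_positive(depth: float, frac: float, locus_len: int, window_size: int,
                      min_depth: float, min_usable: int) -> bool:
    """Whether a planted (depth, fraction) should produce a positive call."""
    covered = int(frac * locus_len)
    full_covered_windows = covered // window_size
    return depth >= min_depth and full_covered_windows >= min_usable


def simulate_cohort(
    config: SimConfig,
    plan: ExpressionPlan,
    outdir: str | Path,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_usable_windows: int = DEFAULT_MIN_USABLE_WINDOWS,
) -> tuple[SampleSheet, pd.DataFrame, list[HervLocus]]:
    """Write a full synthetic cohort to ``outdir`` and return its ground truth.

    Produces the locus reference (``ref.fa``/``ref.bed``), one FASTQ per
    (sample, duplicate run) under ``reads/``, one annotation TSV per sample
    under ``annotations/``, the sample sheet ``samples.tsv``, and
    ``truth.tsv`` listing every (sample, cell_type, locus) triple planted
    deeply and broadly enough to be called positive at the given
    thresholds. Duplicate runs are independent draws with distinct
    sub-seeds. Read counts per (cell type, locus) are chosen so the
    expected per-window depth matches the plan.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)

    loci = make_reference(config)
    locus_by_id = {loc.locus_id: loc for loc in loci}
    for (_g, _ct, lid) in plan.loci:
        if lid not in locus_by_id:
            raise ValueError(f"expression plan references unknown locus {lid}")
    write_locus_reference(loci, outdir / "ref.fa", outdir / "ref.bed")

    sample_ids = [f"patient_{i + 1:02d}" for i in range(config.n_patients)] + [
        f"control_{i + 1:02d}" for i in range(config.n_controls)
    ]
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls

    samples: list[Sample] = []
    truth_rows: list[dict] = []
    for si, (sample_id, group) in enumerate(zip(sample_ids, groups)):
        bc_rng = np.random.default_rng([config.seed, 1, si])
        barcodes: dict[str, list[str]] = {}
        seen: set[str] = set()
        annotations: list[CellAnnotation] = []
        for ct in sorted(config.cell_types):
            n_cells = config.cell_types[ct]
            bcs = []
            while len(bcs) < n_cells:
                bc = _random_sequence(bc_rng, 16) + "-1"
                if bc not in seen:
                    seen.add(bc)
                    bcs.append(bc)
            barcodes[ct] = bcs
            for bc in bcs:
                score = round(float(bc_rng.uniform(0.85, 1.0)), 4)
                annotations.append(CellAnnotation(bc, ct, score))
        ann_path = outdir / "annotations" / f"{sample_id}.tsv"
        write_annotations(annotations, ann_path)

        entries = plan.entries_for(group)
        run_paths = []
        for run in range(config.duplicate_runs):
            rng = np.random.default_rng([config.seed, 2, si, run])
            fq_path = outdir / "reads" / f"{sample_id}_run{run + 1}.fastq"
            serial = 0
            with open(fq_path, "w") as fq:
                for (ct, lid), (depth, frac) in entries.items():
                    if depth <= 0:
                        continue
                    if ct not in barcodes:
                        raise ValueError(f"plan cell type {ct!r} not in config.cell_types")
                    locus = locus_by_id[lid]
                    covered = int(frac * locus.length)
                    if covered < config.read_length:
                        raise ValueError(
                            f"expressed region of {lid} ({covered} bp) shorter "
                            f"than read length {config.read_length}"
                        )
                    n_reads = round(depth * covered / config.read_length)
                    ref = np.frombuffer(locus.sequence.encode(), dtype=np.uint8)
                    starts = rng.integers(0, covered - config.read_length + 1, size=n_reads)
                    bc_idx = rng.integers(0, len(barcodes[ct]), size=n_reads)
                    for start, bi in zip(starts, bc_idx):
                        seq = _mutate(
                            rng,
                            ref[start : start + config.read_length],
                            config.substitution_error_rate,
                        )
                        name = f"{sample_id}.{serial}|{barcodes[ct][bi]}"
                        fq.write(
                            f"@{name}\n{seq.tobytes().decode()}\n+\n"
                            f"{'I' * config.read_length}\n"
                        )
                        serial += 1
            run_paths.append(str(fq_path))

        for (ct, lid), (depth, frac) in entries.items():
            if _planted_positive(depth, frac, locus_by_id[lid].length,
                                 config.window_size, min_depth, min_usable_windows):
                truth_rows.append(
                    {"sample_id": sample_id, "cell_type": ct, "locus_id": lid}
                )

        samples.append(
            Sample(sample_id, group, config.tissue, tuple(run_paths), str(ann_path))
        )

    sheet = SampleSheet(samples)
    write_sample_sheet(sheet, outdir / "samples.tsv")
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "cell_type", "locus_id"])
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return sheet, truth, loci
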