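"""Readers and writers for the standard formats the pipeline touches.

FASTA + BED3/BED4 for the HERV locus reference, TSV for per-cell
annotations (barcode, cell type, mapping score — the shape of an Azimuth
annotation export), presence/absence matrices ("+" / "-") and the sample
sheet assigning samples to groups and duplicate runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from wha.loci import HervLocus

logger = logging.getLogger(__name__)

#: Default cell-type vocabulary: the seven PBMC populations analysed by the
#: pipeline. Unknown labels pass through with a warning, so tissue-specific
#: labels (e.g. monocyte-derived macrophage in lavage samples) work unchanged.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "B", "CD4_T", "CD8_T", "NK", "DC", "CD14_Mono", "CD16_Mono",
)

#: Bin label for reads whose barcode has no annotation.
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class CellAnnotation:
    """Cell-type annotation for one barcode, with the annotation confidence score."""

    barcode: str
    cell_type: str
    mapping_score: float = 1.0


@dataclass
class Sample:
    """One sample of the cohort: group membership, tissue, and file paths."""

    sample_id: str
    group: str  # "patient" or "control"
    tissue: str
    run_paths: tuple[str, ...]  # one FASTQ (or SAM) per duplicate run
    annotation_path: str

    @property
    def n_runs(self) -> int:
        return len(self.run_paths)


@dataclass
class SampleSheet:
    """Cohort sample sheet; every sample carries its duplicate-run file paths."""

    samples: list[Sample] = field(default_factory=list)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def patients(self) -> list[Sample]:
        return [s for s in self.samples if s.group == "patient"]

    def controls(self) -> list[Sample]:
        return [s for s in self.samples if s.group == "control"]

    def by_id(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def read_locus_reference(fasta_path: str | Path, bed_path: str | Path) -> list[HervLocus]:
    """Load the HERV locus reference from a BED file plus matching FASTA.

    BED records are 0-based half-open. FASTA entries are matched to BED
    records by the BED name column (column 4) when present, otherwise by
    ``chrom:start-end`` in 1-based display coordinates; a whole-chromosome
    FASTA entry named by ``chrom`` also works, in which case the interval is
    sliced out. A BED record without a matching sequence, or whose sequence
    length disagrees with the interval length, is a hard error naming the
    record.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    loci: list[HervLocus] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: BED record needs >=3 columns")
            chrom, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) >= 4 else None
            keys = []
            if name:
                keys.append(name)
            keys.append(f"{chrom}:{bed_start + 1}-{bed_end}")
            seq = None
            for key in keys:
                if key in seqs:
                    seq = seqs[key]
                    break
            if seq is None and chrom in seqs and len(seqs[chrom]) >= bed_end:
                seq = seqs[chrom][bed_start:bed_end]
            if seq is None:
                raise ValueError(
                    f"{bed_path}:{lineno}: no FASTA sequence for BED record "
                    f"{chrom}:{bed_start}-{bed_end} (tried keys {keys})"
                )
            if len(seq) != bed_end - bed_start:
                raise ValueError(
                    f"{bed_path}:{lineno}: sequence length {len(seq)} != interval "
                    f"length {bed_end - bed_start} for {chrom}:{bed_start}-{bed_end}"
                )
            loci.append(HervLocus.from_bed_record(chrom, bed_start, bed_end, seq))
    ids = [loc.locus_id for loc in loci]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate locus ids in reference: {dupes}")
    return loci


def write_locus_reference(loci: list[HervLocus], fasta_path: str | Path, bed_path: str | Path) -> None:
    """Write loci as BED4 (name = locus id) plus a FASTA keyed by locus id."""
    with open(bed_path, "w") as bed:
        for loc in loci:
            bed.write(f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{loc.locus_id}\n")
    with open(fasta_path, "w") as fa:
        for loc in loci:
            fa.write(f">{loc.locus_id}\n")
            for i in range(0, len(loc.sequence), 80):
                fa.write(loc.sequence[i : i + 80] + "\n")


def read_annotations(
    tsv_path: str | Path,
    min_mapping_score: float = 0.0,
    vocabulary: tuple[str, ...] = DEFAULT_CELL_TYPES,
) -> list[CellAnnotation]:
    """Load a barcode → cell-type annotation table.

    Expects tab-separated columns ``barcode``, ``cell_type`` and optionally
    ``mapping_score``; a missing score column is imputed as 1.0 with a
    warning. Rows with mapping_score < ``min_mapping_score`` are dropped
    (default 0: no filtering — the score is consumed, not thresholded).
    Duplicate barcodes are a hard error; cell types outside ``vocabulary``
    are kept with a warning.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"barcode": str, "cell_type": str})
    for col in ("barcode", "cell_type"):
        if col not in df.columns:
            raise ValueError(f"{tsv_path}: missing required column {col!r}")
    if "mapping_score" not in df.columns:
        warnings.warn(f"{tsv_path}: no mapping_score column; imputing 1.0")
        df["mapping_score"] = 1.0
    if df["barcode"].duplicated().any():
        dupes = sorted(df.loc[df["barcode"].duplicated(), "barcode"].unique())
        raise ValueError(f"{tsv_path}: duplicate barcodes {dupes[:5]}")
    unknown = sorted(set(df["cell_type"]) - set(vocabulary))
    if unknown:
        warnings.warn(f"{tsv_path}: cell types outside declared vocabulary: {unknown}")
    kept = df[df["mapping_score"] >= min_mapping_score]
    return [
        CellAnnotation(r.barcode, r.cell_type, float(r.mapping_score))
        for r in kept.itertuples(index=False)
    ]


def annotation_map(annotations: list[CellAnnotation]) -> dict[str, str]:
    """Barcode → cell-type lookup."""
    return {a.barcode: a.cell_type for a in annotations}


def write_annotations(annotations: list[CellAnnotation], tsv_path: str | Path) -> None:
    pd.DataFrame(
        {
            "barcode": [a.barcode for a in annotations],
            "cell_type": [a.cell_type for a in annotations],
            "mapping_score": [a.mapping_score for a in annotations],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


# Presence/absence matrices: loci x samples DataFrames of booleans. On disk
# they use "+" / "-" cells (unicode minus/en-dash accepted on read) matching
# the supplementary-table convention.

_ABSENT_GLYPHS = {"-", "−", "–"}


def write_presence_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a loci × samples boolean matrix as a "+"/"-" TSV."""
    out = matrix.map(lambda v: "+" if v else "-")
    out.index.name = "locus_id"
    out.to_csv(path, sep="\t")


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Read a "+"/"-" TSV back into a loci × samples boolean matrix."""
    df = pd.read_csv(path, sep="\t", index_col="locus_id", dtype=str)
    bad = set(df.values.ravel()) - ({"+"} | _ABSENT_GLYPHS)
    if bad:
        raise ValueError(f"{path}: unexpected presence glyphs {sorted(bad)}")
    return df.map(lambda v: v == "+")


def write_sample_sheet(sheet: SampleSheet, path: str | Path, relative: bool = True) -> None:
    """Write the sheet as TSV; with ``relative`` (default), file paths are
    stored relative to the sheet's directory so a cohort is relocatable and
    reruns are byte-identical regardless of the output location."""
    base = Path(path).resolve().parent

    def _fmt(p: str) -> str:
        if not relative or not p:
            return p
        try:
            return str(Path(p).resolve().relative_to(base))
        except ValueError:
            return p

    n_runs = max((s.n_runs for s in sheet), default=2)
    rows = []
    for s in sheet:
        row = {"sample_id": s.sample_id, "group": s.group, "tissue": s.tissue,
               "annotations": _fmt(s.annotation_path)}
        for i in range(n_runs):
            row[f"reads_run{i + 1}"] = _fmt(s.run_paths[i]) if i < s.n_runs else ""
        rows.append(row)
    cols = ["sample_id", "group", "tissue", "annotations"] + [
        f"reads_run{i + 1}" for i in range(n_runs)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    base = Path(path).resolve().parent

    def _resolve(p: str) -> str:
        return p if not p or Path(p).is_absolute() else str(base / p)

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    run_cols = sorted(
        (c for c in df.columns if c.startswith("reads_run")),
        key=lambda c: int(c.removeprefix("reads_run")),
    )
    if not run_cols:
        raise ValueError(f"{path}: no reads_run* columns")
    samples = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        runs = tuple(_resolve(d[c]) for c in run_cols if d[c])
        if d["group"] not in ("patient", "control"):
            raise ValueError(f"{path}: unknown group {d['group']!r} for {d['sample_id']}")
        samples.append(
            Sample(d["sample_id"], d["group"], d.get("tissue", ""), runs,
                   _resolve(d["annotations"]))
        )
    return SampleSheet(samples)
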