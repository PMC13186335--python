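"""End-to-end orchestration: call → cohort → gene stages with a run manifest.

Thresholds live in a single RunConfig whose defaults are the published
operating point of the method (500 bp windows, per-window depth >= 3, >= 9
usable windows, identity strictly > 99%, top-10 selection, alpha 0.05,
duplicate-run intersection consensus). Every run writes the effective
config, its hash and package versions into ``manifest.json``; re-running
with the same config and inputs reproduces byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

import wha
from wha.cohort import (
    build_control_index,
    calls_to_frame,
    cross_celltype_summary,
    filter_patient_loci,
    intersect_subsets,
    rank_and_select_top,
)
from wha.core import (
    LocusAligner,
    LocusCall,
    align_and_filter,
    call_locus,
    compute_window_coverage,
    read_fastq,
)
from wha.genestats import compare_groups, profile_from_alignments, stats_to_frame
from wha.io import (
    UNANNOTATED,
    SampleSheet,
    annotation_map,
    read_annotations,
    read_locus_reference,
    read_sample_sheet,
    write_presence_matrix,
)
from wha.loci import HervLocus

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and paths for one pipeline run."""

    reference_fasta: str = ""
    reference_bed: str = ""
    sample_sheet: str = ""
    gene_fasta: str = ""
    output_dir: str = "wha_out"

    window_size: int = 500
    min_depth: float = 3.0
    min_usable_windows: int = 9
    identity_threshold: float = 99.0
    top_n: int = 10
    alpha: float = 0.05
    consensus: str = "intersection"
    depth_metric: str = "mean"
    min_mapping_score: float = 0.0
    control_trigger: str = "signal"
    subset_labels: tuple[str, ...] = ("CD14_Mono", "CD16_Mono")
    stratify_locus: str = ""
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "subset_labels" in data:
            data["subset_labels"] = tuple(data["subset_labels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subset_labels"] = list(d["subset_labels"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _atomic_to_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=index)
    os.replace(tmp, path)


def read_gene_fasta(path: str | Path) -> list[HervLocus]:
    """Host gene reference sequences, one entry per gene (id = gene name)."""
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        genes.append(HervLocus(rec.id, rec.id, 1, len(seq), seq))
    return genes


def call_stage(
    config: RunConfig, sheet: SampleSheet, loci: list[HervLocus]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Align, partition by cell type, compute window coverage and call loci.

    Returns (per-run calls, consensus calls, per-sample retained-alignment
    counts). Missing (locus, cell type) combinations are implicitly
    negative; a combination observed in any run enters consensus with
    zero-coverage stand-ins for the runs that lack it.
    """
    locus_by_id = {loc.locus_id: loc for loc in loci}
    aligner = LocusAligner(loci)
    run_call_keys: dict[tuple[str, str, str], dict[str, LocusCall]] = {}
    count_rows: list[dict] = []

    for sample in sheet:
        ann = annotation_map(
            read_annotations(sample.annotation_path, config.min_mapping_score)
        )
        for run_idx, run_path in enumerate(sample.run_paths):
            run_id = f"run{run_idx + 1}"
            alignments = align_and_filter(
                read_fastq(run_path), aligner, config.identity_threshold
            )
            grouped: dict[tuple[str, str], list] = {}
            for aln in alignments:
                ct = ann.get(aln.barcode, UNANNOTATED) if aln.barcode else UNANNOTATED
                grouped.setdefault((aln.locus_id, ct), []).append(aln)
            for (lid, ct) in sorted(grouped):
                alns = grouped[(lid, ct)]
                count_rows.append(
                    {"sample_id": sample.sample_id, "run_id": run_id,
                     "cell_type": ct, "locus_id": lid, "retained_reads": len(alns)}
                )
                if ct == UNANNOTATED:
                    continue
                cov = compute_window_coverage(
                    alns, locus_by_id[lid], config.window_size,
                    sample_id=sample.sample_id, cell_type=ct, run_id=run_id,
                    metric=config.depth_metric,
                )
                call = call_locus(
                    cov, config.min_depth, config.min_usable_windows,
                    raw_read_count=len(alns),
                )
                run_call_keys.setdefault((lid, sample.sample_id, ct), {})[run_id] = call
        logger.info("call stage: sample %s done (%d runs)", sample.sample_id, sample.n_runs)

    consensus: list[LocusCall] = []
    for key in sorted(run_call_keys):
        lid, sid, ct = key
        n_runs = sheet.by_id(sid).n_runs
        per_run = run_call_keys[key]
        calls = [
            per_run.get(
                f"run{r + 1}",
                LocusCall(lid, sid, ct, 0, "negative", 0),
            )
            for r in range(n_runs)
        ]
        consensus.append(wha.consensus_call(calls, config.consensus))

    run_df = pd.DataFrame(
        [
            {"locus_id": c.locus_id, "sample_id": c.sample_id, "cell_type": c.cell_type,
             "run_id": rid, "usable_windows": c.usable_windows, "status": c.status,
             "raw_read_count": c.raw_read_count}
            for (key, runs) in sorted(run_call_keys.items())
            for rid, c in sorted(runs.items())
        ],
        columns=["locus_id", "sample_id", "cell_type", "run_id",
                 "usable_windows", "status", "raw_read_count"],
    )
    cons_df = calls_to_frame(consensus)
    counts_df = pd.DataFrame(
        count_rows, columns=["sample_id", "run_id", "cell_type", "locus_id", "retained_reads"]
    )
    return run_df, cons_df, counts_df


def cohort_stage(
    config: RunConfig, sheet: SampleSheet, cons_df: pd.DataFrame, counts_df: pd.DataFrame,
    outdir: Path,
) -> dict:
    """Control exclusion, per-cell-type matrices, top-N, intersections."""
    control_ids = [s.sample_id for s in sheet.controls()]
    patient_ids = [s.sample_id for s in sheet.patients()]
    index = build_control_index(
        counts_df, control_ids, calls=cons_df, trigger=config.control_trigger
    )
    index.table.to_csv(outdir / "control_index.tsv", sep="\t")

    matrices = {}
    mat_dir = outdir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    cell_types = sorted(
        cons_df[cons_df["sample_id"].isin(patient_ids)]["cell_type"].unique()
    )
    for ct in cell_types:
        cm = filter_patient_loci(cons_df, index, patient_ids, ct)
        matrices[ct] = cm
        write_presence_matrix(cm.matrix, mat_dir / f"{ct}.tsv")
        top = rank_and_select_top(cm, config.top_n)
        write_presence_matrix(top.matrix, mat_dir / f"{ct}_top{config.top_n}.tsv")

    summary = cross_celltype_summary(matrices) if matrices else pd.DataFrame()
    _atomic_to_tsv(summary, outdir / "celltype_summary.tsv", index=True)

    inter = None
    subset = {l: matrices[l] for l in config.subset_labels if l in matrices}
    if len(subset) >= 2:
        inter = intersect_subsets(subset)
        _atomic_to_tsv(inter.counts, outdir / "subset_intersection.tsv")
    return {
        "matrices": matrices,
        "control_index": index,
        "summary": summary,
        "intersection": inter,
    }


def gene_stage(
    config: RunConfig, sheet: SampleSheet, cons_df: pd.DataFrame, outdir: Path
) -> dict:
    """Host-gene window/depth stats with ANOVA + Tukey across groups."""
    genes = read_gene_fasta(config.gene_fasta)
    # optional stratification of patient samples by a HERV locus call
    strata: dict[str, str] = {}
    for s in sheet:
        group = s.group
        if config.stratify_locus and s.group == "patient":
            pos = cons_df[
                (cons_df["sample_id"] == s.sample_id)
                & (cons_df["locus_id"] == config.stratify_locus)
                & (cons_df["status"] == "positive")
            ]
            group = "patient_HERV_positive" if len(pos) else "patient_HERV_negative"
        strata[s.sample_id] = group

    all_stats = []
    comparisons = []
    for gene in genes:
        aligner = LocusAligner([gene])
        for s in sheet:
            alns = []
            for run_path in s.run_paths:
                alns.extend(
                    align_and_filter(read_fastq(run_path), aligner, config.identity_threshold)
                )
            all_stats.append(
                profile_from_alignments(
                    alns, gene, config.window_size, config.min_depth,
                    sample_id=s.sample_id, group=strata[s.sample_id],
                )
            )
    stats_df = stats_to_frame(all_stats)
    _atomic_to_tsv(stats_df, outdir / "gene_stats.tsv")

    rows = []
    for gene in genes:
        sub = stats_df[stats_df["gene_id"] == gene.locus_id]
        for metric in ("usable_windows", "mean_depth"):
            gc = compare_groups(sub, metric, config.alpha)
            comparisons.append((gene.locus_id, gc))
            for r in gc.pairwise.itertuples(index=False):
                rows.append(
                    {"gene_id": gene.locus_id, "metric": metric,
                     "anova_F": gc.anova_F, "anova_p": gc.anova_p,
                     "group1": r.group1, "group2": r.group2,
                     "mean_diff": r.mean_diff, "p_adj": r.p_adj,
                     "significant": r.significant}
                )
    _atomic_to_tsv(pd.DataFrame(rows), outdir / "gene_comparisons.tsv")
    return {"stats": stats_df, "comparisons": comparisons}


def run_pipeline(config: RunConfig) -> dict:
    """Run call → cohort → gene stages; returns the in-memory results.

    Stage outputs land under ``config.output_dir``; any stage failure
    aborts with the failing stage named. The manifest records the
    effective config, its hash and package versions.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        sheet = read_sample_sheet(config.sample_sheet)
        loci = read_locus_reference(config.reference_fasta, config.reference_bed)

        stage = "call"
        run_df, cons_df, counts_df = call_stage(config, sheet, loci)
        _atomic_to_tsv(run_df, outdir / "calls_runs.tsv")
        _atomic_to_tsv(cons_df, outdir / "consensus_calls.tsv")
        _atomic_to_tsv(counts_df, outdir / "alignment_counts.tsv")
        results.update(run_calls=run_df, consensus_calls=cons_df, alignment_counts=counts_df)

        stage = "cohort"
        results["cohort"] = cohort_stage(config, sheet, cons_df, counts_df, outdir)

        if config.gene_fasta:
            stage = "gene"
            results["gene"] = gene_stage(config, sheet, cons_df, outdir)

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {
                "wha": wha.__version__,
                "numpy": __import__("numpy").__version__,
                "pandas": pd.__version__,
            },
            "n_samples": len(sheet),
            "n_loci": len(loci),
        }
        tmp = outdir / "manifest.json.tmp"
        tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        os.replace(tmp, outdir / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
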