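# wha — Window-based HERV Alignment

`wha` calls locus-specific transcription of autonomous human endogenous
retroviruses (HERVs) from cell-type-partitioned single-cell RNA-seq reads,
and runs the cohort analyses that sit on top of those calls.

The human genome carries thousands of near-full-length autonomous HERV
proviruses whose long terminal repeats can drive transcription. Because
these loci are highly repetitive, naive read counting cannot distinguish
genuine extended transcription of one locus from scattered cross-mapping
reads. The Window-based HERV Alignment (WHA) approach addresses this by
demanding *extended* and *locus-specific* evidence:

1. Reads (already extracted per cell type by barcode) are aligned against
   a reference of autonomous HERV loci and retained only at **strictly
   greater than 99% identity**; reads tying between loci are discarded.
2. Each locus is tiled into sequential, non-overlapping windows (default
   500 bp). A window is **usable** when its mean per-base read depth is
   **≥ 3**.
3. A locus is **positive** in a (sample, cell type) when it has **≥ 9
   usable windows** — i.e. a long stretch of the provirus is covered —
   and **negative** otherwise (8 or fewer usable windows, or depth below
   3). Duplicate technical runs of each sample are combined by an
   intersection consensus (positive in every run).

Cohort level, for a patient/control design:

- **Control exclusion** — any locus with *any* retained read in *any*
  healthy control is removed from consideration.
- Remaining loci are scored by the number of patient samples they are
  detected in, and the **top 10** are selected per cell type.
- Loci detected in different cell subsets (e.g. CD14⁺ vs CD16⁺ monocytes)
  are intersected UpSet-style, and loci detected in exactly one cell type
  are flagged.
- Host genes near a HERV locus can be profiled the same way (windows +
  depth per sample) and compared across groups by one-way ANOVA followed
  by Tukey's HSD test.

The package ships a synthetic-data generator that plants known
(sample, cell type, locus) expression with configurable depth, extent,
substitution error and duplicate runs, so the entire pipeline can be
exercised against ground truth without any external downloads.

## Worked example

Simulate a small cohort (4 patients, 6 controls, 8 loci of 8–10 kb; the
default plan plants one locus expressed in everyone's CD14⁺ monocytes,
three loci only in patients' CD14⁺ monocytes, and one in patients' CD14⁺
and CD16⁺ monocytes), then run the pipeline:

```bash
cat > sim.yaml <<'EOF'
n_patients: 4
n_controls: 6
n_loci: 8
locus_length_range: [8000, 10000]
cell_types: {CD14_Mono: 6, CD16_Mono: 6, B: 6}
EOF
wha simulate --config sim.yaml --seed 7 --out cohort
# simulated 10 samples, 30 planted positives -> cohort
wha run --ref cohort/ref.fa --bed cohort/ref.bed \
        --samples cohort/samples.tsv --out results
# done: 30 positive consensus calls across 10 samples -> results
```

`results/celltype_summary.tsv` counts, per locus and cell type, the
patients the locus was detected in after control exclusion, and flags
cell-type-exclusive loci:

```text
locus_id                CD14_Mono  CD16_Mono  exclusive_cell_type
Chr2:47337070-47345084  4          0          CD14_Mono
Chr3:383114-392392      4          0          CD14_Mono
Chr4:22977784-22986903  4          0          CD14_Mono
Chr5:24278490-24288410  4          4
```

The three planted CD14-only loci are recovered in 4/4 patients and
flagged exclusive; the CD14+CD16 locus is detected in both subsets; the
locus expressed in controls was excluded entirely.
`results/subset_intersection.tsv` gives the UpSet-style membership
counts (3 loci CD14-only, 1 shared), and
`results/matrices/CD14_Mono_top10.tsv` is the ranked presence/absence
matrix ("+"/"-") of the most frequently detected loci.

The same stages are available as library functions
(`wha.align_and_filter`, `wha.call_locus`, `wha.filter_patient_loci`,
`wha.compare_groups`, ...) and as individual subcommands
(`wha call`, `wha cohort`, `wha gene`).

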