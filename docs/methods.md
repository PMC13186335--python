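# Methods

## The WHA classifier

WHA treats locus-level HERV transcription as a coverage-geometry problem.
For a locus of length L and window size w, the locus is tiled into
⌊L/w⌋ equal, sequential, non-overlapping windows starting at offset 0;
the trailing partial window is discarded rather than rescaled so that the
per-window depth threshold means the same thing in every window. With the
default w = 500 bp, a near-full-length provirus of 8–10 kb tiles into
16–20 windows, which makes the ≥ 9-usable-window criterion a demand for
roughly half the provirus to be covered.

The depth of a window is the **mean per-base depth**: total aligned bases
falling inside the window divided by w. The alternative reading of "read
depth" as the minimum per-base depth within a window is available as
`metric="min"` in `compute_window_coverage`; the mean is the default
because it is scale-free in w and robust to single uncovered bases at
alignment edges. A window is usable at depth ≥ 3; a locus is positive at
≥ 9 usable windows; both thresholds are parameters
(`min_depth`, `min_usable_windows`) and the defaults are the method's
published operating point.

### Identity filter

Reads are retained only at percent identity **strictly greater than**
99.0. Identity = matching aligned bases / aligned (non-clipped) length ×
100; soft-clipped bases are excluded from numerator and denominator, and
every inserted or deleted base counts as a mismatch. Consequences worth
knowing: a 100 bp read with one substitution is exactly 99.0% and is
*discarded*; at 90 bp read length only perfect reads pass, so the
retained fraction under a substitution error rate e is (1−e)^90.

The built-in aligner is exact-k-mer-seeded (k = 20, seeds at the start,
middle and end of the read), ungapped, both strands, scored by direct
base comparison with clipping at locus boundaries. It is sufficient for
substitution-error synthetic reads and small references; it is not a
BWA-class production aligner. Externally produced SAM records can be
ingested instead (`alignments_from_sam`), with identity recomputed from
CIGAR + NM when present, else by re-comparison to the reference. In both
routes a read whose best identity ties across distinct loci is discarded
— locus-specific attribution is the point of the method — and the
discard count is logged.

### Duplicate runs

Each sample is processed as duplicate technical runs. The consensus rule
is **intersection** (positive only if positive in every run), with
usable-window count and raw read count reported as the minimum across
runs; this is the conservative choice and `union`/`single` are available
by config. How the original analyses combined duplicates is not
documented, so intersection is this package's choice, not an asserted
fact about the original runs.

## Cohort analysis

Control exclusion operationalises "any detectable signal" as **≥ 1
retained (identity-filtered) alignment in ≥ 1 control sample**, pooled
across that donor's cell types and runs — deliberately weaker than a
positive call, because a locus with any control evidence is not
patient-specific. A `trigger="call"` switch restricts exclusion to
positive control calls instead. Exclusion is donor-wide (not per cell
type): a control read in any compartment removes the locus everywhere.

Detection frequency is the number of patient samples with a positive
consensus call; ranking is frequency-descending with ties broken by
(chromosome, start) ascending, so top-N selection is a deterministic
function of the matrix. Subset intersection declares a locus "in" a
subset when it is positive in at least one sample of that subset's
matrix; membership patterns partition the positive loci, so pattern
counts always sum to the number of distinct positive loci.

## Host-gene statistics

Reads are realigned to each gene's reference sequence with the same
identity filter and windowing. Per sample, the pipeline records the
usable-window count and the gene-wide mean per-base depth (total aligned
bases / gene length) — depths are raw, with no library-size
normalisation, matching the upstream analysis's use of absolute depth.
Groups are compared per metric by one-way ANOVA (scipy) followed by
Tukey's HSD (statsmodels, studentized-range distribution) at α = 0.05,
with no further multiple-testing correction. When every observation is
identical the F statistic is undefined; the comparison is reported
non-significant with a warning. Patient samples can be stratified into
HERV-positive/negative subsets by the consensus call of a configured
locus (`stratify_locus`) before comparison.

## Synthetic data generator

The generator emulates the pipeline's intended inputs: a cohort of
patients and controls (defaults 12 and 30), several annotated cell types
per sample (the seven PBMC labels, 10 cells each), duplicate runs,
8–10 kb random-sequence loci, 90 bp reads, and i.i.d. substitution
errors. Reads are drawn uniformly over the expressed prefix of a locus
(expressed fraction f covers the first ⌊fL⌋ bases, which lets tests
plant exactly k covered windows); the read count per
(sample, cell type, locus, run) is round(depth × covered/read_length), so
the expected per-window depth equals the planted value. Barcodes are
carried in read names (`{id}|{barcode}`); 10x chemistry, UMIs, PCR
duplication and cell-type misannotation are not modelled. The default
substitution rate is 0.001, at which >90% of 90 bp reads are error-free
and pass the strict identity filter; the planted per-window depth of 10
in the default plan keeps post-filter depth well above the threshold
even at a 0.5% error rate, where only ~64% of 90 bp reads survive.

What passing tests on this generator show: exact recovery of planted
positives through alignment, windowing, calling, consensus and control
exclusion, at realistic coverage and error. What they do not show:
robustness to cross-mapping between paralogous real HERV loci (random
sequences are far more distinguishable than real LTR families), to
alignment artefacts of a production aligner, or to annotation noise.

## Numerical and design choices

- Coordinates: BED input is 0-based half-open; locus identifiers display
  1-based inclusive (`Chr3:46046256-46054342`); the parser tolerates
  thousands-separator commas and en-dash/minus range separators.
- Window depth accumulates interval overlaps (not a per-base pile-up);
  tests verify equality with an explicit pile-up oracle to 1e−9.
- Determinism: all randomness flows from `numpy.random.default_rng`
  seeded per (seed, stream, sample, run); identical config + seed gives
  byte-identical FASTQ/TSV/JSON outputs, and sample sheets store paths
  relative to the sheet so reruns are location-independent.
- Problem sizes in the test suite: the end-to-end checks run the full
  12-patient/30-control default cohort (~100k reads per cohort); unit
  tests use 2–3 samples and 5–6 kb loci.
- The exact window length of the original analyses is not printed in the
  sources the package follows; 500 bp is this package's documented
  default and must be reviewed when comparing against other WHA runs.

## Known limitations

- The built-in aligner is ungapped; indel-bearing reads only enter via
  the SAM route.
- `raw_read_count` for consensus calls is the minimum across runs
  (consistent with the intersection rule), not a pooled count.
- Control exclusion with very shallow control sequencing is permissive:
  absence of control signal may reflect absence of control reads.
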