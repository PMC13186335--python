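import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_locus, reads_at
from wha.core import (
    FilteredAlignment,
    LocusAligner,
    LocusCall,
    Read,
    WindowCoverage,
    align_and_filter,
    alignments_from_sam,
    call_locus,
    compute_window_coverage,
    consensus_call,
    parse_barcode,
    partition_reads_by_celltype,
)
from wha.loci import HervLocus


def pileup_window_means(alignments, locus_length, window_size):
    """Independent oracle: explicit per-base pile-up, then window means."""
    depth = np.zeros(locus_length)
    for a in alignments:
        depth[max(a.start_offset, 0): min(a.end_offset, locus_length)] += 1
    n = locus_length // window_size
    return depth[: n * window_size].reshape(n, window_size).mean(axis=1)


class TestAligner:
    def test_perfect_read_has_identity_100(self, rng):
        locus = random_locus(rng, 2000)
        (aln,) = align_and_filter(reads_at(locus, [300]), [locus])
        assert aln.percent_identity == 100.0
        assert aln.start_offset == 300
        assert aln.aligned_length == 100

    def test_two_substitutions_in_100bp_discarded(self, rng):
        locus = random_locus(rng, 2000)
        reads = reads_at(locus, [300], mutate_at={0: [50, 70]})
        assert align_and_filter(reads, [locus]) == []

    def test_exactly_99_percent_is_discarded(self, rng):
        # strict threshold: one substitution in a 100 bp read is 99.0%, out
        locus = random_locus(rng, 2000)
        reads = reads_at(locus, [300], mutate_at={0: [50]})
        assert align_and_filter(reads, [locus]) == []
        # ... but retained when the configured threshold is lowered below it
        (aln,) = align_and_filter(reads, [locus], identity_threshold=98.9)
        assert aln.percent_identity == pytest.approx(99.0)

    def test_reverse_complement_read_aligns(self, rng):
        locus = random_locus(rng, 2000)
        fwd = locus.sequence[400:500]
        rc = fwd[::-1].translate(str.maketrans("ACGT", "TGCA"))
        (aln,) = align_and_filter([Read("r0|BC-1", rc, "BC-1")], [locus])
        assert aln.start_offset == 400
        assert aln.percent_identity == 100.0

    def test_short_reads_skipped_with_warning(self, rng, caplog):
        locus = random_locus(rng, 2000)
        with caplog.at_level("WARNING"):
            out = align_and_filter([Read("r|b", "ACGTACGT", "b")], [locus])
        assert out == []
        assert "shorter than seed length" in caplog.text

    def test_ambiguous_read_across_identical_loci_discarded(self, rng):
        locus = random_locus(rng, 2000)
        twin = HervLocus("Chr9:1-2000", "chr9", 1, 2000, locus.sequence)
        assert align_and_filter(reads_at(locus, [500]), [locus, twin]) == []

    def test_best_identity_locus_wins(self, rng):
        locus = random_locus(rng, 2000)
        seq2 = list(locus.sequence)
        seq2[450] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq2[450]]
        near = HervLocus("Chr9:1-2000", "chr9", 1, 2000, "".join(seq2))
        (aln,) = align_and_filter(reads_at(locus, [400]), [locus, near])
        assert aln.locus_id == locus.locus_id

    def test_duplicate_locus_ids_rejected(self, rng):
        locus = random_locus(rng, 1000)
        with pytest.raises(ValueError, match="duplicate locus_ids"):
            LocusAligner([locus, locus])

    def test_overhanging_read_is_clipped(self, rng):
        locus = random_locus(rng, 1000)
        tail = locus.sequence[950:] + "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"
        (aln,) = align_and_filter([Read("r|b", tail, "b")], [locus])
        assert aln.start_offset == 950
        assert aln.aligned_length == 50
        assert aln.end_offset == 1000


class TestWindowCoverage:
    def test_no_alignments_all_zero(self, rng):
        locus = random_locus(rng, 2000)
        cov = compute_window_coverage([], locus, 500)
        assert cov.n_windows == 4
        assert not cov.depths.any()

    def test_single_alignment_spanning_one_window(self, rng):
        locus = random_locus(rng, 1000)
        aln = FilteredAlignment("r", "b", locus.locus_id, 0, 500, 500)
        cov = compute_window_coverage([aln], locus, 500)
        assert cov.depths.tolist() == [1.0, 0.0]

    def test_uniform_30x100bp_over_1000bp_gives_depth_3(self, rng):
        # 30 reads x 100 bp tiled uniformly over 1000 bp = 3 x coverage
        locus = random_locus(rng, 1000)
        alns = [
            FilteredAlignment(f"r{i}", "b", locus.locus_id, (i % 10) * 100, 100, 100)
            for i in range(30)
        ]
        cov = compute_window_coverage(alns, locus, 500)
        assert cov.depths.tolist() == [3.0, 3.0]
        oracle = pileup_window_means(alns, locus.length, 500)
        np.testing.assert_allclose(cov.depths, oracle, atol=1e-9)

    def test_matches_pileup_oracle_on_random_instances(self, rng):
        locus = random_locus(rng, 3777)
        for _ in range(20):
            wsize = int(rng.integers(100, 900))
            n = int(rng.integers(0, 120))
            alns = [
                FilteredAlignment(
                    f"r{i}", "b", locus.locus_id,
                    int(rng.integers(-20, locus.length - 10)),
                    int(rng.integers(30, 150)), 0,
                )
                for i in range(n)
            ]
            cov = compute_window_coverage(alns, locus, wsize)
            oracle = pileup_window_means(alns, locus.length, wsize)
            np.testing.assert_allclose(cov.depths, oracle, atol=1e-9)

    def test_past_end_alignment_clipped(self, rng):
        locus = random_locus(rng, 1000)
        aln = FilteredAlignment("r", "b", locus.locus_id, 950, 100, 100)
        cov = compute_window_coverage([aln], locus, 500)
        assert cov.depths.tolist() == [0.0, 0.1]  # 50 bases in [500,1000)

    def test_min_metric_reports_minimum_per_base_depth(self, rng):
        locus = random_locus(rng, 1000)
        alns = [FilteredAlignment("r", "b", locus.locus_id, 0, 499, 499)]
        mean_cov = compute_window_coverage(alns, locus, 500, metric="mean")
        min_cov = compute_window_coverage(alns, locus, 500, metric="min")
        assert mean_cov.depths[0] == pytest.approx(499 / 500)
        assert min_cov.depths[0] == 0.0  # base 499 uncovered


class TestCallLocus:
    def _cov(self, depths):
        return WindowCoverage("Chr1:1-100", "s", "CD14_Mono", "run1", np.asarray(depths, float))

    def test_nine_windows_at_threshold_depth_is_positive(self):
        call = call_locus(self._cov([3.0] * 9 + [0.0] * 7))
        assert (call.usable_windows, call.status) == (9, "positive")

    def test_eight_deep_windows_is_negative(self):
        call = call_locus(self._cov([50.0] * 8 + [0.0] * 8))
        assert (call.usable_windows, call.status) == (8, "negative")

    def test_subthreshold_depth_everywhere_is_negative(self):
        call = call_locus(self._cov([2.9] * 16))
        assert (call.usable_windows, call.status) == (0, "negative")

    @settings(deadline=None, max_examples=60)
    @given(
        depths=st.lists(st.floats(0, 100, allow_nan=False), min_size=0, max_size=30),
        extra=st.floats(0.01, 50),
        idx=st.integers(0, 29),
    )
    def test_adding_coverage_never_flips_positive_to_negative(self, depths, extra, idx):
        before = call_locus(self._cov(depths))
        bumped = list(depths)
        if bumped:
            bumped[idx % len(bumped)] += extra
        after = call_locus(self._cov(bumped))
        assert after.usable_windows >= before.usable_windows
        if before.status == "positive":
            assert after.status == "positive"


class TestConsensus:
    def _call(self, status, usable=10, key=("Chr1:1-100", "s", "CD14_Mono")):
        return LocusCall(*key, usable, status, 100)

    def test_positive_in_both_runs_is_positive(self):
        c = consensus_call([self._call("positive"), self._call("positive", usable=12)])
        assert c.status == "positive"
        assert c.usable_windows == 10  # minimum across runs

    def test_mixed_runs_negative_under_intersection(self):
        c = consensus_call([self._call("positive"), self._call("negative", usable=3)])
        assert c.status == "negative"

    def test_mixed_runs_positive_under_union(self):
        c = consensus_call([self._call("positive"), self._call("negative")], mode="union")
        assert c.status == "positive"

    def test_single_run_passes_through_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            c = consensus_call([self._call("positive")])
        assert c.status == "positive"
        assert "single run" in caplog.text

    def test_mixed_keys_rejected(self):
        with pytest.raises(ValueError, match="mixed call keys"):
            consensus_call([
                self._call("positive"),
                self._call("positive", key=("Chr2:1-100", "s", "CD14_Mono")),
            ])


class TestPartition:
    def test_all_annotated_to_one_type(self):
        reads = [Read(f"r{i}|bc{i}", "ACGT", f"bc{i}") for i in range(10)]
        bins = partition_reads_by_celltype(reads, {f"bc{i}": "CD14_Mono" for i in range(10)})
        assert set(bins) == {"CD14_Mono"}
        assert len(bins["CD14_Mono"]) == 10

    def test_unknown_barcode_goes_to_unannotated(self):
        bins = partition_reads_by_celltype([Read("r|zz", "ACGT", "zz")], {"bc": "B"})
        assert len(bins["unannotated"]) == 1

    @settings(deadline=None, max_examples=30)
    @given(
        n=st.integers(0, 60),
        annotated_frac=st.floats(0, 1),
    )
    def test_read_counts_conserved(self, n, annotated_frac):
        rng = np.random.default_rng(0)
        barcodes = [f"bc{i % 7}" for i in range(n)]
        ann = {
            f"bc{i}": ["B", "NK", "CD14_Mono"][i % 3]
            for i in range(int(7 * annotated_frac))
        }
        reads = [Read(f"r{i}|{b}", "ACGT", b) for i, b in enumerate(barcodes)]
        bins = partition_reads_by_celltype(reads, ann)
        assert sum(len(v) for v in bins.values()) == n


class TestSamIngestion:
    def _write_sam(self, path, locus, records):
        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": locus.locus_id, "LN": locus.length}],
        })
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for name, seq, pos, cigar, tags in records:
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.query_sequence = seq
                rec.reference_id = 0
                rec.reference_start = pos
                rec.cigarstring = cigar
                rec.mapping_quality = 60
                rec.flag = 0
                for tag, val in tags:
                    rec.set_tag(tag, val)
                out.write(rec)

    def test_nm_tag_identity_and_strict_filter(self, rng, tmp_path):
        locus = random_locus(rng, 2000)
        perfect = locus.sequence[100:200]
        sam = tmp_path / "x.sam"
        self._write_sam(sam, locus, [
            ("good|BC-1", perfect, 100, "100M", [("NM", 0)]),
            ("onemm|BC-1", perfect, 300, "100M", [("NM", 1)]),   # 99.0% -> out
        ])
        (aln,) = alignments_from_sam(sam, [locus])
        assert aln.read_id == "good|BC-1"
        assert aln.barcode == "BC-1"
        assert aln.start_offset == 100

    def test_identity_recomputed_without_nm(self, rng, tmp_path):
        locus = random_locus(rng, 2000)
        seq = list(locus.sequence[100:200])
        seq[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10]]
        sam = tmp_path / "x.sam"
        self._write_sam(sam, locus, [("r1", "".join(seq), 100, "100M", [])])
        out = alignments_from_sam(sam, [locus], identity_threshold=98.0)
        assert len(out) == 1
        assert out[0].percent_identity == pytest.approx(99.0)
        assert alignments_from_sam(sam, [locus]) == []  # strict >99 filter

    def test_indel_bases_count_as_mismatches(self, rng, tmp_path):
        locus = random_locus(rng, 2000)
        # 99 matching bases with a 1 bp insertion: 99/100 columns
        seq = locus.sequence[100:150] + "A" + locus.sequence[150:199]
        sam = tmp_path / "x.sam"
        self._write_sam(sam, locus, [("r1", seq, 100, "50M1I49M", [("NM", 1)])])
        out = alignments_from_sam(sam, [locus], identity_threshold=98.0)
        assert out[0].aligned_length == 100
        assert out[0].percent_identity == pytest.approx(99.0)

    def test_soft_clips_excluded_from_denominator(self, rng, tmp_path):
        locus = random_locus(rng, 2000)
        seq = "ACGTACGTAC" + locus.sequence[100:190]
        sam = tmp_path / "x.sam"
        self._write_sam(sam, locus, [("r1", seq, 100, "10S90M", [("NM", 0)])])
        (aln,) = alignments_from_sam(sam, [locus])
        assert aln.aligned_length == 90
        assert aln.percent_identity == 100.0

    def test_agrees_with_builtin_aligner(self, rng, tmp_path):
        locus = random_locus(rng, 2000)
        reads = reads_at(locus, [150, 700, 1300])
        builtin = align_and_filter(reads, [locus])
        sam = tmp_path / "x.sam"
        self._write_sam(sam, locus, [
            (r.read_id, r.sequence, p, "100M", [("NM", 0)])
            for r, p in zip(reads, [150, 700, 1300])
        ])
        from_sam = alignments_from_sam(sam, [locus])
        assert {(a.read_id, a.start_offset, a.aligned_length, a.matches) for a in builtin} == \
               {(a.read_id, a.start_offset, a.aligned_length, a.matches) for a in from_sam}


def test_parse_barcode_round_trip():
    assert parse_barcode("sample.12|AAACCTG-1") == "AAACCTG-1"
    assert parse_barcode("noseparator") is None
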