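"""The WHA statistic: identity-filtered alignment, window depth, locus calls.

Reads are aligned to the HERV locus reference and retained only above a
strict percent-identity threshold (default: strictly greater than 99%).
Each locus is tiled into equal windows; a window is *usable* when its mean
per-base read depth reaches the depth threshold (default 3), and a locus is
called *positive* when it has at least the minimum number of usable windows
(default 9) — i.e. evidence of an extended transcript rather than isolated
read pile-ups. Duplicate runs of the same sample are combined by a
conservative intersection consensus.

The built-in aligner is an exact-k-mer-seeded, ungapped seed-and-extend
aligner, sufficient for the substitution-error reads the simulator
produces; externally produced SAM records can be ingested instead, with
identity recomputed from their alignment fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from wha.io import UNANNOTATED
from wha.loci import HervLocus, Window, tile_windows  # noqa: F401  (re-exported op)

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 99.0
DEFAULT_MIN_DEPTH = 3.0
DEFAULT_MIN_USABLE_WINDOWS = 9
DEFAULT_SEED_LENGTH = 20

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


class Read(NamedTuple):
    """A sequencing read with the cell barcode carried in its name."""

    read_id: str
    sequence: str
    barcode: str | None


def encode_read_name(read_id: str, barcode: str) -> str:
    """Encode the cell barcode into a read name as ``{read_id}|{barcode}``."""
    return f"{read_id}|{barcode}"


def parse_barcode(read_name: str) -> str | None:
    """Extract the barcode from a ``{read_id}|{barcode}`` read name, else None."""
    if "|" in read_name:
        return read_name.rsplit("|", 1)[1]
    return None


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate reads from a FASTQ file, decoding barcodes from read names."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            name = title.split()[0]
            yield Read(name, seq.upper(), parse_barcode(name))


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads (barcode re-encoded into the name) as FASTQ; returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            name = r.read_id if r.barcode is None else encode_read_name(
                r.read_id.rsplit("|", 1)[0], r.barcode
            )
            fh.write(f"@{name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
            n += 1
    return n


@dataclass(frozen=True)
class FilteredAlignment:
    """A retained alignment of one read to one locus (ungapped coordinates).

    ``start_offset`` is 0-based within the locus; ``aligned_length`` excludes
    clipped bases, and ``matches`` counts identical aligned bases, so
    ``percent_identity = matches / aligned_length * 100``.
    """

    read_id: str
    barcode: str | None
    locus_id: str
    start_offset: int
    aligned_length: int
    matches: int

    @property
    def percent_identity(self) -> float:
        return self.matches / self.aligned_length * 100.0

    @property
    def end_offset(self) -> int:
        return self.start_offset + self.aligned_length


@dataclass
class WindowCoverage:
    """Per-window mean read depth for one (locus, sample, cell type, run)."""

    locus_id: str
    sample_id: str
    cell_type: str
    run_id: str
    depths: np.ndarray  # one mean per-base depth per full window

    @property
    def n_windows(self) -> int:
        return len(self.depths)


@dataclass(frozen=True)
class LocusCall:
    """Positive/negative call for one (locus, sample, cell type)."""

    locus_id: str
    sample_id: str
    cell_type: str
    usable_windows: int
    status: str  # "positive" | "negative"
    raw_read_count: int

    @property
    def is_positive(self) -> bool:
        return self.status == "positive"


class LocusAligner:
    """Exact-k-mer-seeded, ungapped seed-and-extend aligner over a locus set.

    Seeds are exact k-mers sampled from the start, middle and end of the
    read; each seed hit proposes an ungapped placement which is scored by
    direct base comparison (both strands). A read is assigned to its single
    best-identity locus; a tie between distinct loci makes the read
    ambiguous and it is discarded. Overhanging placements are clipped to the
    locus and scored over the overlap only.
    """

    def __init__(self, loci: list[HervLocus], seed_length: int = DEFAULT_SEED_LENGTH):
        ids = [loc.locus_id for loc in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("reference contains duplicate locus_ids")
        self.seed_length = seed_length
        self.loci = list(loci)
        self._seqs = [np.frombuffer(loc.sequence.encode(), dtype=np.uint8) for loc in loci]
        self._index: dict[bytes, list[tuple[int, int]]] = {}
        k = seed_length
        for li, loc in enumerate(loci):
            s = loc.sequence.encode()
            index = self._index
            for pos in range(len(s) - k + 1):
                index.setdefault(s[pos : pos + k], []).append((li, pos))

    def _candidates(self, seq: bytes) -> set[tuple[int, int]]:
        k = self.seed_length
        offsets = {0, (len(seq) - k) // 2, len(seq) - k}
        cands: set[tuple[int, int]] = set()
        for off in offsets:
            for li, pos in self._index.get(seq[off : off + k], ()):
                cands.add((li, pos - off))
        return cands

    def align(self, read: Read) -> tuple[FilteredAlignment | None, bool]:
        """Best placement of one read, or None.

        Returns (alignment, ambiguous): ``ambiguous`` is True when two
        distinct loci tie at the best identity (the read is unusable for
        locus-specific attribution).
        """
        if len(read.sequence) < self.seed_length:
            return None, False
        best: tuple[float, int, int, int, int] | None = None  # identity, li, start, alen, matches
        tied_loci: set[int] = set()
        for strand_seq in (read.sequence.encode(), read.sequence.encode().translate(_COMPLEMENT)[::-1]):
            arr = np.frombuffer(strand_seq, dtype=np.uint8)
            for li, start in sorted(self._candidates(strand_seq)):
                ref = self._seqs[li]
                lo = max(start, 0)
                hi = min(start + len(arr), len(ref))
                alen = hi - lo
                if alen < self.seed_length:
                    continue
                matches = int(np.count_nonzero(ref[lo:hi] == arr[lo - start : hi - start]))
                ident = matches / alen * 100.0
                if best is None or ident > best[0]:
                    best = (ident, li, lo, alen, matches)
                    tied_loci = {li}
                elif ident == best[0]:
                    tied_loci.add(li)
        if best is None:
            return None, False
        if len(tied_loci) > 1:
            return None, True
        ident, li, lo, alen, matches = best
        return (
            FilteredAlignment(
                read_id=read.read_id,
                barcode=read.barcode,
                locus_id=self.loci[li].locus_id,
                start_offset=lo,
                aligned_length=alen,
                matches=matches,
            ),
            False,
        )


def align_and_filter(
    reads: Iterable[Read],
    loci: list[HervLocus] | LocusAligner,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> list[FilteredAlignment]:
    """Align reads to the locus reference and keep only high-identity hits.

    A retained alignment has percent identity *strictly greater than*
    ``identity_threshold`` (default 99.0, so a 100 bp read with even one
    mismatch — 99.0% — is discarded). Reads shorter than the seed length
    are skipped with a warning; ambiguous reads (best identity tied across
    loci) are discarded and counted in the log.
    """
    aligner = loci if isinstance(loci, LocusAligner) else LocusAligner(loci, seed_length)
    retained: list[FilteredAlignment] = []
    n_total = n_short = n_ambiguous = n_unaligned = n_low_identity = 0
    for read in reads:
        n_total += 1
        if len(read.sequence) < aligner.seed_length:
            n_short += 1
            continue
        aln, ambiguous = aligner.align(read)
        if ambiguous:
            n_ambiguous += 1
        elif aln is None:
            n_unaligned += 1
        elif aln.percent_identity > identity_threshold:
            retained.append(aln)
        else:
            n_low_identity += 1
    if n_short:
        logger.warning("%d reads shorter than seed length %d skipped", n_short, aligner.seed_length)
    logger.info(
        "align_and_filter: %d reads -> %d retained (>%g%% identity), "
        "%d below threshold, %d unaligned, %d ambiguous, %d too short",
        n_total, len(retained), identity_threshold, n_low_identity,
        n_unaligned, n_ambiguous, n_short,
    )
    return retained


def _sam_identity(rec, locus_seq_by_id: dict[str, str]) -> tuple[int, int]:
    """(matches, aligned_length) for a pysam record.

    aligned_length counts alignment columns (M/=/X/I/D), excluding clips;
    every inserted or deleted base counts as a mismatch. Uses the NM tag
    when present, otherwise recomputes by comparison to the reference.
    """
    cig = rec.cigartuples or []
    # op codes: 0=M 1=I 2=D 7== 8=X 4=S 5=H
    alen = sum(n for op, n in cig if op in (0, 1, 2, 7, 8))
    if rec.has_tag("NM"):
        nm = rec.get_tag("NM")
        return alen - nm, alen
    ref = locus_seq_by_id.get(rec.reference_name)
    if ref is None:
        raise ValueError(f"SAM reference {rec.reference_name!r} not in locus set")
    q = rec.query_sequence or ""
    matches = 0
    qpos, rpos = 0, rec.reference_start
    for op, n in cig:
        if op in (0, 7, 8):  # aligned columns
            matches += sum(
                1 for i in range(n)
                if rpos + i < len(ref) and q[qpos + i].upper() == ref[rpos + i]
            )
            qpos += n
            rpos += n
        elif op == 1:  # insertion: mismatch bases
            qpos += n
        elif op == 2:  # deletion: mismatch bases
            rpos += n
        elif op == 4:  # soft clip: excluded entirely
            qpos += n
    return matches, alen


def alignments_from_sam(
    sam_path: str | Path,
    loci: list[HervLocus],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[FilteredAlignment]:
    """Ingest externally produced SAM records as identity-filtered alignments.

    Identity is recomputed from CIGAR + NM when present, else by
    re-comparison to the locus reference. Secondary/supplementary records
    are ignored; when a read has primary records on several loci the best
    identity wins and ties are discarded, matching the built-in aligner.
    Barcodes come from the CB/BC tag or the read-name encoding.
    """
    import pysam

    seq_by_id = {loc.locus_id: loc.sequence for loc in loci}
    per_read: dict[str, list[FilteredAlignment]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            matches, alen = _sam_identity(rec, seq_by_id)
            if alen <= 0:
                continue
            barcode = None
            for tag in ("CB", "BC"):
                if rec.has_tag(tag):
                    barcode = rec.get_tag(tag)
                    break
            if barcode is None:
                barcode = parse_barcode(rec.query_name)
            aln = FilteredAlignment(
                read_id=rec.query_name,
                barcode=barcode,
                locus_id=rec.reference_name,
                start_offset=rec.reference_start,
                aligned_length=alen,
                matches=matches,
            )
            per_read.setdefault(rec.query_name, []).append(aln)
    retained = []
    for alns in per_read.values():
        best = max(a.percent_identity for a in alns)
        best_alns = [a for a in alns if a.percent_identity == best]
        if len({a.locus_id for a in best_alns}) > 1:
            continue  # ambiguous across loci
        aln = best_alns[0]
        if aln.percent_identity > identity_threshold:
            retained.append(aln)
    return retained


def compute_window_coverage(
    alignments: Iterable[FilteredAlignment],
    locus: HervLocus,
    window_size: int,
    sample_id: str = "",
    cell_type: str = "",
    run_id: str = "",
    metric: str = "mean",
) -> WindowCoverage:
    """Per-window read depth from the retained alignments of one locus.

    With the default ``metric="mean"``, the depth of a window is the total
    aligned bases falling inside it divided by the window size (the mean
    per-base depth); aligned bases are attributed by interval overlap, not
    per-base pile-up. ``metric="min"`` instead reports each window's minimum
    per-base depth. Alignments extending past the locus end contribute only
    the bases inside the locus; bases in the discarded trailing partial
    window contribute nothing.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    nwin = locus.length // window_size
    if metric == "mean":
        bases = np.zeros(nwin, dtype=np.float64)
        for aln in alignments:
            if aln.locus_id != locus.locus_id:
                raise ValueError(f"alignment to {aln.locus_id} passed with locus {locus.locus_id}")
            s = max(aln.start_offset, 0)
            e = min(aln.end_offset, locus.length)
            w_first, w_last = s // window_size, min((e - 1) // window_size, nwin - 1)
            for w in range(w_first, w_last + 1):
                lo = max(s, w * window_size)
                hi = min(e, (w + 1) * window_size)
                if hi > lo:
                    bases[w] += hi - lo
        depths = bases / window_size
    elif metric == "min":
        pileup = np.zeros(locus.length, dtype=np.int64)
        for aln in alignments:
            if aln.locus_id != locus.locus_id:
                raise ValueError(f"alignment to {aln.locus_id} passed with locus {locus.locus_id}")
            pileup[max(aln.start_offset, 0) : min(aln.end_offset, locus.length)] += 1
        depths = (
            pileup[: nwin * window_size].reshape(nwin, window_size).min(axis=1).astype(np.float64)
            if nwin
            else np.zeros(0)
        )
    else:
        raise ValueError(f"unknown depth metric {metric!r}")
    return WindowCoverage(locus.locus_id, sample_id, cell_type, run_id, depths)


def call_locus(
    coverage: WindowCoverage,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_usable_windows: int = DEFAULT_MIN_USABLE_WINDOWS,
    raw_read_count: int = 0,
) -> LocusCall:
    """Classify a locus from its window depths.

    A window is usable when its depth is at least ``min_depth``; the locus
    is positive when the usable-window count is at least
    ``min_usable_windows`` (defaults 3 and 9), negative otherwise.
    """
    if min_usable_windows < 1:
        raise ValueError("min_usable_windows must be >= 1")
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    usable = int(np.count_nonzero(coverage.depths >= min_depth))
    return LocusCall(
        locus_id=coverage.locus_id,
        sample_id=coverage.sample_id,
        cell_type=coverage.cell_type,
        usable_windows=usable,
        status="positive" if usable >= min_usable_windows else "negative",
        raw_read_count=raw_read_count,
    )


def consensus_call(calls: list[LocusCall], mode: str = "intersection") -> LocusCall:
    """Combine the calls of one (locus, sample, cell type) across duplicate runs.

    ``intersection`` (default): positive only when positive in every run —
    the conservative rule. ``union``: positive when positive in any run.
    ``single``: requires exactly one call. Usable windows and the raw read
    count are reported as the minimum across runs.
    """
    if not calls:
        raise ValueError("consensus_call needs at least one run call")
    ids = {(c.locus_id, c.sample_id, c.cell_type) for c in calls}
    if len(ids) > 1:
        raise ValueError(f"mixed call keys in consensus: {sorted(ids)}")
    if mode == "single" and len(calls) != 1:
        raise ValueError(f"consensus mode 'single' with {len(calls)} runs")
    if len(calls) == 1 and mode != "single":
        logger.warning(
            "consensus over a single run for %s/%s/%s",
            calls[0].locus_id, calls[0].sample_id, calls[0].cell_type,
        )
    if mode == "intersection":
        positive = all(c.is_positive for c in calls)
    elif mode in ("union",):
        positive = any(c.is_positive for c in calls)
    elif mode == "single":
        positive = calls[0].is_positive
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    return LocusCall(
        locus_id=calls[0].locus_id,
        sample_id=calls[0].sample_id,
        cell_type=calls[0].cell_type,
        usable_windows=min(c.usable_windows for c in calls),
        status="positive" if positive else "negative",
        raw_read_count=min(c.raw_read_count for c in calls),
    )


def partition_reads_by_celltype(
    reads: Iterable[Read], annotations: dict[str, str]
) -> dict[str, list[Read]]:
    """Split reads by the cell type their barcode is annotated with.

    Reads whose barcode is missing or unannotated go to the
    ``"unannotated"`` bin; counts are conserved (every input read lands in
    exactly one bin).
    """
    bins: dict[str, list[Read]] = {}
    for read in reads:
        ct = annotations.get(read.barcode, UNANNOTATED) if read.barcode else UNANNOTATED
        bins.setdefault(ct, []).append(read)
    return bins
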