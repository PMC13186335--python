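"""HERV locus coordinate model and window tiling.

A locus is identified by its genomic interval in 1-based inclusive display
form, ``Chr{c}:{start}-{end}`` (e.g. ``Chr3:46046256-46054342``); BED input
uses the standard 0-based half-open convention and is converted on read.
Each locus is tiled into sequential, non-overlapping, equal-length windows
starting at offset 0; a trailing partial window is discarded so that every
window has the same length and per-window depth thresholds are comparable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_LOCUS_ID_RE = re.compile(
    r"^[Cc]hr(?P<chrom>[^:]+):(?P<start>[\d,]+)\s*[-–−]\s*(?P<end>[\d,]+)$"
)


def _chrom_core(chrom: str) -> str:
    """Strip a leading 'chr'/'Chr' prefix from a chromosome name."""
    if chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def format_locus_id(chrom: str, start: int, end: int) -> str:
    """Display identifier for a locus, 1-based inclusive, no thousands separators."""
    return f"Chr{_chrom_core(chrom)}:{start}-{end}"


def parse_locus_id(locus_id: str) -> tuple[str, int, int]:
    """Parse ``Chr{c}:{start}-{end}`` into (chrom, start, end), 1-based inclusive.

    Tolerates thousands-separator commas and en-dash / minus-sign range
    separators, as found in display form (``Chr3:46,046,256–46,054,342``).
    """
    m = _LOCUS_ID_RE.match(locus_id.strip())
    if m is None:
        raise ValueError(f"unparseable locus id: {locus_id!r}")
    chrom = "chr" + m.group("chrom")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return chrom, start, end


@dataclass(frozen=True)
class HervLocus:
    """One autonomous HERV locus: coordinates plus reference sequence.

    ``start``/``end`` are 1-based inclusive. The sequence length must equal
    the interval length, ``end - start + 1``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    sequence: str = field(repr=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.locus_id}: end < start")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.locus_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_bed_record(cls, chrom: str, bed_start: int, bed_end: int, sequence: str) -> "HervLocus":
        """Build from a BED interval (0-based half-open)."""
        start = bed_start + 1
        return cls(
            locus_id=format_locus_id(chrom, start, bed_end),
            chrom=chrom,
            start=start,
            end=bed_end,
            sequence=sequence.upper(),
        )


@dataclass(frozen=True)
class Window:
    """One tiling window of a locus; offsets are 0-based half-open within the locus."""

    locus_id: str
    index: int
    start_offset: int
    end_offset: int

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset


def tile_windows(locus: HervLocus, window_size: int) -> list[Window]:
    """Tile a locus into sequential non-overlapping windows of ``window_size`` bp.

    Returns floor(locus_length / window_size) full windows, contiguous from
    offset 0; the trailing partial remainder is discarded.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    n = locus.length // window_size
    return [
        Window(locus.locus_id, i, i * window_size, (i + 1) * window_size)
        for i in range(n)
    ]


def n_windows(locus_length: int, window_size: int) -> int:
    """Number of full windows a locus of the given length tiles into."""
    if window_size <= 0:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    return locus_length // window_size
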