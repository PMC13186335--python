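import numpy as np
import pytest

from wha.core import Read
from wha.loci import HervLocus, format_locus_id

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_locus(rng: np.random.Generator, length: int, chrom: str = "chr1",
                 start: int = 1_000_000) -> HervLocus:
    seq = BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    return HervLocus(
        locus_id=format_locus_id(chrom, start, start + length - 1),
        chrom=chrom, start=start, end=start + length - 1, sequence=seq,
    )


def reads_at(locus: HervLocus, positions, read_length: int = 100,
             barcode: str = "AAAACCCCGGGGTTTT-1", mutate_at=()) -> list[Read]:
    """Reads sliced from the locus at given start offsets, optionally mutated.

    ``mutate_at`` maps read index -> list of within-read positions to
    substitute (always to a different base).
    """
    mut = dict(mutate_at) if not isinstance(mutate_at, dict) else mutate_at
    out = []
    for i, pos in enumerate(positions):
        seq = list(locus.sequence[pos : pos + read_length])
        for j in mut.get(i, ()):
            seq[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[j]]
        out.append(Read(f"r{i}|{barcode}", "".join(seq), barcode))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
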