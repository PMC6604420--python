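"""Byte-frequency profiling of arbitrary byte streams.

The byte frequency distribution (BFD) — the 256-entry table of occurrence
counts of each byte value — is the only statistic the static Huffman coder
needs. It is computed over the *entire* file, preamble and header included,
so that DICOM metadata participates in (and is obfuscated by) compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ByteFrequencyTable", "DistributionStats", "compute_bfd", "distribution_stats"]


@dataclass(frozen=True)
class ByteFrequencyTable:
    """Occurrence count of each byte value 0..255 in a byte stream.

    Attributes
    ----------
    counts : numpy.ndarray
        Length-256 array of non-negative integer counts; ``counts[b]`` is
        the number of times byte value ``b`` occurs.
    total_bytes : int
        Length of the profiled input; equals ``counts.sum()``.
    """

    counts: np.ndarray = field(repr=False)
    total_bytes: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError(f"counts must have exactly 256 entries, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if int(c.sum()) != self.total_bytes:
            raise ValueError("total_bytes must equal the sum of counts")
        object.__setattr__(self, "counts", c)

    @property
    def n_symbols(self) -> int:
        """Number of byte values with nonzero frequency."""
        return int(np.count_nonzero(self.counts))

    def nonzero_items(self) -> list[tuple[int, int]]:
        """(symbol, count) pairs for all nonzero entries, in symbol order."""
        idx = np.flatnonzero(self.counts)
        return [(int(s), int(self.counts[s])) for s in idx]


@dataclass(frozen=True)
class DistributionStats:
    """Summary of how spread-out a byte distribution is.

    ``evenness`` is entropy normalised by ``log2(n_symbols)`` (1.0 for
    degenerate distributions of at most one symbol): 1.0 means all present
    byte values are equally frequent — the regime where Huffman coding
    cannot compress — while values near 0 indicate one dominant byte.
    """

    n_symbols: int
    entropy_bits_per_byte: float
    evenness: float


def compute_bfd(data: bytes | bytearray | memoryview | np.ndarray) -> ByteFrequencyTable:
    """Tally the byte frequency distribution of ``data``.

    Empty input is valid and yields an all-zero table.
    """
    arr = np.frombuffer(bytes(data), dtype=np.uint8) if not isinstance(data, np.ndarray) else data.astype(np.uint8, copy=False).ravel()
    counts = np.bincount(arr, minlength=256).astype(np.int64)
    return ByteFrequencyTable(counts=counts, total_bytes=int(arr.size))


def distribution_stats(bfd: ByteFrequencyTable) -> DistributionStats:
    """Shannon entropy (bits/byte), symbol count and evenness of a BFD.

    The empirical distribution is ``counts / total_bytes`` with the usual
    convention 0·log0 = 0. An empty table has entropy 0 and evenness 1.
    """
    n_symbols = bfd.n_symbols
    if bfd.total_bytes == 0:
        return DistributionStats(n_symbols=0, entropy_bits_per_byte=0.0, evenness=1.0)
    p = bfd.counts[bfd.counts > 0] / bfd.total_bytes
    entropy = float(-(p * np.log2(p)).sum())
    entropy = max(entropy, 0.0)  # guard tiny negative rounding
    if n_symbols <= 1:
        return DistributionStats(n_symbols=n_symbols, entropy_bits_per_byte=0.0, evenness=1.0)
    evenness = entropy / math.log2(n_symbols)
    return DistributionStats(
        n_symbols=n_symbols,
        entropy_bits_per_byte=entropy,
        evenness=min(evenness, 1.0),
    )
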