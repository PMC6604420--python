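"""Compression evaluation: ratio, space savings, per-file batch reports.

Compression ratio is original/compressed (reported "1 : r", r to 4
decimals); space savings is 100 × (1 − compressed/original) percent (2
decimals). A ratio below 1 — possible for near-uniform byte distributions —
means the compressed file is *larger* than the input. Timings are recorded
for information only: they depend on hardware and carry no analytical
weight.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import container
from .bytefreq import compute_bfd

__all__ = ["CompressionReport", "compression_ratio", "space_savings", "measure_file", "batch_report"]

REPORT_COLUMNS = [
    "file_name",
    "original_size",
    "n_symbols",
    "compress_seconds",
    "compressed_size",
    "ratio",
    "space_savings_pct",
    "decompress_seconds",
    "error",
]


@dataclass(frozen=True)
class CompressionReport:
    file_name: str
    original_size: int
    compressed_size: int
    n_symbols: int
    ratio: float
    space_savings_pct: float
    compress_seconds: float
    decompress_seconds: float


def compression_ratio(original_size: int, compressed_size: int) -> float:
    """original/compressed; > 1 means the output shrank."""
    if original_size <= 0 or compressed_size <= 0:
        raise ValueError("sizes must be positive")
    return original_size / compressed_size


def space_savings(original_size: int, compressed_size: int) -> float:
    """Percent saved: 100 × (1 − compressed/original); negative on expansion."""
    if original_size <= 0:
        raise ValueError("original size must be positive")
    return 100.0 * (1.0 - compressed_size / original_size)


def measure_file(data: bytes, file_name: str = "<memory>") -> CompressionReport:
    """Compress, verify the round trip, and report all metrics for one input."""
    t0 = time.perf_counter()
    cont = container.compress_file(data)
    blob = container.serialize(cont)
    t1 = time.perf_counter()
    restored = container.decompress_file(container.parse(blob))
    t2 = time.perf_counter()
    if restored != data:
        raise container.ContainerError(f"round trip mismatch for {file_name}")
    original_size = len(data)
    compressed_size = len(blob)
    return CompressionReport(
        file_name=file_name,
        original_size=original_size,
        compressed_size=compressed_size,
        n_symbols=compute_bfd(data).n_symbols,
        ratio=round(compression_ratio(original_size, compressed_size), 4),
        space_savings_pct=round(space_savings(original_size, compressed_size), 2),
        compress_seconds=t1 - t0,
        decompress_seconds=t2 - t1,
    )


def batch_report(files: Iterable[str | Path]) -> pd.DataFrame:
    """One metrics row per file; unreadable files get an error row.

    Columns follow the per-file result tables: name, original size, symbol
    count, compression time, compressed size, ratio, space savings,
    decompression time.
    """
    rows = []
    for path in files:
        path = Path(path)
        row = dict.fromkeys(REPORT_COLUMNS)
        row["file_name"] = path.name
        try:
            data = path.read_bytes()
            rep = measure_file(data, file_name=path.name)
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        else:
            row.update(
                original_size=rep.original_size,
                n_symbols=rep.n_symbols,
                compress_seconds=rep.compress_seconds,
                compressed_size=rep.compressed_size,
                ratio=rep.ratio,
                space_savings_pct=rep.space_savings_pct,
                decompress_seconds=rep.decompress_seconds,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
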