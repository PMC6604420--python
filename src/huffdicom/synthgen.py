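"""Deterministic synthetic inputs: raw byte streams and minimal DICOM files.

Replaces external CT archives for testing. Two byte-distribution regimes
bracket real CT behaviour: ``dominant_byte`` emulates files whose pixel data
is mostly one value (large black background — highly compressible), and
``uniform`` emulates files whose bytes spread almost evenly (dense 16-bit
noise — incompressible, compression ratio below 1). ``custom`` accepts an
explicit 256-weight vector.

Every generator is a pure function of (spec, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .bytefreq import ByteFrequencyTable

__all__ = ["SyntheticSpec", "generate_bytes", "generate_dicom", "worked_example_fixtures"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic input.

    ``kind`` is "raw" (a bare byte stream of ``size_bytes``) or "dicom" (a
    minimal part-10 file of ``rows × cols × n_frames`` samples at
    ``bits_allocated`` bits). ``distribution`` selects the byte-value law:
    "uniform", "dominant_byte" (byte 0x00 with probability
    ``dominant_fraction``, the rest uniform) or "custom" (``weights``).
    """

    kind: str = "raw"
    size_bytes: int = 0
    rows: int = 64
    cols: int = 64
    n_frames: int = 1
    bits_allocated: int = 16
    distribution: str = "dominant_byte"
    dominant_fraction: float = 0.63
    weights: Optional[Sequence[float]] = None
    seed: int = 0

    def probabilities(self) -> np.ndarray:
        """Per-byte-value probability vector implied by the distribution."""
        if self.distribution == "uniform":
            return np.full(256, 1.0 / 256.0)
        if self.distribution == "dominant_byte":
            f = self.dominant_fraction
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"dominant_fraction must be in [0, 1], got {f}")
            p = np.full(256, (1.0 - f) / 255.0)
            p[0] = f
            return p
        if self.distribution == "custom":
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (256,):
                raise ValueError("custom weights must have 256 entries")
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("custom weights must be non-negative with positive sum")
            return w / w.sum()
        raise ValueError(f"unknown distribution {self.distribution!r}")


def _draw_bytes(spec: SyntheticSpec, n: int) -> bytes:
    rng = np.random.default_rng(spec.seed)
    if n == 0:
        return b""
    return rng.choice(256, size=n, p=spec.probabilities()).astype(np.uint8).tobytes()


def generate_bytes(spec: SyntheticSpec) -> bytes:
    """Pseudorandom byte stream with the spec's distribution (kind="raw")."""
    if spec.kind != "raw":
        raise ValueError(f'generate_bytes needs kind="raw", got {spec.kind!r}')
    return _draw_bytes(spec, spec.size_bytes)


def generate_dicom(spec: SyntheticSpec) -> bytes:
    """Minimal valid part-10 DICOM stream (kind="dicom").

    Explicit-VR little-endian, CT image storage, monochrome; pixel bytes —
    the bulk of the file, as in real CTs — carry the spec's distribution
    while the small tag header is fixed overhead.
    """
    if spec.kind != "dicom":
        raise ValueError(f'generate_dicom needs kind="dicom", got {spec.kind!r}')
    if spec.rows < 1 or spec.cols < 1 or spec.n_frames < 1:
        raise ValueError("rows, cols and n_frames must be positive")
    if spec.bits_allocated not in (8, 16):
        raise ValueError(f"bits_allocated must be 8 or 16, got {spec.bits_allocated}")

    uid_entropy = [f"huffdicom-synth-{spec.seed}-{spec.rows}x{spec.cols}x{spec.n_frames}"]
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = CTImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=uid_entropy)
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.preamble = b"\x00" * 128
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = f"SYN{spec.seed:06d}"
    ds.Modality = "CT"
    ds.Rows = spec.rows
    ds.Columns = spec.cols
    ds.NumberOfFrames = spec.n_frames
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = spec.bits_allocated
    ds.BitsStored = spec.bits_allocated
    ds.HighBit = spec.bits_allocated - 1
    ds.PixelRepresentation = 0
    ds.WindowCenter = 2048 if spec.bits_allocated == 16 else 128
    ds.WindowWidth = 4096 if spec.bits_allocated == 16 else 256

    n_bytes = spec.rows * spec.cols * spec.n_frames * (spec.bits_allocated // 8)
    pixels = _draw_bytes(spec, n_bytes)
    ds.PixelData = pixels + (b"\x00" if n_bytes % 2 else b"")

    buf = io.BytesIO()
    pydicom.dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


# 80-byte hexadecimal excerpt of a part-10 file head: 16 preamble bytes,
# "DICM" at offset 16, a file-meta group-length element, then 16-bit pixel
# sample pairs trailing into zeros
_HEX_EXCERPT = (
    "00 00 00 00 00 00 00 00 00 00 00 00 00 00 00 00 "
    "44 49 43 4d 02 00 00 00 55 4c 04 00 be 00 00 00 "
    "82 04 82 04 82 04 82 04 82 04 82 04 82 04 82 04 "
    "7d 04 78 04 78 04 78 04 78 04 78 04 69 04 5a 04 "
    "5a 04 00 00 00 00 00 00 00 00 00 00 00 00 00 00"
)


def _partial_bfd(counts_by_symbol: dict[int, int]) -> ByteFrequencyTable:
    counts = np.zeros(256, dtype=np.int64)
    for sym, c in counts_by_symbol.items():
        counts[sym] = c
    return ByteFrequencyTable(counts=counts, total_bytes=int(counts.sum()))


def worked_example_fixtures() -> dict:
    """Deterministic, seed-free fixtures for the worked arithmetic examples.

    Returns a registry with:

    - ``hex_excerpt``: the 80-byte part-10 head above, as bytes.
    - ``skewed_bfd`` / ``very_skewed_bfd``: three-symbol partial BFDs of two
      CT files — counts (663477, 24806, 24489) and (698830, 14, 91) on byte
      values 0x00, 0x03, 0xFE.
    - ``assumed_lengths``: the codeword lengths {0x00: 2, 0x03: 5, 0xFE: 6}
      used with those BFDs in the weighted-bit-sum example.
    - ``equal8_stream``: 40 bytes — 8 distinct symbols, 5 occurrences each —
      the equal-frequency case where Huffman coding cannot compress.
    """
    return {
        "hex_excerpt": bytes.fromhex(_HEX_EXCERPT.replace(" ", "")),
        "skewed_bfd": _partial_bfd({0x00: 663477, 0x03: 24806, 0xFE: 24489}),
        "very_skewed_bfd": _partial_bfd({0x00: 698830, 0x03: 14, 0xFE: 91}),
        "assumed_lengths": {0x00: 2, 0x03: 5, 0xFE: 6},
        "equal8_stream": b"ABCDEFGH" * 5,
    }
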