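"""Minimal DICOM viewing support: parse, frame selection, windowing, resize.

Exists to demonstrate that a compressed-then-decompressed file is the same
usable image: parsing, window level/width mapping and resizing produce
bit-identical arrays before and after a compression round trip. Parsing is
delegated to pydicom; only native (uncompressed) transfer syntaxes are in
scope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

__all__ = ["DicomParseError", "DicomImage", "parse_dicom", "apply_window", "resize"]

# metadata tags surfaced for display, by pydicom keyword
_DISPLAY_KEYWORDS = (
    "PatientName",
    "PatientID",
    "Modality",
    "Rows",
    "Columns",
    "NumberOfFrames",
    "BitsAllocated",
    "BitsStored",
    "PixelRepresentation",
    "WindowCenter",
    "WindowWidth",
    "SOPClassUID",
    "TransferSyntaxUID",
)


class DicomParseError(ValueError):
    """Input is not a parseable part-10 DICOM file with pixel data."""


@dataclass
class DicomImage:
    """In-memory view of a DICOM image: frames plus display metadata."""

    rows: int
    cols: int
    n_frames: int
    bits_allocated: int
    pixel_frames: list[np.ndarray] = field(repr=False)
    window_center: Optional[float] = None
    window_width: Optional[float] = None
    metadata: dict[str, str] = field(default_factory=dict, repr=False)

    def frame(self, index: int) -> np.ndarray:
        if not (0 <= index < self.n_frames):
            raise IndexError(f"frame {index} out of range 0–{self.n_frames - 1}")
        return self.pixel_frames[index]


def _first_number(value) -> Optional[float]:
    # WindowCenter/Width may be multi-valued; display uses the first
    if value is None:
        return None
    if isinstance(value, (list, pydicom.multival.MultiValue)):
        value = value[0] if len(value) else None
    return None if value is None else float(value)


def parse_dicom(data: bytes) -> DicomImage:
    """Parse a part-10 DICOM byte stream with uncompressed pixel data."""
    try:
        ds = pydicom.dcmread(io.BytesIO(bytes(data)))
    except InvalidDicomError as exc:
        raise DicomParseError(f"not a part-10 DICOM stream: {exc}") from exc
    if "PixelData" not in ds:
        raise DicomParseError("DICOM stream has no pixel data")
    try:
        arr = ds.pixel_array
    except Exception as exc:  # pydicom raises several types for bad pixel data
        raise DicomParseError(f"cannot decode pixel data: {exc}") from exc

    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    rows, cols = int(ds.Rows), int(ds.Columns)
    frames = [arr[i] for i in range(n_frames)] if arr.ndim == 3 else [arr]
    if len(frames) != n_frames:
        raise DicomParseError(
            f"declared {n_frames} frames but pixel data holds {len(frames)}"
        )
    metadata: dict[str, str] = {}
    for kw in _DISPLAY_KEYWORDS:
        if kw == "TransferSyntaxUID":
            metadata[kw] = str(ds.file_meta.TransferSyntaxUID)
        elif kw in ds:
            metadata[kw] = str(ds[kw].value)
    return DicomImage(
        rows=rows,
        cols=cols,
        n_frames=n_frames,
        bits_allocated=int(ds.BitsAllocated),
        pixel_frames=frames,
        window_center=_first_number(getattr(ds, "WindowCenter", None)),
        window_width=_first_number(getattr(ds, "WindowWidth", None)),
        metadata=metadata,
    )


def apply_window(frame: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linear window level/width mapping to an 8-bit grayscale frame.

    Samples at or below center − width/2 map to 0, at or above
    center + width/2 to 255; in between the mapping is linear with
    round-half-up (the midpoint maps to 128).
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    frame = np.asarray(frame, dtype=np.float64)
    scaled = (frame - (center - width / 2.0)) / width * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def resize(frame: np.ndarray, out_rows: int, out_cols: int) -> np.ndarray:
    """Nearest-neighbor resampling to ``out_rows × out_cols``."""
    if out_rows < 1 or out_cols < 1:
        raise ValueError("target dimensions must be positive")
    frame = np.asarray(frame)
    in_rows, in_cols = frame.shape
    row_idx = (np.arange(out_rows) * in_rows) // out_rows
    col_idx = (np.arange(out_cols) * in_cols) // out_cols
    return frame[np.ix_(row_idx, col_idx)]
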