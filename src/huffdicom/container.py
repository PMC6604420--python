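"""The .huf compressed container: format, serialization, whole-file codec.

Layout (bit-exact)::

    offset  size  field
    0       4     magic "HUF1"
    4       1     format version (0x01)
    5       8     original_length, unsigned 64-bit little-endian
    13      256   canonical code lengths, one byte per symbol (0 = absent)
    269     1     padding_bits (0–7)
    270     ...   bit-packed payload

The header stores canonical code *lengths*, not the tree: together with the
canonical-code convention they fully determine the code, and they are the
smallest sound description. Byte offset 128 of the serialized form falls
inside the length table, so a compressed file never reproduces the DICOM
part-10 layout ("DICM" at offset 128) — the obfuscation property checked by
:func:`check_obfuscation`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from . import bitcodec, hufftree
from .bitcodec import CorruptionError, EncodedPayload
from .bytefreq import compute_bfd
from .hufftree import HuffmanError, kraft_sum

__all__ = [
    "MAGIC",
    "VERSION",
    "HEADER_SIZE",
    "ContainerError",
    "CompressedContainer",
    "ObfuscationReport",
    "compress_file",
    "decompress_file",
    "serialize",
    "parse",
    "check_obfuscation",
]

MAGIC = b"HUF1"
VERSION = 1
HEADER_SIZE = 4 + 1 + 8 + 256 + 1  # 270 bytes


class ContainerError(ValueError):
    """Malformed or inconsistent container bytes."""


@dataclass(frozen=True)
class CompressedContainer:
    magic: bytes
    format_version: int
    original_length: int
    code_lengths: np.ndarray = field(repr=False)
    payload: EncodedPayload

    def __post_init__(self) -> None:
        lengths = np.asarray(self.code_lengths, dtype=np.int64)
        if lengths.shape != (256,):
            raise ContainerError("code_lengths must have 256 entries")
        if (lengths < 0).any() or (lengths > 255).any():
            raise ContainerError("code lengths must fit in one unsigned byte")
        object.__setattr__(self, "code_lengths", lengths)

    def compressed_size(self) -> int:
        """Size in bytes of the serialized container."""
        return HEADER_SIZE + len(self.payload.payload_bytes)


@dataclass(frozen=True)
class ObfuscationReport:
    """Outcome of the plain-text-readability check on serialized bytes."""

    dicm_absent_at_128: bool
    uid_prefix_absent: bool

    @property
    def ok(self) -> bool:
        return self.dicm_absent_at_128 and self.uid_prefix_absent

    def __bool__(self) -> bool:
        return self.ok


def compress_file(data: bytes) -> CompressedContainer:
    """Compress a byte stream into a container.

    Pipeline: byte frequency distribution → Huffman tree → canonical code
    lengths → canonical codewords → bit-packed payload.

    Raises
    ------
    HuffmanError
        On empty input (nothing to encode).
    """
    data = bytes(data)
    if not data:
        raise HuffmanError("empty input: nothing to encode")
    bfd = compute_bfd(data)
    tree = hufftree.build_tree(bfd)
    table = hufftree.assign_codewords(tree)
    lengths = hufftree.canonical_lengths(table)
    canonical = hufftree.canonical_codewords(lengths)
    payload = bitcodec.encode_payload(data, canonical)
    return CompressedContainer(
        magic=MAGIC,
        format_version=VERSION,
        original_length=len(data),
        code_lengths=lengths,
        payload=payload,
    )


def decompress_file(container: CompressedContainer) -> bytes:
    """Restore the original byte stream from a container.

    Raises
    ------
    CorruptionError
        If the payload does not decode to exactly ``original_length`` bytes.
    """
    table = hufftree.canonical_codewords(container.code_lengths)
    lookup = bitcodec.build_lookup(table)
    return bitcodec.decode_payload(container.payload, lookup, container.original_length)


def serialize(container: CompressedContainer) -> bytes:
    lengths = container.code_lengths
    header = (
        MAGIC
        + struct.pack("<B", container.format_version)
        + struct.pack("<Q", container.original_length)
        + bytes(int(v) for v in lengths)
        + struct.pack("<B", container.payload.padding_bits)
    )
    return header + container.payload.payload_bytes


def parse(blob: bytes) -> CompressedContainer:
    """Parse serialized bytes back into a container, validating as it goes.

    Raises
    ------
    ContainerError
        Distinct messages for bad magic, unsupported version, invalid code
        lengths (Kraft violation), bad padding, or truncated payload.
    """
    blob = bytes(blob)
    if len(blob) < HEADER_SIZE:
        raise ContainerError(f"truncated header: {len(blob)} < {HEADER_SIZE} bytes")
    if blob[:4] != MAGIC:
        raise ContainerError(f"bad magic {blob[:4]!r}, expected {MAGIC!r}")
    version = blob[4]
    if version != VERSION:
        raise ContainerError(f"unsupported format version {version}")
    (original_length,) = struct.unpack("<Q", blob[5:13])
    lengths = np.frombuffer(blob[13:269], dtype=np.uint8).astype(np.int64)
    padding_bits = blob[269]
    if padding_bits > 7:
        raise ContainerError(f"padding_bits {padding_bits} out of range 0–7")
    n_present = int(np.count_nonzero(lengths))
    ks = kraft_sum(lengths)
    if ks > 1:
        raise ContainerError("invalid code lengths: Kraft inequality violated")
    if n_present >= 2 and ks != 1:
        raise ContainerError("invalid code lengths: incomplete code (Kraft sum < 1)")
    if n_present == 0 and original_length > 0:
        raise ContainerError("no code lengths but nonzero original length")
    payload_bytes = blob[HEADER_SIZE:]
    payload_bits = len(payload_bytes) * 8 - padding_bits
    if payload_bits < 0:
        raise ContainerError("truncated payload: padding exceeds payload size")
    if not payload_bytes and padding_bits:
        raise ContainerError("padding declared on empty payload")
    payload = EncodedPayload(
        payload_bytes=payload_bytes, payload_bits=payload_bits, padding_bits=padding_bits
    )
    return CompressedContainer(
        magic=MAGIC,
        format_version=version,
        original_length=original_length,
        code_lengths=lengths,
        payload=payload,
    )


def check_obfuscation(serialized: bytes) -> ObfuscationReport:
    """Check that serialized bytes no longer look like a part-10 DICOM file.

    Passes iff bytes 128–131 are not ASCII "DICM" and the DICOM UID root
    "1.2.840" does not appear verbatim in the first 1024 bytes.
    """
    serialized = bytes(serialized)
    return ObfuscationReport(
        dicm_absent_at_128=serialized[128:132] != b"DICM",
        uid_prefix_absent=b"1.2.840" not in serialized[:1024],
    )
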