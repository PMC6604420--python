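"""Bit-level encoder/decoder: codeword concatenation, padding, lookup decode.

Bit order is MSB-first within each output byte. The encoder appends zero
bits up to the next byte boundary; padding is inert at decode because the
decoder stops after emitting the recorded number of original symbols and
then checks it consumed exactly the meaningful bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bytefreq import compute_bfd
from .hufftree import CodewordTable, HuffmanError, predicted_payload_bits

__all__ = [
    "CorruptionError",
    "EncodedPayload",
    "DecodeLookup",
    "encode_payload",
    "build_lookup",
    "decode_payload",
    "decode_payload_treewalk",
]


class CorruptionError(ValueError):
    """The bitstream does not decode cleanly under the given code."""


@dataclass(frozen=True)
class EncodedPayload:
    """A byte-aligned bitstream: payload bytes plus padding accounting."""

    payload_bytes: bytes = field(repr=False)
    payload_bits: int
    padding_bits: int

    def __post_init__(self) -> None:
        if not (0 <= self.padding_bits <= 7):
            raise ValueError(f"padding_bits must be 0–7, got {self.padding_bits}")
        if len(self.payload_bytes) * 8 != self.payload_bits + self.padding_bits:
            raise ValueError("payload_bytes length inconsistent with payload_bits + padding_bits")

    def bitstring(self) -> str:
        """The meaningful bits as a '0'/'1' string (padding stripped)."""
        if not self.payload_bytes:
            return ""
        n = len(self.payload_bytes) * 8
        bits = format(int.from_bytes(self.payload_bytes, "big"), f"0{n}b")
        return bits[: self.payload_bits]


@dataclass(frozen=True)
class DecodeLookup:
    """Inverse of a CodewordTable: codeword bitstring → symbol."""

    mapping: dict[str, int]


def encode_payload(data: bytes, table: CodewordTable) -> EncodedPayload:
    """Concatenate codewords for ``data`` in input order and pad to a byte.

    Raises
    ------
    HuffmanError
        If a byte value occurring in ``data`` has no codeword.
    """
    data = bytes(data)
    if not data:
        return EncodedPayload(payload_bytes=b"", payload_bits=0, padding_bits=0)
    codes: list[str] = [""] * 256
    for sym, cw in table.entries.items():
        codes[sym] = cw
    missing = {b for b in set(data) if not codes[b]}
    if missing:
        sym = min(missing)
        raise HuffmanError(f"no codeword for byte value {sym} (0x{sym:02x}) present in input")
    bits = "".join(map(codes.__getitem__, data))
    payload_bits = len(bits)
    padding = (8 - payload_bits % 8) % 8
    padded = bits + "0" * padding
    payload = int(padded, 2).to_bytes(len(padded) // 8, "big")
    return EncodedPayload(payload_bytes=payload, payload_bits=payload_bits, padding_bits=padding)


def build_lookup(table: CodewordTable) -> DecodeLookup:
    """Invert a codeword table into the decode lookup table."""
    return DecodeLookup(mapping={cw: sym for sym, cw in table.entries.items()})


def decode_payload(payload: EncodedPayload, lookup: DecodeLookup, original_length: int) -> bytes:
    """Decode by growing a bit thread until it matches a codeword.

    Reads the meaningful bits one at a time, accumulating a thread; whenever
    the thread is a codeword in the lookup table the symbol is emitted and
    the thread resets. Decoding stops after ``original_length`` symbols and
    then requires that exactly ``payload_bits`` bits were consumed.

    Raises
    ------
    CorruptionError
        If the stream ends mid-codeword, ends before ``original_length``
        symbols are produced, or leaves meaningful bits unconsumed.
    """
    if original_length < 0:
        raise ValueError("original_length must be non-negative")
    if original_length == 0:
        return b""
    mapping = lookup.mapping
    bits = payload.bitstring()
    out = bytearray()
    thread = ""
    consumed = 0
    max_len = max(map(len, mapping), default=0)
    for i, ch in enumerate(bits):
        thread += ch
        if len(thread) > max_len:
            raise CorruptionError(f"bit thread {thread!r} matches no codeword")
        sym = mapping.get(thread)
        if sym is not None:
            out.append(sym)
            thread = ""
            if len(out) == original_length:
                consumed = i + 1
                break
    if len(out) < original_length:
        raise CorruptionError(
            f"stream exhausted after {len(out)} of {original_length} symbols"
        )
    if consumed != payload.payload_bits:
        raise CorruptionError(
            f"decoded {original_length} symbols after {consumed} bits "
            f"but payload declares {payload.payload_bits} meaningful bits"
        )
    return bytes(out)


def decode_payload_treewalk(payload: EncodedPayload, table: CodewordTable, original_length: int) -> bytes:
    """Root-to-leaf decode over an implicit binary trie of the codewords.

    Independent of the lookup-table route; used to cross-check that the two
    decoding strategies agree bit for bit.
    """
    if original_length == 0:
        return b""
    # implicit trie: dict keyed by bitstring prefix
    prefixes: set[str] = set()
    for cw in table.entries.values():
        for k in range(1, len(cw)):
            prefixes.add(cw[:k])
    leaves = {cw: sym for sym, cw in table.entries.items()}
    bits = payload.bitstring()
    out = bytearray()
    node = ""
    consumed = 0
    for i, ch in enumerate(bits):
        node += ch
        if node in leaves:
            out.append(leaves[node])
            node = ""
            if len(out) == original_length:
                consumed = i + 1
                break
        elif node not in prefixes:
            raise CorruptionError(f"bit path {node!r} falls off the prefix tree")
    if len(out) < original_length:
        raise CorruptionError(
            f"stream exhausted after {len(out)} of {original_length} symbols"
        )
    if consumed != payload.payload_bits:
        raise CorruptionError("meaningful bits left unconsumed after final symbol")
    return bytes(out)


def roundtrip_check(data: bytes, table: CodewordTable) -> bool:
    """Encode then decode ``data`` under ``table``; True iff bit-exact."""
    payload = encode_payload(data, table)
    assert payload.payload_bits == predicted_payload_bits(compute_bfd(data), table)
    return decode_payload(payload, build_lookup(table), len(data)) == data
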