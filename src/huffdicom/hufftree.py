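"""Huffman prefix-tree construction and canonical codeword machinery.

Builds the optimal prefix-free code for a byte frequency distribution by
repeated merging of the two minimum-weight nodes. Tie-breaking is fully
deterministic: candidates are ordered by (weight, lowest contained symbol
value) and the lower-ordered node becomes the left (0) child, so the same
BFD always yields the same tree and the same codeword table.

The container format does not store the tree itself; it stores per-symbol
*canonical* code lengths, from which ``canonical_codewords`` rebuilds a
decodable code. Canonical assignment orders symbols by (length, symbol
value) and hands out lexicographically increasing codewords.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .bytefreq import ByteFrequencyTable

__all__ = [
    "HuffmanError",
    "Node",
    "PrefixTree",
    "CodewordTable",
    "build_tree",
    "assign_codewords",
    "canonical_lengths",
    "canonical_codewords",
    "predicted_payload_bits",
    "kraft_sum",
]


class HuffmanError(ValueError):
    """Raised when no valid Huffman code can be built or applied."""


@dataclass
class Node:
    """A prefix-tree node: a leaf carries a symbol, an internal node two children."""

    weight: int
    symbol: Optional[int] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None
    # lowest symbol value in this subtree; deterministic tie-break key
    min_symbol: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.symbol is not None


@dataclass
class PrefixTree:
    root: Node
    leaf_count: int

    def node_count(self) -> int:
        """Total nodes; 2·leaf_count − 1 for any full binary tree."""

        def count(n: Optional[Node]) -> int:
            if n is None:
                return 0
            return 1 + count(n.left) + count(n.right)

        return count(self.root)

    def depth(self) -> int:
        def d(n: Node) -> int:
            if n.is_leaf:
                return 0
            return 1 + max(d(n.left), d(n.right))

        return d(self.root)


@dataclass(frozen=True)
class CodewordTable:
    """Map from byte value to its prefix-free codeword (a '0'/'1' string)."""

    entries: dict[int, str] = field(repr=False)
    max_length: int

    def __post_init__(self) -> None:
        if not self.entries:
            raise HuffmanError("codeword table must not be empty")
        for sym, cw in self.entries.items():
            if not (0 <= sym <= 255):
                raise HuffmanError(f"symbol {sym} out of byte range")
            if not cw or set(cw) - {"0", "1"}:
                raise HuffmanError(f"invalid codeword {cw!r} for symbol {sym}")

    def lengths(self) -> dict[int, int]:
        return {s: len(cw) for s, cw in self.entries.items()}


def build_tree(bfd: ByteFrequencyTable) -> PrefixTree:
    """Huffman tree over the nonzero symbols of ``bfd``.

    Raises
    ------
    HuffmanError
        If every count is zero (nothing to encode).
    """
    items = bfd.nonzero_items()
    if not items:
        raise HuffmanError("all-zero byte frequency table: nothing to encode")
    # heap entries keyed by (weight, min_symbol); min_symbol is unique per
    # node because subtrees partition the alphabet
    heap: list[tuple[int, int, Node]] = [
        (count, sym, Node(weight=count, symbol=sym, min_symbol=sym)) for sym, count in items
    ]
    heapq.heapify(heap)
    while len(heap) > 1:
        w1, m1, n1 = heapq.heappop(heap)
        w2, m2, n2 = heapq.heappop(heap)
        parent = Node(weight=w1 + w2, left=n1, right=n2, min_symbol=min(m1, m2))
        heapq.heappush(heap, (parent.weight, parent.min_symbol, parent))
    return PrefixTree(root=heap[0][2], leaf_count=len(items))


def assign_codewords(tree: PrefixTree) -> CodewordTable:
    """Read codewords off the tree: path from root, left = '0', right = '1'.

    A single-leaf tree yields the 1-bit codeword "0" so that every symbol
    costs at least one bit and payload length stays well defined.
    """
    entries: dict[int, str] = {}
    if tree.root.is_leaf:
        entries[tree.root.symbol] = "0"
        return CodewordTable(entries=entries, max_length=1)

    stack = [(tree.root, "")]
    while stack:
        node, prefix = stack.pop()
        if node.is_leaf:
            entries[node.symbol] = prefix
        else:
            stack.append((node.left, prefix + "0"))
            stack.append((node.right, prefix + "1"))
    return CodewordTable(entries=entries, max_length=max(len(c) for c in entries.values()))


def canonical_lengths(table: CodewordTable) -> np.ndarray:
    """Per-symbol codeword lengths as a length-256 array (0 = absent symbol)."""
    lengths = np.zeros(256, dtype=np.int64)
    for sym, cw in table.entries.items():
        lengths[sym] = len(cw)
    return lengths


def kraft_sum(lengths) -> Fraction:
    """Exact Kraft sum Σ 2^(−len) over the nonzero entries."""
    total = Fraction(0)
    for ln in np.asarray(lengths).ravel():
        if ln > 0:
            total += Fraction(1, 2 ** int(ln))
    return total


def canonical_codewords(lengths) -> CodewordTable:
    """Rebuild the canonical code determined by per-symbol lengths.

    Symbols are ordered by (length, symbol value); codewords are assigned as
    lexicographically increasing bitstrings. The result is prefix-free
    whenever the lengths satisfy the Kraft inequality.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.shape != (256,):
        raise HuffmanError(f"length array must have 256 entries, got {lengths.shape}")
    present = [(int(lengths[s]), s) for s in range(256) if lengths[s] > 0]
    if not present:
        raise HuffmanError("no symbols present in length array")
    if kraft_sum(lengths) > 1:
        raise HuffmanError("code lengths violate the Kraft inequality")
    present.sort()
    entries: dict[int, str] = {}
    code = 0
    prev_len = present[0][0]
    for ln, sym in present:
        code <<= ln - prev_len
        entries[sym] = format(code, f"0{ln}b")
        code += 1
        prev_len = ln
    return CodewordTable(entries=entries, max_length=present[-1][0])


def predicted_payload_bits(bfd: ByteFrequencyTable, table: CodewordTable) -> int:
    """Unpadded encoded bit length: Σ count(s) × len(codeword(s)).

    Raises
    ------
    HuffmanError
        If a symbol with nonzero count has no codeword.
    """
    total = 0
    for sym, count in bfd.nonzero_items():
        cw = table.entries.get(sym)
        if cw is None:
            raise HuffmanError(f"symbol {sym} occurs {count} times but has no codeword")
        total += count * len(cw)
    return total
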