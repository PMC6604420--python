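"""Huffman tree construction, codeword assignment, canonical codes, payload size."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from huffdicom.bytefreq import compute_bfd, distribution_stats
from huffdicom.hufftree import (
    CodewordTable,
    HuffmanError,
    assign_codewords,
    build_tree,
    canonical_codewords,
    canonical_lengths,
    kraft_sum,
    predicted_payload_bits,
)

from conftest import bfd_from_counts


def brute_force_min_weighted_bits(counts):
    """Minimum Σ count·length over all prefix codes (Kraft equality).

    Independent oracle: enumerate every length assignment with
    Σ 2^(−l) = 1 and take the cheapest. Feasible for ≤ 6 symbols.
    """
    k = len(counts)
    if k == 1:
        return counts[0]  # one symbol still costs one bit each
    best = None
    for lengths in itertools.product(range(1, k), repeat=k):
        if sum(Fraction(1, 2**l) for l in lengths) != 1:
            continue
        cost = sum(c * l for c, l in zip(counts, lengths))
        best = cost if best is None else min(best, cost)
    return best


class TestBuildTree:
    def test_eight_equal_symbols_balanced(self):
        tree = build_tree(bfd_from_counts({s: 5 for s in range(65, 73)}))
        table = assign_codewords(tree)
        assert tree.leaf_count == 8
        assert tree.depth() == 3
        assert all(len(cw) == 3 for cw in table.entries.values())

    def test_256_equal_symbols_depth_8(self):
        tree = build_tree(bfd_from_counts({s: 3 for s in range(256)}))
        table = assign_codewords(tree)
        assert tree.depth() == 8
        assert all(len(cw) == 8 for cw in table.entries.values())
        assert tree.node_count() == 511  # 2·256 − 1

    def test_skewed_four_symbol_depths(self):
        # frequencies {5, 2, 1, 1}: depths {1, 2, 3, 3}, weighted path length 15
        bfd = bfd_from_counts({10: 5, 20: 2, 30: 1, 40: 1})
        table = assign_codewords(build_tree(bfd))
        assert sorted(len(cw) for cw in table.entries.values()) == [1, 2, 3, 3]
        assert predicted_payload_bits(bfd, table) == 15
        assert brute_force_min_weighted_bits([5, 2, 1, 1]) == 15

    def test_all_zero_bfd_rejected(self):
        with pytest.raises(HuffmanError):
            build_tree(compute_bfd(b""))

    def test_node_count_invariant(self):
        for n in (1, 2, 3, 17, 100):
            tree = build_tree(bfd_from_counts({s: s + 1 for s in range(n)}))
            assert tree.node_count() == 2 * n - 1
            assert tree.leaf_count == n

    def test_deterministic_under_ties(self):
        bfd = bfd_from_counts({s: 1 for s in range(16)})
        t1 = assign_codewords(build_tree(bfd)).entries
        t2 = assign_codewords(build_tree(bfd)).entries
        assert t1 == t2


class TestAssignCodewords:
    def test_two_symbols(self):
        table = assign_codewords(build_tree(bfd_from_counts({7: 3, 9: 1})))
        assert sorted(table.entries.values()) == ["0", "1"]

    def test_single_symbol_one_bit(self):
        table = assign_codewords(build_tree(bfd_from_counts({0: 100})))
        assert table.entries == {0: "0"}

    def test_eight_equal_yields_all_3bit_strings(self):
        table = assign_codewords(build_tree(bfd_from_counts({s: 5 for s in range(8)})))
        assert sorted(table.entries.values()) == sorted(
            format(i, "03b") for i in range(8)
        )

    @given(st.dictionaries(st.integers(0, 255), st.integers(1, 1000), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=80)
    def test_prefix_free_kraft_and_monotone(self, freq):
        bfd = bfd_from_counts(freq)
        table = assign_codewords(build_tree(bfd))
        words = list(table.entries.values())
        # prefix-free
        for a, b in itertools.permutations(words, 2):
            assert not b.startswith(a)
        # Kraft equality for ≥ 2 symbols
        assert kraft_sum(canonical_lengths(table)) == 1
        # higher frequency never gets a longer codeword
        for s1, s2 in itertools.permutations(freq, 2):
            if freq[s1] > freq[s2]:
                assert len(table.entries[s1]) <= len(table.entries[s2])


class TestCanonicalCode:
    def test_lengths_roundtrip_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            syms = rng.choice(256, size=n, replace=False)
            bfd = bfd_from_counts({int(s): int(rng.integers(1, 500)) for s in syms})
            lengths = canonical_lengths(assign_codewords(build_tree(bfd)))
            rebuilt = canonical_codewords(lengths)
            assert (canonical_lengths(rebuilt) == lengths).all()

    def test_single_symbol_length_one(self):
        lengths = canonical_lengths(assign_codewords(build_tree(bfd_from_counts({99: 4}))))
        assert lengths[99] == 1 and lengths.sum() == 1

    def test_canonical_is_prefix_free(self):
        lengths = np.zeros(256, dtype=np.int64)
        lengths[:8] = 3
        table = canonical_codewords(lengths)
        assert sorted(table.entries.values()) == sorted(format(i, "03b") for i in range(8))

    def test_kraft_violation_rejected(self):
        lengths = np.zeros(256, dtype=np.int64)
        lengths[:3] = 1  # three 1-bit codes cannot coexist
        with pytest.raises(HuffmanError):
            canonical_codewords(lengths)


class TestPredictedPayloadBits:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({0x00: 663477, 0x03: 24806, 0xFE: 24489}, 1_597_918),
            ({0x00: 698830, 0x03: 14, 0xFE: 91}, 1_398_276),
        ],
    )
    def test_weighted_bit_sums(self, counts, expected):
        """Σ count×length for the worked three-symbol examples (lengths 2, 5, 6)."""
        table = CodewordTable(
            entries={0x00: "00", 0x03: "11110", 0xFE: "111110"}, max_length=6
        )
        assert predicted_payload_bits(bfd_from_counts(counts), table) == expected

    def test_all_zero_counts_is_zero_bits(self):
        table = CodewordTable(entries={0: "0"}, max_length=1)
        assert predicted_payload_bits(compute_bfd(b""), table) == 0

    def test_missing_codeword_raises(self):
        table = CodewordTable(entries={0: "0"}, max_length=1)
        with pytest.raises(HuffmanError, match="no codeword"):
            predicted_payload_bits(bfd_from_counts({0: 3, 5: 1}), table)

    def test_optimality_vs_exhaustive_search(self):
        """Huffman payload equals brute-force minimum on all small alphabets."""
        rng = np.random.default_rng(42)
        for k in range(2, 7):
            for _ in range(8):
                counts = [int(c) for c in rng.integers(1, 50, size=k)]
                bfd = bfd_from_counts({i * 37: c for i, c in enumerate(counts)})
                table = assign_codewords(build_tree(bfd))
                assert predicted_payload_bits(bfd, table) == brute_force_min_weighted_bits(counts)

    @given(st.binary(min_size=2, max_size=400))
    @settings(deadline=None, max_examples=80)
    def test_entropy_sandwich(self, data):
        """n·H ≤ payload bits ≤ n·(H+1) for any input with ≥ 2 distinct bytes."""
        bfd = compute_bfd(data)
        if bfd.n_symbols < 2:
            return
        table = assign_codewords(build_tree(bfd))
        bits = predicted_payload_bits(bfd, table)
        h = distribution_stats(bfd).entropy_bits_per_byte
        n = bfd.total_bytes
        assert n * h - 1e-6 <= bits <= n * (h + 1) + 1e-6

    def test_equal_frequency_limit_no_compression(self):
        # 2^k equal-frequency symbols each get a k-bit codeword: n·k bits total
        for k in (1, 2, 3, 4):
            n_sym = 2**k
            bfd = bfd_from_counts({s: 5 for s in range(n_sym)})
            table = assign_codewords(build_tree(bfd))
            assert predicted_payload_bits(bfd, table) == 5 * n_sym * k
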