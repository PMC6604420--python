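# Methods

## Model

`huffdicom` treats a DICOM part-10 file as an opaque byte stream and applies
classical static Huffman coding in two passes: one pass tallies the byte
frequency distribution (BFD), a second substitutes each byte with its
codeword. The whole file is profiled — preamble, "DICM" magic, data
elements and pixel data — so that restoration is trivially bit-exact and
the compressed artifact carries no recognizable DICOM structure. The code
is optimal among prefix codes for the measured BFD; its payload obeys the
entropy sandwich `n·H ≤ bits ≤ n·(H+1)`. No adaptive or streaming variant
is implemented: the statistic is global and the code static.

Consequences the package makes measurable rather than hides:

- **Equal-frequency limit.** If all `2^k` present symbols are equally
  frequent, every codeword has length `k` and the payload equals the
  fixed-length encoding — no compression. With all 256 byte values equally
  frequent the code is uniformly 8 bits and the container's 270-byte header
  makes the output strictly larger.
- **Ratio < 1.** Near-uniform BFDs (high-entropy 16-bit pixel noise) yield
  codewords of ≥ ~8 bits and compressed files larger than the input; the
  metrics module reports negative space savings in that case.

## Tie-breaking and determinism

The classical algorithm leaves merge order ambiguous under weight ties.
Candidates here are ordered by `(weight, lowest contained symbol value)`
and the lower-ordered node becomes the left (0) child. Lowest contained
symbol is unique per subtree (subtrees partition the alphabet), so the heap
order, the tree, and the codeword table are fully deterministic functions
of the BFD. Any other valid tie-break yields the same *length multiset*
(and hence identical compressed sizes); only the particular bit strings
differ. Published codeword tables from other implementations are therefore
comparable in lengths, not in literal bits.

## Canonical code and container format

The container does not store the tree. It stores per-symbol codeword
*lengths* (one byte each, 0 = absent symbol); the decoder rebuilds the
canonical code: symbols sorted by `(length, symbol value)` receive
lexicographically increasing codewords. The encoder uses the same canonical
codewords, so encode and decode agree by construction. Layout:

| offset | size | field |
|---|---|---|
| 0 | 4 | magic `HUF1` |
| 4 | 1 | version (0x01) |
| 5 | 8 | original length, u64 little-endian |
| 13 | 256 | canonical code lengths |
| 269 | 1 | padding bits (0–7) |
| 270 | … | MSB-first bit-packed payload |

Validation on parse: magic, version, padding range, and the exact Kraft
condition (`Σ 2^(−ℓ) = 1` for ≥ 2 symbols, `≤ 1` otherwise, computed with
rational arithmetic so that a flipped length byte anywhere in the table is
caught). Decoding stops after `original_length` symbols and then requires
that exactly `payload_bits` bits were consumed; any single-bit header
tamper therefore fails loudly instead of returning a silently wrong file.
Payload tampering decodes to wrong bytes or raises a corruption error — the
code is not error-correcting, and repair is out of scope.

Byte offset 128 of a serialized container falls inside the length table,
so the part-10 signature ("DICM" at 128) can never reappear; the
obfuscation check additionally scans the first 1024 bytes for the DICOM UID
root string `1.2.840`.

Degenerate inputs: empty input is refused at compression (nothing to
encode); a single-symbol alphabet is assigned the 1-bit codeword "0" so the
payload size stays well defined; `original_length = 0` decodes to the empty
stream without touching the payload.

## Bit-level conventions

Bits are packed MSB-first within each byte. Padding is zero bits to the
next 8-bit boundary only (never to 32-bit words); padding is inert because
decoding is terminated by symbol count, not by sentinel. Codeword lengths
are capped at 255 to fit the one-byte header field — unreachable for a
256-symbol alphabet, whose worst-case (degenerate, Fibonacci-like
frequency) depth is 255 only in theory and ≤ 255 always.

## Viewing layer

`dicomview` exists to demonstrate that a decompressed file is the same
usable image, not to be a viewer. Parsing delegates to pydicom (native,
uncompressed transfer syntaxes only). Window level/width uses the linear
mapping `clamp(round_half_up((p − (c − w/2))/w · 255), 0, 255)`, so the
window midpoint maps to 128 and values outside `c ± w/2` saturate. Resize
is nearest-neighbor (`src_index = floor(i·in/out)`), chosen because it is
deterministic and exactly testable; interpolating modes are deliberately
absent.

## Synthetic data

Real CT archives are not redistributable, so all fixtures are generated:

- **`dominant_byte`** — byte 0x00 with probability *f* (default 0.63, the
  zero-byte share observed in skewed CT files where dark background
  dominates the 16-bit pixel stream), remaining mass uniform over the other
  255 values. Entropy ≈ 4 bits/byte at the default: strongly compressible.
- **`uniform`** — all 256 values equally likely, entropy ≈ 8 bits/byte:
  incompressible, reproducing the ratio < 1 regime.
- **`custom`** — an explicit 256-weight vector.

DICOM fixtures are minimal explicit-VR little-endian part-10 files (CT
image storage, monochrome, 8- or 16-bit, 1–15 frames) whose pixel bytes
carry the prescribed distribution; the tag header is a fixed small
overhead, mirroring real files where pixel data dominates. Generators are
pure functions of (spec, seed). What synthetic fixtures do **not** emulate:
anatomical pixel correlations, modality-specific tag semantics, encapsulated
transfer syntaxes, and real files' mixture of text and binary element
values — so passing tests certify the codec's contracts (losslessness,
optimality, format soundness), not clinical compression ratios.

A small registry of seed-free worked-example inputs backs the arithmetic
tests: an 80-byte part-10 file head, two three-symbol partial BFDs with
counts (663477, 24806, 24489) and (698830, 14, 91) paired with codeword
lengths (2, 5, 6), and the 40-byte equal-frequency 8-symbol stream.

## Test and problem sizes

Property suites use randomized inputs of 1–5000 bytes (1,000 round trips in
the end-to-end suite), DICOM fixtures of 16×16 to 64×64 pixels and 1–15
frames, and 100–200 kB streams for distribution-fidelity and
expansion/shrinkage checks — sizes at which every code path (1-symbol,
skewed, near-uniform, multi-frame) is exercised and the full suite runs in
well under a minute. Optimality is verified exhaustively for alphabets of
up to 6 symbols against enumeration of all Kraft-equality length
assignments. Timing fields in reports are wall-clock and informational
only; they depend on hardware and are asserted only to be non-negative.

## Known limitations

- Pure-Python bit threading decodes at roughly a few MB/s; this is a
  reference-quality codec, not a high-throughput one.
- Compression is whole-file: the output is not a valid DICOM file until
  decompressed. Compressing only the pixel-data element inside a still-valid
  wrapper is out of scope.
- Obfuscation is not encryption; it defeats casual inspection only.
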