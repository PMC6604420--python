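# huffdicom

Lossless Huffman-coding compression for DICOM medical image files.

DICOM part-10 files — the standard output of CT, MRI and X-ray modalities —
are large, and moving them through a PACS (picture archiving and
communication system) costs storage and bandwidth. Lossy codecs shrink them
further but sacrifice pixel fidelity, which is unacceptable when the image
is the diagnostic evidence. `huffdicom` implements a static, two-pass
Huffman codec over the *entire* file byte stream: every byte of the
restored file, metadata and pixel data alike, is identical to the input. A
side effect is obfuscation — the compressed file no longer carries the
"DICM" magic at offset 128 or readable patient text, so it cannot be
casually read in a text editor.

## Method

For an input of `n` bytes with byte frequency distribution (BFD)
`f(s), s ∈ Σ ⊆ {0,…,255}`:

1. **Profile** — tally `f(s)` over the whole file.
2. **Build the prefix tree** — repeatedly merge the two minimum-weight
   nodes; ties broken by (weight, lowest contained symbol). Frequent bytes
   end near the root and receive short codewords.
3. **Assign codewords** — the root-to-leaf path (left = 0, right = 1) of
   each symbol; the code is prefix-free with Kraft sum `Σ 2^(−ℓ(s)) = 1`
   for `|Σ| ≥ 2`, and the payload size `Σ f(s)·ℓ(s)` is the minimum of any
   prefix code, sandwiched by `n·H ≤ bits ≤ n·(H+1)` for entropy `H`.
4. **Encode** — concatenate codewords MSB-first and zero-pad to the next
   byte boundary. The `.huf` container stores the original length and the
   256 canonical code lengths (270-byte header), from which the decoder
   rebuilds the code and reads the bit stream through a lookup table until
   the original byte count is restored.

Compression ratio is `original/compressed` (written `1 : r`) and space
savings is `100·(1 − compressed/original)` %. When the BFD is nearly
uniform every codeword needs ≥ 8 bits and the ratio drops below 1 — the
compressed file is *larger*; `huffdicom` reports this honestly rather than
hiding it.

## Worked example

```sh
$ huffdicom synth --kind dicom --rows 64 --cols 64 --frames 2 \
      --dist dominant:0.63 --seed 7 -o fixture.dcm
wrote 17034 bytes to fixture.dcm (256 symbols, 4.038 bits/byte)

$ huffdicom compress fixture.dcm -o fixture.huf
fixture.dcm: 17034 -> 8965 bytes (ratio 1:1.9001, savings 47.37%)

$ huffdicom verify fixture.dcm fixture.huf
round trip      : OK (17034 bytes, bit-exact)
DICM at 128     : absent
UID root in 1kB : absent
```

The synthetic CT has 63 % of its pixel bytes equal to 0x00 (a dark
background dominates, as in real CT slices), so its entropy is ≈ 4.0
bits/byte and Huffman coding halves the file (ratio 1 : 1.9001, 47.37 %
saved). `verify` decompresses the container, confirms the restored bytes
match the original bit for bit, and checks that the compressed form no
longer looks like a DICOM file. `huffdicom inspect`, `view`, `report` and
`decompress` cover the remaining workflow; a near-uniform fixture
(`--dist uniform`) demonstrates the ratio < 1 limitation.

The same operations are available as a library:

```python
import huffdicom as hd

blob = hd.serialize(hd.compress_file(open("fixture.dcm", "rb").read()))
restored = hd.decompress_file(hd.parse(blob))
```

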