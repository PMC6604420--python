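import numpy as np
import pytest

from huffdicom import SyntheticSpec, generate_dicom, worked_example_fixtures
from huffdicom.bytefreq import ByteFrequencyTable


@pytest.fixture(scope="session")
def worked():
    """Registry of the in-paper worked-example inputs."""
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def dicom_factory():
    """Factory for small synthetic part-10 DICOM byte streams."""

    def make(rows=32, cols=32, n_frames=1, bits=16, distribution="dominant_byte",
             fraction=0.63, seed=0):
        spec = SyntheticSpec(
            kind="dicom", rows=rows, cols=cols, n_frames=n_frames,
            bits_allocated=bits, distribution=distribution,
            dominant_fraction=fraction, seed=seed,
        )
        return generate_dicom(spec)

    return make


def bfd_from_counts(counts_by_symbol):
    """Build a ByteFrequencyTable from a {symbol: count} dict."""
    counts = np.zeros(256, dtype=np.int64)
    for sym, c in counts_by_symbol.items():
        counts[sym] = c
    return ByteFrequencyTable(counts=counts, total_bytes=int(counts.sum()))
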