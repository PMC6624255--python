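import numpy as np
import pytest

from pioneerscan.intervals import GenomicInterval, Peak, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_peakset(rng, n, contig="chr1", contig_len=100_000, max_width=500, label="x"):
    """Random peaks (possibly overlapping) on one contig."""
    peaks = []
    for i in range(n):
        start = int(rng.integers(0, contig_len - max_width))
        width = int(rng.integers(1, max_width))
        peaks.append(
            Peak(GenomicInterval(contig, start, start + width), width // 2,
                 float(rng.integers(0, 100)), f"{label}_{i}")
        )
    return PeakSet(peaks, label=label)


@pytest.fixture
def make_peakset(rng):
    def _make(n, **kw):
        return random_peakset(rng, n, **kw)
    return _make
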