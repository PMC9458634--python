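import numpy as np
import pytest

from ramscan import ChromSizes, GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_sizes():
    return ChromSizes({"chrT": 10_000_000})


def make_peaks(intervals, sample_id="s1", mark="H3K27ac"):
    return PeakSet(
        sample_id=sample_id,
        mark=mark,
        peaks=[GenomicInterval(c, s, e) for c, s, e in intervals],
    )
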