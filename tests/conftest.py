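import numpy as np
import pytest

from deeppeak.trace_io import ALL_CHANNELS, TraceSegment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_segment(n=2000, sample_rate=60_000.0, seed=0, stds=(0.411, 0.672, 0.715)):
    """Small five-channel segment of Gaussian baseline noise."""
    r = np.random.default_rng(seed)
    channels = {
        "scatter405": r.standard_normal(n) * stds[0],
        "scatter488": r.standard_normal(n) * stds[1],
        "scatter633": r.standard_normal(n) * stds[2],
        "gfp525": r.standard_normal(n) * 0.03,
        "red670": r.standard_normal(n) * 0.05,
    }
    return TraceSegment(channels=channels, sample_rate=sample_rate)


@pytest.fixture
def noise_segment():
    return make_segment()
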