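import numpy as np
import pytest

from murihrv import RRISeries


def make_series(intervals, start=0.0, labels=None):
    """RRISeries from a list of intervals (ms), beats starting at ``start`` s."""
    intervals = np.asarray(intervals, dtype=float)
    beat_times = start + np.cumsum(intervals) / 1000.0
    return RRISeries(intervals=intervals, beat_times=beat_times, labels=labels)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
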