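import numpy as np
import pytest

from eventconn.connectivity import BandSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def low_gamma():
    return BandSpec("low_gamma", 30.0, 55.0, window_length_s=60.0)


@pytest.fixture
def high_gamma():
    return BandSpec("high_gamma", 65.0, 95.0, window_length_s=30.0)


def brute_force_histogram(tx, ty, band):
    """O(n^2) all-pairs lag histogram used as an independent oracle."""
    T, w, N = band.T_ms, band.bin_width_ms, band.n_bins
    counts = np.zeros(N, dtype=int)
    for a in tx:
        for c in ty:
            lag = c - a
            if -T <= lag < T:
                counts[int((lag + T) // w)] += 1
    return counts
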