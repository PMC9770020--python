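import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eventconn.connectivity import (
    BandSpec,
    ConnectivityStack,
    EventTrain,
    PeriEventHistogram,
    band_spec,
    connectivity_index,
    detect_events,
    matrix_similarity,
    mean_connectivity,
    peri_event_histogram,
    shannon_entropy,
    window_connectivity_from_trains,
)
from conftest import brute_force_histogram


class TestBandSpec:
    @pytest.mark.parametrize(
        "fmin,fmax,L,T,n_bins,min_count,min_dur",
        [
            (30, 55, 60, 34, 34, 1020, 24.0),   # low gamma
            (65, 95, 30, 16, 16, 480, 6.0),     # high gamma
            (4, 8, 300, 250, 250, 7500, 1250.0),  # theta
        ],
    )
    def test_histogram_design_arithmetic(self, fmin, fmax, L, T, n_bins,
                                         min_count, min_dur):
        b = band_spec(fmin, fmax, 2.0, L, 30)
        assert b.T_ms == T
        assert b.n_bins == n_bins
        assert b.min_total_count == min_count
        assert b.min_duration_s == pytest.approx(min_dur)
        assert b.mean_event_freq_hz == pytest.approx((fmin + fmax) / 2)

    def test_theta_window_cannot_satisfy_validity_rule(self):
        theta = band_spec(4, 8, 2.0, 300, 30)
        assert not theta.window_satisfies_validity
        lg = band_spec(30, 55, 2.0, 60, 30)
        assert lg.window_satisfies_validity

    def test_non_integer_bin_count_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            band_spec(30, 55, bin_width_ms=3.0)  # 68 ms / 3 ms not integer

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            band_spec(55, 30)


class TestDetectEvents:
    def test_constant_signal_has_no_events(self):
        assert len(detect_events(np.zeros(100))) == 0

    def test_single_peak(self):
        tr = detect_events(np.array([0.0, 1.0, 0.0]), threshold=0.1)
        assert list(tr.times_ms) == [1.0]

    def test_neighbor_exceedance_is_required_on_both_sides(self):
        # the middle sample beats its right neighbour by only 0.05 < 0.1
        tr = detect_events(np.array([0.0, 1.0, 0.95, 0.0]), threshold=0.1)
        assert len(tr) == 0

    def test_sinusoid_peak_count_matches_cycle_count(self):
        t = np.arange(1000) / 1000.0
        x = 50.0 * np.sin(2 * np.pi * 40 * t)  # realistic µV amplitude
        assert len(detect_events(x, threshold=0.1)) == 40


class TestPeriEventHistogram:
    def test_coincident_events_land_in_zero_lag_bin(self, low_gamma):
        h = peri_event_histogram(EventTrain("x", [100.0]),
                                 EventTrain("y", [100.0]), low_gamma)
        assert h.total_count == 1
        zero_bin = np.searchsorted(h.bin_edges_ms, 0.0, side="right") - 1
        assert h.counts[zero_bin] == 1

    def test_symmetric_lags(self, low_gamma):
        h = peri_event_histogram(EventTrain("x", [100.0, 200.0]),
                                 EventTrain("y", [110.0, 190.0]), low_gamma)
        assert h.total_count == 2
        centers = (h.bin_edges_ms[:-1] + h.bin_edges_ms[1:]) / 2
        hit = centers[h.counts > 0]
        assert np.any((hit > 8) & (hit < 12)) and np.any((hit < -8) & (hit > -12))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed, low_gamma):
        rng = np.random.default_rng(seed)
        tx = np.sort(rng.uniform(0, 60000, rng.integers(50, 500)))
        ty = np.sort(rng.uniform(0, 60000, rng.integers(50, 500)))
        h = peri_event_histogram(EventTrain("x", tx), EventTrain("y", ty),
                                 low_gamma)
        assert np.array_equal(h.counts, brute_force_histogram(tx, ty, low_gamma))

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(offset=st.floats(-1e5, 1e5), seed=st.integers(0, 100))
    def test_invariant_under_common_time_offset(self, offset, seed):
        band = BandSpec("low_gamma", 30.0, 55.0)
        rng = np.random.default_rng(seed)
        tx = np.sort(rng.uniform(0, 10000, 60))
        ty = np.sort(rng.uniform(0, 10000, 60))
        h0 = peri_event_histogram(EventTrain("x", tx), EventTrain("y", ty), band)
        h1 = peri_event_histogram(EventTrain("x", tx + offset),
                                  EventTrain("y", ty + offset), band)
        assert np.array_equal(h0.counts, h1.counts)


class TestEntropyIndex:
    def test_single_bin_entropy_zero(self, low_gamma):
        h = PeriEventHistogram(np.eye(1, 34, 5).ravel() * 50,
                               np.arange(35, dtype=float))
        assert shannon_entropy(h) == 0.0
        assert connectivity_index(0.0, 34) == 1.0

    def test_uniform_entropy_is_log_n(self):
        h = PeriEventHistogram(np.full(34, 30), np.arange(35, dtype=float))
        assert shannon_entropy(h) == pytest.approx(math.log(34), abs=1e-12)
        assert connectivity_index(math.log(34), 34) == 0.0

    def test_two_bin_example(self):
        h = PeriEventHistogram(np.array([3, 1]), np.array([0.0, 1, 2]))
        s = shannon_entropy(h)
        assert s == pytest.approx(0.5623351446188083, abs=1e-12)
        assert connectivity_index(s, 34) == pytest.approx(0.8405338476615298,
                                                          abs=1e-10)

    def test_entropy_matches_direct_summation(self, rng):
        counts = rng.integers(0, 100, size=34)
        counts[0] = 1  # ensure non-empty
        h = PeriEventHistogram(counts, np.arange(35, dtype=float))
        p = counts[counts > 0] / counts.sum()
        assert shannon_entropy(h) == pytest.approx(-(p * np.log(p)).sum(),
                                                   abs=1e-12)

    def test_out_of_range_entropy_rejected(self):
        with pytest.raises(ValueError):
            connectivity_index(10.0, 34)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=64))
    def test_index_bounded_for_any_histogram(self, counts):
        counts = np.asarray(counts)
        if counts.sum() == 0:
            return
        h = PeriEventHistogram(counts, np.arange(counts.size + 1, dtype=float))
        hval = connectivity_index(shannon_entropy(h), counts.size)
        assert 0.0 <= hval <= 1.0


class TestWindowedConnectivity:
    def _stack(self, trains, band, n_windows):
        return window_connectivity_from_trains(trains, band, n_windows)

    def test_identical_sparse_trains_give_h_one(self, low_gamma):
        # inter-event gaps > 2T so each event pairs only with itself
        times = np.arange(500.0, 60000.0, 500.0)
        band = BandSpec("low_gamma", 30, 55, window_length_s=60,
                        min_events_per_bin=1)
        st_ = self._stack([EventTrain("a", times), EventTrain("b", times)],
                          band, 1)
        assert st_.values[0, 0, 1] == 1.0
        assert st_.valid[0, 0, 1]

    def test_slices_are_exactly_symmetric(self, rng, low_gamma):
        trains = [EventTrain(f"c{i}", np.sort(rng.uniform(0, 120000, 800)))
                  for i in range(4)]
        st_ = self._stack(trains, low_gamma, 2)
        for m in range(2):
            sl = st_.values[m]
            assert np.array_equal(sl, sl.T, equal_nan=True)
            assert np.array_equal(st_.valid[m], st_.valid[m].T)

    def test_values_bounded(self, rng, low_gamma):
        trains = [EventTrain(f"c{i}", np.sort(rng.uniform(0, 60000, 2000)))
                  for i in range(3)]
        st_ = self._stack(trains, low_gamma, 1)
        finite = st_.values[np.isfinite(st_.values)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_short_recording_rejected(self, low_gamma):
        from eventconn.connectivity import window_connectivity

        with pytest.raises(ValueError, match="full window"):
            window_connectivity(np.zeros((2, 1000)), low_gamma)


class TestMeanConnectivity:
    def _stack(self, values, valid, band):
        return ConnectivityStack(np.asarray(values, dtype=float),
                                 np.asarray(valid, dtype=bool), band)

    def test_single_window_mean_is_the_slice(self, low_gamma):
        v = np.array([[[np.nan, 0.5], [0.5, np.nan]]])
        m = mean_connectivity(self._stack(v, np.ones_like(v, bool), low_gamma))
        assert m.h[0, 1] == 0.5

    def test_mean_over_valid_windows(self, low_gamma):
        v = np.array([[[np.nan, 0.2], [0.2, np.nan]],
                      [[np.nan, 0.4], [0.4, np.nan]]])
        m = mean_connectivity(self._stack(v, np.ones_like(v, bool), low_gamma))
        assert m.h[0, 1] == pytest.approx(0.3)
        assert m.n_windows_used[0, 1] == 2

    def test_invalid_windows_excluded_not_zero_filled(self, low_gamma):
        v = np.array([[[np.nan, 0.2], [0.2, np.nan]],
                      [[np.nan, 0.8], [0.8, np.nan]]])
        valid = np.array([[[False, True], [True, False]],
                          [[False, False], [False, False]]])
        m = mean_connectivity(self._stack(v, valid, low_gamma))
        assert m.h[0, 1] == pytest.approx(0.2)
        assert m.n_windows_used[0, 1] == 1

    def test_pair_with_no_valid_windows_is_missing(self, low_gamma):
        v = np.array([[[np.nan, 0.2], [0.2, np.nan]]])
        m = mean_connectivity(self._stack(v, np.zeros_like(v, bool), low_gamma))
        assert np.isnan(m.h[0, 1])


class TestMatrixSimilarity:
    def _cm(self, h, band="low_gamma"):
        from eventconn.connectivity import ConnectivityMatrix

        return ConnectivityMatrix(h=np.asarray(h, float), band_name=band)

    def test_self_similarity_is_100(self, rng):
        h = rng.random((6, 6))
        h = (h + h.T) / 2
        assert matrix_similarity(self._cm(h), self._cm(h)) == pytest.approx(100.0)

    def test_shuffled_matrix_decorrelates(self, rng):
        n = 30
        h = rng.random((n, n))
        h = (h + h.T) / 2
        iu = np.triu_indices(n, 1)
        vals = h[iu].copy()
        rng.shuffle(vals)
        g = np.zeros_like(h)
        g[iu] = vals
        g = g + g.T
        assert abs(matrix_similarity(self._cm(h), self._cm(g))) < 25.0

    def test_split_halves_of_stationary_recording_agree(self):
        from eventconn.synth import coupled_pair_trains

        band = BandSpec("low_gamma", 30, 55, window_length_s=60,
                        min_events_per_bin=2)
        # heterogeneous coupling across 4 disjoint pairs, 240 s
        rhos = [0.8, 0.5, 0.25, 0.05]
        trains = []
        for k, rho in enumerate(rhos):
            t1, t2 = coupled_pair_trains(8.0, 240.0, rho, 0.0,
                                         np.random.default_rng(50 + k))
            trains += [EventTrain(f"a{k}", t1), EventTrain(f"b{k}", t2)]
        first = window_connectivity_from_trains(trains, band, 2)
        second = window_connectivity_from_trains(trains, band, 2,
                                                 window_start_ms=120000.0)
        sim = matrix_similarity(mean_connectivity(first),
                                mean_connectivity(second))
        assert sim > 80.0

    def test_too_few_common_pairs_rejected(self):
        h = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            matrix_similarity(self._cm(h), self._cm(h))
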