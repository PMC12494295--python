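"""Rates, binning, correlation, bursts, transients, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliasim import analysis


class TestMeanFiringRate:
    def test_simple_counts(self):
        spikes = pd.DataFrame({"cell_id": [0] * 3 + [1] * 5,
                               "time_ms": np.linspace(0, 1999, 8)})
        assert analysis.mean_firing_rate(spikes, 2, (0, 2000)) == pytest.approx(2.0)

    def test_no_spikes(self):
        assert analysis.mean_firing_rate(np.array([]), 5, (0, 1000)) == 0.0

    def test_zero_neurons_rejected(self):
        with pytest.raises(ValueError):
            analysis.mean_firing_rate(np.array([]), 0, (0, 1000))

    def test_matches_per_neuron_average_oracle(self, rng):
        trains = {i: np.sort(rng.uniform(0, 10_000, rng.integers(0, 50)))
                  for i in range(8)}
        all_times = np.concatenate(list(trains.values()))
        got = analysis.mean_firing_rate(all_times, 8, (0, 10_000))
        per_neuron = np.mean([len(t) / 10.0 for t in trains.values()])
        assert got == pytest.approx(per_neuron)


class TestBinCounts:
    def test_empty_train_all_zero(self):
        bt = analysis.bin_counts({0: np.array([])}, 10, 10, (0, 100))
        assert bt.counts.shape == (1, 10)
        assert not bt.counts.any()

    def test_left_edge_membership(self):
        bt = analysis.bin_counts({0: np.array([10.0])}, 10, 10, (0, 100))
        assert bt.counts[0, 1] == 1
        assert bt.counts[0, 0] == 0

    def test_sliding_window_counts(self):
        bt = analysis.bin_counts({0: np.array([5.0, 14.0])}, 10, 4, (0, 30))
        # bins [0,10) [4,14) [8,18) [12,22) [16,26) [20,30); the spike at
        # 14 ms is excluded from [4,14) by the half-open convention
        np.testing.assert_array_equal(bt.counts[0], [1, 1, 1, 1, 0, 0])

    def test_brute_force_oracle(self, rng):
        t = np.sort(rng.uniform(0, 5000, 400))
        width, stride = 100.0, 30.0
        bt = analysis.bin_counts({0: t}, width, stride, (0, 5000))
        for k in range(bt.counts.shape[1]):
            lo = k * stride
            assert bt.counts[0, k] == np.sum((t >= lo) & (t < lo + width))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            analysis.bin_counts({0: np.array([])}, 10, 10, (50, 50))


class TestPairwiseCorrelation:
    def test_identical_rows(self):
        x = np.tile(np.array([0, 1, 3, 2, 5]), (2, 1))
        bt = analysis.BinnedTrains(x, 10, 10, (0, 50))
        r, mean_r = analysis.pairwise_correlation(bt)
        assert r[0, 1] == pytest.approx(1.0)
        assert mean_r == pytest.approx(1.0)

    def test_anticorrelated_rows(self):
        a = np.array([0, 1, 2, 3, 4])
        bt = analysis.BinnedTrains(np.vstack([a, 4 - a]), 10, 10, (0, 50))
        r, mean_r = analysis.pairwise_correlation(bt)
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_poisson_near_zero(self, rng):
        x = rng.poisson(2.0, size=(2, 20_000))
        bt = analysis.BinnedTrains(x, 10, 10, (0, 1))
        r, _ = analysis.pairwise_correlation(bt)
        assert abs(r[0, 1]) < 3 / np.sqrt(x.shape[1])

    def test_silent_rows_excluded(self):
        x = np.array([[1, 2, 3, 4], [0, 0, 0, 0], [4, 3, 2, 1]])
        bt = analysis.BinnedTrains(x, 10, 10, (0, 40))
        r, mean_r = analysis.pairwise_correlation(bt)
        assert np.isnan(r[0, 1]) and np.isnan(r[1, 2])
        assert mean_r == pytest.approx(-1.0)  # only the (0,2) pair remains

    def test_relabel_invariance_and_bounds(self, rng):
        x = rng.poisson(1.0, size=(6, 500))
        bt = analysis.BinnedTrains(x, 10, 10, (0, 5000))
        _, m1 = analysis.pairwise_correlation(bt)
        perm = rng.permutation(6)
        bt2 = analysis.BinnedTrains(x[perm], 10, 10, (0, 5000))
        r2, m2 = analysis.pairwise_correlation(bt2)
        assert m1 == pytest.approx(m2)
        assert np.nanmax(np.abs(r2)) <= 1.0 + 1e-12


class TestDetectBursts:
    WIN = [(0.0, 10_000.0)]

    def test_gap_rule_excitatory(self):
        spikes = np.array([0.0, 500.0, 1000.0, 5000.0])
        row = analysis.detect_bursts(spikes, "exc", self.WIN,
                                     min_spikes_per_burst=1)
        np.testing.assert_array_equal(row.onsets, [0.0, 5000.0])
        np.testing.assert_array_equal(row.n_spikes, [3, 1])
        np.testing.assert_array_equal(row.durations, [1000.0, 0.0])
        row2 = analysis.detect_bursts(spikes, "exc", self.WIN,
                                      min_spikes_per_burst=2)
        np.testing.assert_array_equal(row2.onsets, [0.0])

    def test_gap_rule_inhibitory(self):
        spikes = np.array([0.0, 300.0, 800.0])
        row = analysis.detect_bursts(spikes, "inh", self.WIN,
                                     min_spikes_per_burst=1)
        np.testing.assert_array_equal(row.onsets, [0.0, 800.0])

    def test_no_sic_windows_no_bursts(self):
        row = analysis.detect_bursts(np.array([0.0, 100.0]), "exc", [],
                                     min_spikes_per_burst=1)
        assert len(row.onsets) == 0

    def test_sic_gating_window(self):
        # burst onset must fall within [onset, offset + gap]
        spikes = np.array([7000.0, 7100.0])
        row = analysis.detect_bursts(spikes, "inh", [(1000.0, 2000.0)])
        assert len(row.onsets) == 0
        row = analysis.detect_bursts(spikes, "inh", [(6800.0, 6900.0)])
        np.testing.assert_array_equal(row.onsets, [7000.0])

    def test_translation_invariance_and_idempotence(self, rng):
        spikes = np.sort(rng.uniform(0, 30_000, 40))
        wins = [(0.0, 30_000.0)]
        r1 = analysis.detect_bursts(spikes, "exc", wins)
        shift = 5000.0
        r2 = analysis.detect_bursts(spikes + shift,
                                    "exc", [(w0 + shift, w1 + shift)
                                            for w0, w1 in wins])
        np.testing.assert_allclose(r2.onsets - shift, r1.onsets)
        np.testing.assert_allclose(r2.durations, r1.durations)


class TestDetectTransients:
    def test_constant_below_threshold(self):
        t = np.arange(0, 1000, 10.0)
        row = analysis.detect_transients(t, np.full(len(t), 0.05), 0.2)
        assert len(row.onsets) == 0

    def test_square_bump(self):
        t = np.arange(0, 10_000, 10.0)
        ca = np.where((t >= 2000) & (t < 5000), 0.5, 0.05)
        row = analysis.detect_transients(t, ca, 0.2)
        assert len(row.onsets) == 1
        assert row.offsets[0] - row.onsets[0] == pytest.approx(3000.0, abs=20)
        assert row.peaks[0] == pytest.approx(0.5)

    def test_merge_close_bumps(self):
        t = np.arange(0, 10_000, 10.0)
        ca = np.where(((t >= 1000) & (t < 2000)) | ((t >= 2300) & (t < 3300)),
                      0.5, 0.05)
        row = analysis.detect_transients(t, ca, 0.2, merge_gap=500.0)
        assert len(row.onsets) == 1
        row2 = analysis.detect_transients(t, ca, 0.2, merge_gap=100.0)
        assert len(row2.onsets) == 2

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            analysis.detect_transients(np.array([0.0]), np.array([0.1]), 0.2)


class TestBurstOnsetDistance:
    def test_identical_lists(self):
        a = np.array([100.0, 5000.0, 9000.0])
        np.testing.assert_array_equal(analysis.burst_onset_distance(a, a),
                                      [0.0, 0.0, 0.0])

    def test_constant_offset(self):
        a = np.array([1000.0, 5000.0, 9000.0])
        d = analysis.burst_onset_distance(a, a + 200.0)
        np.testing.assert_allclose(d, 200.0)

    def test_empty_list(self):
        assert len(analysis.burst_onset_distance(np.array([]), np.array([1.0]))) == 0

    def test_optimal_matches_brute_force(self, rng):
        """Assignment matcher equals exhaustive minimal-cost matching."""
        for _ in range(30):
            a = np.sort(rng.uniform(0, 100, rng.integers(1, 6)))
            b = np.sort(rng.uniform(0, 100, rng.integers(1, 6)))
            got = analysis.burst_onset_distance(a, b, method="optimal")
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            best = None
            for perm in itertools.permutations(range(len(long_)), len(short)):
                dists = [abs(short[i] - long_[j]) for i, j in enumerate(perm)]
                if best is None or sum(dists) < sum(best):
                    best = dists
            # cost-ties permit different pairings; the total is unique
            assert np.sum(got) == pytest.approx(np.sum(best))
            assert len(got) == len(best)

    @given(st.floats(1.0, 400.0))
    @settings(deadline=None, max_examples=20)
    def test_greedy_equals_optimal_for_separated_bursts(self, delta):
        # offsets below half the inter-burst spacing: both matchers agree
        a = np.arange(0.0, 10_000.0, 1000.0)
        b = a + delta
        g = analysis.burst_onset_distance(a, b, method="greedy")
        o = analysis.burst_onset_distance(a, b, method="optimal")
        np.testing.assert_allclose(np.sort(g), np.sort(o))


class TestGroupContrast:
    def test_identical_samples(self):
        x = np.arange(10.0)
        d, p = analysis.group_contrast(x, x)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_support(self):
        d, _ = analysis.group_contrast(np.arange(10.0), np.arange(100.0, 110.0))
        assert d == pytest.approx(1.0)

    def test_small_sample_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.5, 2.5, 4.0, 5.0])
        d, _ = analysis.group_contrast(x, y)
        # D = sup |F_x - F_y| computed by direct enumeration
        grid = np.sort(np.concatenate([x, y]))
        fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
        fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
        assert d == pytest.approx(np.max(np.abs(fx - fy)))

    def test_bonferroni(self):
        x = np.arange(50.0)
        y = x + 5
        _, p1 = analysis.group_contrast(x, y, n_tests=1)
        _, p4 = analysis.group_contrast(x, y, n_tests=4)
        assert p4 == pytest.approx(min(1.0, 4 * p1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            analysis.group_contrast(np.array([]), np.array([1.0]))
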