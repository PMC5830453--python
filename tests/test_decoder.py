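"""Pseudo-population decoding: assembly bookkeeping, calibration, curves."""

import numpy as np
import pytest

from trapcode.decoder import (accuracy_curve, build_feature_matrix,
                              decode_pair, syllable_count_tensor)
from trapcode.metrics import TrialSet, syllable_windows
from trapcode.simulate import NeuronModel, make_call, simulate_spike_trains
from trapcode.stimuli import build_call_protocol


def _cells_from_rates(calls, rates_by_cell, n_trials=20, seed=0,
                      spont=2.0):
    """Simulate one TrialSet per stimulus per cell from per-syllable rates."""
    cells = []
    for i, rates in enumerate(rates_by_cell):
        neuron = NeuronModel(spont_rate=spont, evoked_rates=rates,
                             latency_ms=10.0, latency_jitter_sd_ms=2.0,
                             response_duration_ms=50.0)
        trains = {}
        for j, call in enumerate(calls.values()):
            sched = build_call_protocol(call, n_trials, [0], isi=1.0,
                                        seed=seed + i)
            # independent realizations per stimulus (identical parameters
            # must not mean identical spike trains)
            ts, _ = simulate_spike_trains(neuron, sched, list(calls.values()),
                                          seed=seed * 1000 + i * 17 + j)
            trains.update(ts)
        cells.append(trains)
    return cells


@pytest.fixture
def two_calls():
    return {"USV": make_call("USV", 6), "WC": make_call("WC", 6)}


@pytest.fixture
def separable_cells(two_calls):
    """Cells firing strongly to USV and not at all to WC: fully separable."""
    rates = [{"USV": np.full(6, 120.0), "WC": np.zeros(6)} for _ in range(5)]
    return _cells_from_rates(two_calls, rates, spont=0.0)


@pytest.fixture
def null_cells(two_calls):
    """Identical response statistics to both stimuli: chance decoding."""
    rates = [{"USV": np.full(6, 10.0), "WC": np.full(6, 10.0)}
             for _ in range(5)]
    return _cells_from_rates(two_calls, rates, seed=3)


class TestFeatureMatrix:
    def test_column_count_neurons_times_syllables(self, two_calls,
                                                  null_cells):
        fm = build_feature_matrix(null_cells[:3], two_calls, ("USV", "WC"),
                                  n_syllables=2, seed=0)
        assert fm.X.shape == (40, 6)
        assert np.all(fm.X >= 0)
        assert fm.X.dtype.kind in "fi" and np.allclose(fm.X, np.rint(fm.X))

    def test_balanced_classes(self, two_calls, null_cells):
        fm = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 3,
                                  seed=1)
        assert np.sum(fm.y == 0) == np.sum(fm.y == 1) == 20

    def test_seed_determinism(self, two_calls, null_cells):
        a = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 4,
                                 seed=7)
        b = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 4,
                                 seed=7)
        assert np.array_equal(a.X, b.X)

    def test_permutation_preserves_column_sums(self, two_calls, null_cells):
        fm = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 6,
                                  seed=2)
        # per-neuron per-syllable totals are invariant to trial pairing
        n_syl = fm.n_syllables
        for n in range(fm.counts_a.shape[0]):
            cols = fm.X[fm.y == 0][:, n * n_syl:(n + 1) * n_syl]
            assert np.allclose(cols.sum(axis=0), fm.counts_a[n].sum(axis=0))

    def test_short_cells_excluded_with_warning(self, two_calls):
        rates = [{"USV": np.full(6, 10.0), "WC": np.full(6, 10.0)}]
        good = _cells_from_rates(two_calls, rates, n_trials=20)
        short = _cells_from_rates(two_calls, rates, n_trials=10)
        with pytest.warns(UserWarning, match="excluded"):
            fm = build_feature_matrix(good + short, two_calls, ("USV", "WC"),
                                      2, seed=0)
        assert fm.counts_a.shape[0] == 1

    def test_too_many_syllables_rejected(self, two_calls, null_cells):
        with pytest.raises(ValueError, match="syllables"):
            build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 7,
                                 seed=0)


class TestDecodePair:
    def test_separable_classes_perfect_accuracy(self, two_calls,
                                                separable_cells):
        fm = build_feature_matrix(separable_cells, two_calls, ("USV", "WC"),
                                  3, seed=0)
        res = decode_pair(fm, n_iterations=50, seed=0)
        assert res.accuracy == 1.0

    def test_chance_level_on_null(self, two_calls, null_cells):
        fm = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 3,
                                  seed=0)
        res = decode_pair(fm, n_iterations=300, seed=1)
        assert abs(res.accuracy - 0.5) < 0.07

    def test_train_test_split_sizes(self, two_calls, null_cells):
        fm = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 1,
                                  seed=0)
        assert fm.n_trials_per_class == 20
        # 18/2 per class: scored on 4 held-out pseudo-trials -> accuracies
        # are multiples of 1/4
        res = decode_pair(fm, n_iterations=20, seed=2)
        assert np.all(np.isin(res.per_iteration, [0, 0.25, 0.5, 0.75, 1.0]))

    def test_mean_bookkeeping_and_bounds(self, two_calls, null_cells):
        fm = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 2,
                                  seed=0)
        res = decode_pair(fm, n_iterations=40, seed=3)
        assert res.accuracy == pytest.approx(np.mean(res.per_iteration))
        assert np.all((res.per_iteration >= 0) & (res.per_iteration <= 1))

    def test_determinism(self, two_calls, null_cells):
        fm = build_feature_matrix(null_cells, two_calls, ("USV", "WC"), 2,
                                  seed=0)
        a = decode_pair(fm, n_iterations=30, seed=9)
        b = decode_pair(fm, n_iterations=30, seed=9)
        assert np.array_equal(a.per_iteration, b.per_iteration)


class TestAccuracyCurve:
    def test_full_design_emits_all_curves(self, two_calls):
        calls = {n: make_call(n, 6) for n in ["USV", "A", "B", "C", "D", "E"]}
        rates = [{n: np.clip(np.random.default_rng(i * 10 + j).normal(15, 5, 6),
                             0, None) for j, n in enumerate(calls)}
                 for i in range(3)]
        pops = {"TRAP": _cells_from_rates(calls, rates, seed=0),
                "nonTRAP": _cells_from_rates(calls, rates, seed=50)}
        curves, diffs = accuracy_curve(pops, calls, "USV",
                                       ["A", "B", "C", "D", "E"],
                                       n_syllables_range=[1, 2],
                                       n_iterations=10, seed=0)
        assert len(curves) == 10  # 2 populations x 5 comparisons
        assert all(len(c.accuracy) == 2 for c in curves)
        assert len(diffs) == 5

    def test_curve_truncated_at_syllable_count(self):
        calls = {"USV": make_call("USV", 6), "short": make_call("short", 4)}
        rates = [{"USV": np.full(6, 20.0), "short": np.full(4, 5.0)}
                 for _ in range(3)]
        pops = {"p": _cells_from_rates(calls, rates)}
        curves, _ = accuracy_curve(pops, calls, "USV", ["short"],
                                   n_syllables_range=[1, 2, 3, 4, 5, 6],
                                   n_iterations=5, seed=0)
        assert list(curves[0].n_syllables) == [1, 2, 3, 4]

    def test_identical_populations_near_zero_difference(self, two_calls):
        rates = [{"USV": np.full(6, 12.0), "WC": np.full(6, 12.0)}
                 for _ in range(4)]
        pops = {"TRAP": _cells_from_rates(two_calls, rates, seed=1),
                "nonTRAP": _cells_from_rates(two_calls, rates, seed=2)}
        _, diffs = accuracy_curve(pops, two_calls, "USV", ["WC"],
                                  n_syllables_range=[1, 3, 6],
                                  n_iterations=150, seed=4)
        assert np.all(np.abs(diffs[("USV", "WC")]) < 0.1)
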