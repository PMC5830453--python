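"""Response metrics: PSTH, rates, FWHM windows, significance, tuning, groups."""

import numpy as np
import pytest

from trapcode.metrics import (FRA, PSTH, ResponseWindow, TrialSet,
                              align_trials, best_frequency,
                              characteristic_frequency, compute_fra,
                              compute_psth, evoked_rate_syllables,
                              exclude_nonresponsive, fwhm_window,
                              group_comparison, NeuronProfile,
                              response_latency, spontaneous_rate,
                              spontaneous_rate_per_trial,
                              syllable_significance, syllable_windows)
from trapcode.simulate import NeuronModel, make_call, simulate_spike_trains
from trapcode.stimuli import build_call_protocol, CallStimulus, Syllable


def _trialset(trials, pre=1000.0, dur=3000.0, post=500.0):
    return TrialSet(trials=[np.asarray(t, dtype=float) for t in trials],
                    pre_ms=pre, post_ms=post, stimulus_duration_ms=dur)


class TestPSTH:
    def test_single_bin_accumulates_over_trials(self):
        ts = _trialset([[10.0]] * 60)
        psth = compute_psth(ts)
        idx = int(10 - psth.t_start_ms)
        assert psth.counts[idx] == 60
        assert psth.counts.sum() == 60

    def test_empty_trials_all_zero(self):
        psth = compute_psth(_trialset([[], [], []]))
        assert psth.counts.sum() == 0

    def test_conservation_random_spikes(self, rng):
        trials = [np.sort(rng.uniform(-1000, 3500, size=rng.integers(0, 40)))
                  for _ in range(30)]
        psth = compute_psth(_trialset(trials))
        n_in_range = sum(np.sum((t >= -1000) & (t < 3500)) for t in trials)
        assert psth.counts.sum() == n_in_range


class TestSpontaneousRate:
    def test_hand_example_natural(self):
        # 4 spikes inside the 800 ms pre-window of a single trial -> 5 sp/s
        ts = _trialset([[-900.0, -700.0, -500.0, -300.0]])
        assert spontaneous_rate(ts, "natural") == pytest.approx(5.0)

    def test_spikes_outside_window_ignored(self):
        # the -1000..-200 ms convention: spikes in the last 200 ms don't count
        ts = _trialset([[-100.0, -50.0]])
        assert spontaneous_rate(ts, "natural") == 0.0

    def test_tone_window(self):
        ts = _trialset([[-50.0], [-20.0]], pre=100.0, dur=100.0)
        # 1 spike per 100 ms window per trial -> 10 sp/s
        assert spontaneous_rate(ts, "tone") == pytest.approx(10.0)

    def test_insufficient_pre_window_raises(self):
        ts = _trialset([[0.0]], pre=300.0)
        with pytest.raises(ValueError, match="1000"):
            spontaneous_rate(ts, "natural")

    def test_poisson_recovery_within_3se(self, usv_call):
        lam = 5.0
        neuron = NeuronModel(spont_rate=lam)
        sched = build_call_protocol(usv_call, 60, [0], isi=1.0, seed=2)
        trains, _ = simulate_spike_trains(neuron, sched, [usv_call], seed=17)
        est = spontaneous_rate(trains["USV"], "natural")
        se = np.sqrt(lam / (0.8 * 60))  # Poisson SE over 60 x 0.8 s
        assert abs(est - lam) < 3 * se


class TestEvokedRates:
    def test_fixed_window_hand_example(self, usv_call):
        # 5 spikes in the first 100 ms window, single trial -> 50 sp/s
        on0 = usv_call.syllables[0].onset * 1000
        ts = _trialset([[on0 + 5, on0 + 20, on0 + 40, on0 + 60, on0 + 80]])
        rates, mean = evoked_rate_syllables(ts, usv_call, "fixed-100")
        assert rates[0] == pytest.approx(50.0)
        assert np.all(rates[1:] == 0)

    def test_length_capped_rule_uses_syllable_length(self):
        call = CallStimulus("long", [Syllable(0.0, 0.15)], 3.0)
        ts = _trialset([[10.0, 30.0, 50.0, 70.0, 100.0, 140.0]])
        rates, _ = evoked_rate_syllables(ts, call, "syllable-length")
        assert rates[0] == pytest.approx(6 / 0.15)  # 40 sp/s

    def test_mean_over_syllables(self):
        call = make_call("c", 3, syllable_duration=0.08, gap=0.15)
        wins = syllable_windows(call, "fixed-100")
        trials = [[wins[0].start_ms + 10] * 1
                  + [wins[1].start_ms + 10] * 2
                  + [wins[2].start_ms + 10] * 3]
        ts = _trialset([np.sort(trials[0])])
        rates, mean = evoked_rate_syllables(ts, call, "fixed-100")
        assert np.allclose(rates, [10.0, 20.0, 30.0])
        assert mean == pytest.approx(20.0)

    def test_overlapping_windows_truncated_with_warning(self):
        call = CallStimulus("tight", [Syllable(0.0, 0.05), Syllable(0.06, 0.05)],
                            3.0)
        with pytest.warns(UserWarning, match="truncated"):
            wins = syllable_windows(call, "fixed-100")
        assert wins[0].end_ms == pytest.approx(60.0)


class TestFWHM:
    def test_triangular_psth_half_width(self):
        # triangle: base 40 ms centered at 50 ms, baseline 0
        t = np.arange(-100, 200)
        counts = np.clip(20 - np.abs(t - 50), 0, None) / 2.0
        counts[t < 30] = 0
        counts[t > 70] = 0
        psth = PSTH(counts=counts, t_start_ms=-100, n_trials=1)
        win = fwhm_window(psth, smoothing_sd=0.0)
        # half-max crossings at 40 and 60 ms (right edge half-open)
        assert win.start_ms == 40.0
        assert win.end_ms == 61.0
        assert abs((win.start_ms + win.end_ms) / 2 - 50.0) <= 1.0

    def test_rectangular_pulse_extent(self):
        t = np.arange(-100, 200)
        counts = np.where((t >= 20) & (t < 50), 8.0, 0.0)
        psth = PSTH(counts=counts, t_start_ms=-100, n_trials=1)
        win = fwhm_window(psth, smoothing_sd=0.0)
        assert win.start_ms == 20.0 and win.end_ms == 50.0

    def test_two_equal_peaks_single_spanning_window(self):
        # rule applied by hand: first left crossing 10, last right crossing 80
        t = np.arange(-50, 150)
        counts = np.zeros_like(t, dtype=float)
        counts[(t >= 10) & (t < 20)] = 10.0
        counts[(t >= 70) & (t < 80)] = 10.0
        psth = PSTH(counts=counts, t_start_ms=-50, n_trials=1)
        win = fwhm_window(psth, smoothing_sd=0.0)
        assert win.start_ms == 10.0 and win.end_ms == 80.0

    def test_flat_psth_raises(self):
        psth = PSTH(counts=np.full(200, 3.0), t_start_ms=-100, n_trials=1)
        with pytest.raises(ValueError, match="flat|no response"):
            fwhm_window(psth, smoothing_sd=0.0)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 17.0])
    def test_scale_invariance(self, scale):
        t = np.arange(-100, 200)
        counts = np.clip(20 - np.abs(t - 50), 0, None).astype(float)
        a = fwhm_window(PSTH(counts, -100, 1), smoothing_sd=3.0)
        b = fwhm_window(PSTH(counts * scale, -100, 1), smoothing_sd=3.0)
        assert (a.start_ms, a.end_ms) == (b.start_ms, b.end_ms)


class TestSignificance:
    def test_strong_response_flagged(self):
        trials = [np.arange(10.0, 110.0, 10.0)] * 60  # 10 spikes in window
        ts = _trialset(trials)
        win = ResponseWindow(0.0, 100.0, "FWHM")
        p, flag = syllable_significance(ts, win, np.zeros(60))
        assert p < 0.001 and flag

    def test_identical_distributions_not_flagged(self):
        ts = _trialset([[50.0]] * 20)
        win = ResponseWindow(0.0, 100.0, "FWHM")
        # spontaneous also 10 sp/s per trial
        p, flag = syllable_significance(ts, win, np.full(20, 10.0))
        assert not flag

    def test_min_trials(self):
        ts = _trialset([[50.0]])
        with pytest.raises(ValueError):
            syllable_significance(ts, ResponseWindow(0, 100), np.array([0.0]))


class TestTuning:
    def _fra(self, mat, freqs=None, levels=None):
        mat = np.asarray(mat, dtype=float)
        freqs = freqs if freqs is not None else 1000.0 * (
            2 ** np.arange(mat.shape[1]))
        levels = levels if levels is not None else np.arange(mat.shape[0])
        norm = mat / mat.max() if mat.max() > 0 else None
        return FRA(freqs_hz=np.asarray(freqs, dtype=float),
                   levels_db=np.asarray(levels, dtype=float),
                   matrix=mat, normalized=norm)

    def test_bf_unique_maximum(self):
        fra = self._fra([[0, 1, 0], [0, 5, 2]], freqs=[4000, 12000, 24000])
        assert best_frequency(fra) == 12000

    def test_cf_level_average(self):
        fra = self._fra([[3, 0], [3, 5]], freqs=[8000, 16000])
        # column means: 3.0 vs 2.5 -> 8 kHz
        assert characteristic_frequency(fra) == 8000

    def test_ties_resolve_to_lowest_frequency(self):
        fra = self._fra([[5, 5]], freqs=[4000, 8000])
        assert best_frequency(fra) == 4000
        assert characteristic_frequency(fra) == 4000

    def test_all_zero_fra_raises(self):
        fra = self._fra([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            best_frequency(fra)

    def test_bf_cf_brute_force_oracle(self, rng):
        for _ in range(300):
            mat = rng.random((4, 8))
            freqs = np.sort(rng.choice(np.arange(3000, 80000, 500), 8,
                                       replace=False)).astype(float)
            fra = self._fra(mat, freqs=freqs)
            assert best_frequency(fra) == freqs[
                np.unravel_index(np.argmax(mat), mat.shape)[1]]
            assert characteristic_frequency(fra) == freqs[
                np.argmax(mat.mean(axis=0))]

    def test_latency_peak_and_2sd(self):
        t = np.arange(-100, 200)
        counts = np.zeros_like(t, dtype=float)
        counts[t == 18] = 30.0
        psth = PSTH(counts=counts, t_start_ms=-100, n_trials=1)
        assert response_latency(psth, smoothing_sd=0.0) == 18.0
        assert response_latency(psth, smoothing_sd=0.0, method="2sd") == 18.0

    def test_latency_brute_force_oracle(self, rng):
        for _ in range(300):
            counts = rng.poisson(2.0, size=300).astype(float)
            counts[120 + rng.integers(0, 50)] += 40
            psth = PSTH(counts=counts, t_start_ms=-100, n_trials=1)
            lat = response_latency(psth, smoothing_sd=0.0)
            post = counts[100:]
            assert lat == float(np.argmax(post))  # earliest max, onset at 0

    def test_compute_fra_mean_over_reps(self):
        win = ResponseWindow(0.0, 100.0)
        tone_trials = {}
        for f in (4000.0, 8000.0):
            for lv in (48.0, 78.0):
                n_spk = 3 if f == 8000.0 and lv == 78.0 else 1
                trials = [np.linspace(5, 95, n_spk) for _ in range(12)]
                tone_trials[(f, lv)] = TrialSet(trials, pre_ms=100.0,
                                                post_ms=0.0,
                                                stimulus_duration_ms=100.0)
        fra = compute_fra(tone_trials, win)
        assert fra.matrix.shape == (2, 2)
        assert fra.normalized.max() == 1.0
        assert np.sum(fra.normalized == 1.0) == 1
        assert best_frequency(fra) == 8000.0


class TestExclusionAndGroups:
    def _profile(self, nid, group, flags):
        p = NeuronProfile(neuron_id=nid, group=group)
        p.syllable_flags = {"USV": np.array(flags)}
        return p

    def test_exclusion_arithmetic(self):
        profiles = ([self._profile(f"t{i}", "TRAP", [True, False])
                     for i in range(16)]
                    + [self._profile(f"n{i}", "nonTRAP", [False, False])
                       for i in range(3)]
                    + [self._profile(f"m{i}", "nonTRAP", [False, True])
                       for i in range(16)])
        retained, report = exclude_nonresponsive(profiles)
        assert report["n_input"] == 35
        assert report["n_retained"] == 32
        assert report["excluded_by_group"] == {"nonTRAP": 3}

    def test_single_flag_retains(self):
        p = self._profile("a", "TRAP", [False] * 12 + [True])
        retained, _ = exclude_nonresponsive([p])
        assert retained == [p]

    def test_identical_groups_no_pairwise(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]}
        res = group_comparison(g)
        assert res["omnibus_p"] > 0.9
        assert res["pairwise_p"] == {}

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)  # 5 SD shift
        res = group_comparison({"a": a, "b": b})
        assert res["omnibus_p"] < 0.001
        assert res["pairwise_p"][("a", "b")] < 0.001

    def test_only_shifted_group_pairwise_significant(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        c = rng.normal(4, 1, 30)
        res = group_comparison({"a": a, "b": b, "c": c})
        assert res["pairwise_p"][("a", "c")] < 0.001
        assert res["pairwise_p"][("b", "c")] < 0.001
        assert res["pairwise_p"][("a", "b")] > 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison({"a": [1.0], "b": [1.0, 2.0]})


class TestAlignment:
    def test_align_trials_re_references_onsets(self, usv_call):
        sched = build_call_protocol(usv_call, 3, [0], isi=1.0, seed=0)
        onsets_ms = [e.onset * 1000 for e in sched.events]
        spikes = np.array([o + 25.0 for o in onsets_ms])
        ts = align_trials(spikes, sched, "USV", pre_ms=1000, post_ms=500)
        assert ts.n_trials == 3
        for trial in ts.trials:
            assert np.allclose(trial, [25.0])
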