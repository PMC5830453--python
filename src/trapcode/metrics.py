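"""Per-neuron response statistics.

Everything downstream of spike times lives here: peri-stimulus time
histograms at 1 ms resolution, spontaneous and syllable-evoked firing rates,
the full-width-half-maximum (FWHM) response window, per-syllable rank-sum
significance, frequency-response-area (FRA) tuning metrics (best frequency,
characteristic frequency, latency), the responsiveness inclusion filter for
population analyses, and nonparametric group comparisons.

Time conventions: stimulus onset is 0 ms; windows are half-open ``[a, b)``
in milliseconds; spike times are integers (nearest ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .stimuli import CallStimulus, StimSchedule

__all__ = [
    "TrialSet", "PSTH", "ResponseWindow", "NeuronProfile", "FRA",
    "align_trials", "compute_psth", "spontaneous_rate",
    "spontaneous_rate_per_trial", "evoked_rate_syllables",
    "syllable_windows", "per_trial_window_rates", "matched_spont_rates",
    "fwhm_window",
    "syllable_significance", "compute_fra", "best_frequency",
    "characteristic_frequency", "response_latency",
    "exclude_nonresponsive", "group_comparison",
]

# pre-stimulus segment used for the natural-call spontaneous rate:
# the 800 ms from -1000 to -200 ms before each presentation
NATURAL_SPONT_WINDOW_MS = (-1000.0, -200.0)
TONE_SPONT_WINDOW_MS = (-100.0, 0.0)


@dataclass
class TrialSet:
    """Spike times per trial, in ms relative to stimulus onset."""

    trials: list[np.ndarray]
    stimulus_id: str = ""
    level: float = 0.0
    pre_ms: float = 0.0
    post_ms: float = 0.0
    stimulus_duration_ms: float = 0.0

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("TrialSet requires at least one trial")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def t_max(self) -> float:
        return self.stimulus_duration_ms + self.post_ms


@dataclass
class PSTH:
    """1-ms-binned spike counts summed over trials, origin at stimulus onset."""

    counts: np.ndarray
    t_start_ms: float
    n_trials: int
    bin_ms: float = 1.0
    smoothing_sd_ms: float | None = None

    @property
    def t(self) -> np.ndarray:
        """Left edge of each bin, ms."""
        return self.t_start_ms + np.arange(len(self.counts)) * self.bin_ms

    def rate(self) -> np.ndarray:
        """Mean firing rate per bin across trials, spikes/s."""
        return self.counts / self.n_trials / (self.bin_ms / 1000.0)

    def smoothed(self, sd_ms: float = 5.0) -> "PSTH":
        """Gaussian-smoothed copy (kernel SD recorded in the result)."""
        if sd_ms <= 0:
            sm = self.counts.astype(float)
        else:
            sm = ndimage.gaussian_filter1d(self.counts.astype(float),
                                           sigma=sd_ms / self.bin_ms)
        return PSTH(counts=sm, t_start_ms=self.t_start_ms,
                    n_trials=self.n_trials, bin_ms=self.bin_ms,
                    smoothing_sd_ms=sd_ms)


@dataclass(frozen=True)
class ResponseWindow:
    """Half-open response window [start, end) in ms."""

    start_ms: float
    end_ms: float
    rule: str = "fixed-100"

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("window end must exceed start")

    @property
    def width_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class FRA:
    """Frequency-response area: mean evoked rate per (frequency, level)."""

    freqs_hz: np.ndarray
    levels_db: np.ndarray
    matrix: np.ndarray  # levels x freqs, spikes/s
    normalized: np.ndarray | None = None  # matrix / max, None if all-zero


@dataclass
class NeuronProfile:
    """The per-cell summary the population analyses consume."""

    neuron_id: str
    spont_rate: float = np.nan
    evoked_rate: float = np.nan  # mean over syllables
    latency_ms: float = np.nan
    bf_hz: float = np.nan
    cf_hz: float = np.nan
    fra: FRA | None = None
    # per call: syllable-wise rates, p-values and significance flags
    syllable_rates: dict[str, np.ndarray] = field(default_factory=dict)
    syllable_pvalues: dict[str, np.ndarray] = field(default_factory=dict)
    syllable_flags: dict[str, np.ndarray] = field(default_factory=dict)
    group: str = ""

    @property
    def n_responded_syllables(self) -> int:
        return int(sum(np.sum(f) for f in self.syllable_flags.values()))

    def responds_to_any_call(self) -> bool:
        return any(np.any(f) for f in self.syllable_flags.values())


# ---------------------------------------------------------------------------
# trial alignment


def align_trials(
    spike_times_ms: np.ndarray,
    schedule: StimSchedule,
    stimulus_id: str | None = None,
    level: float | None = None,
    pre_ms: float = 1000.0,
    post_ms: float = 500.0,
) -> TrialSet:
    """Cut a continuous spike train into stimulus-aligned trials.

    Selects schedule events matching ``stimulus_id``/``level`` (None = all)
    and collects spikes in ``[-pre_ms, duration + post_ms)`` around each
    onset, re-referenced to the onset.
    """
    spikes = np.asarray(spike_times_ms, dtype=float)
    events = [e for e in schedule.events
              if (stimulus_id is None or e.stimulus_id == stimulus_id)
              and (level is None or e.level == level)]
    if not events:
        raise ValueError(f"no schedule events match stimulus_id={stimulus_id!r}, "
                         f"level={level!r}")
    dur_ms = events[0].duration * 1000.0
    trials = []
    for ev in events:
        onset_ms = ev.onset * 1000.0
        sel = spikes[(spikes >= onset_ms - pre_ms)
                     & (spikes < onset_ms + dur_ms + post_ms)]
        trials.append(sel - onset_ms)
    return TrialSet(trials=trials,
                    stimulus_id=stimulus_id or "all",
                    level=events[0].level if level is not None else np.nan,
                    pre_ms=pre_ms, post_ms=post_ms,
                    stimulus_duration_ms=dur_ms)


# ---------------------------------------------------------------------------
# PSTH and rates


def compute_psth(trials: TrialSet) -> PSTH:
    """1-ms-binned histogram over [-pre, duration + post), summed over trials.

    Conservation: the bin counts sum to the number of spikes in range.
    """
    t0, t1 = -trials.pre_ms, trials.t_max
    edges = np.arange(t0, t1 + 1.0, 1.0)
    allspikes = np.concatenate(trials.trials) if trials.trials else np.array([])
    counts, _ = np.histogram(allspikes, bins=edges)
    return PSTH(counts=counts, t_start_ms=t0, n_trials=trials.n_trials)


def spontaneous_rate(trials: TrialSet,
                     mode: Literal["natural", "tone"] = "natural") -> float:
    """Mean pre-stimulus firing rate, spikes/s.

    Natural-call protocols use the 800 ms from -1000 to -200 ms before each
    presentation; tone protocols the 100 ms immediately preceding onset.
    """
    return float(np.mean(spontaneous_rate_per_trial(trials, mode)))


def spontaneous_rate_per_trial(trials: TrialSet,
                               mode: Literal["natural", "tone"] = "natural",
                               ) -> np.ndarray:
    w0, w1 = NATURAL_SPONT_WINDOW_MS if mode == "natural" else TONE_SPONT_WINDOW_MS
    if trials.pre_ms < -w0:
        raise ValueError(
            f"{mode} spontaneous rate needs a pre-window of >= {-w0:.0f} ms, "
            f"TrialSet has {trials.pre_ms:.0f} ms")
    width_s = (w1 - w0) / 1000.0
    return np.array([np.sum((t >= w0) & (t < w1)) / width_s
                     for t in trials.trials])


def matched_spont_rates(trials: TrialSet, width_ms: float,
                        mode: Literal["natural", "tone"] = "natural",
                        ) -> np.ndarray:
    """Per-trial spontaneous rates from a window matched in width.

    Rank-sum comparisons of firing rates are only calibrated when both
    samples share the same counting-window length (otherwise the two count
    distributions differ in discreteness even at equal rates). This draws the
    per-trial spontaneous sample from the last ``width_ms`` of the
    pre-stimulus segment used for the spontaneous-rate estimate.
    """
    w0, w1 = NATURAL_SPONT_WINDOW_MS if mode == "natural" else TONE_SPONT_WINDOW_MS
    if width_ms > (w1 - w0):
        raise ValueError(f"matched window {width_ms} ms exceeds the "
                         f"{w1 - w0:.0f} ms spontaneous segment")
    win = ResponseWindow(start_ms=w1 - width_ms, end_ms=w1, rule="matched-spont")
    return per_trial_window_rates(trials, win)


def syllable_windows(call: CallStimulus,
                     window_rule: Literal["fixed-100", "syllable-length"] = "fixed-100",
                     ) -> list[ResponseWindow]:
    """Per-syllable evoked-count windows, ms from stimulus onset.

    ``fixed-100``: 100 ms from each syllable onset. ``syllable-length``: 100 ms or the
    syllable length, whichever is longer (several syllables exceed 100 ms).
    Windows that would run into the next syllable are truncated at its onset.
    """
    wins = []
    for i, syl in enumerate(call.syllables):
        start = syl.onset * 1000.0
        if window_rule == "fixed-100":
            w = 100.0
        elif window_rule == "syllable-length":
            w = max(100.0, syl.duration * 1000.0)
        else:
            raise ValueError(f"unknown window rule {window_rule!r}")
        end = start + w
        if i + 1 < len(call.syllables):
            nxt = call.syllables[i + 1].onset * 1000.0
            if end > nxt:
                warnings.warn(
                    f"syllable {i} window truncated at next onset "
                    f"({end:.0f} -> {nxt:.0f} ms)", stacklevel=2)
                end = nxt
        wins.append(ResponseWindow(start_ms=start, end_ms=end, rule=window_rule))
    return wins


def per_trial_window_rates(trials: TrialSet, window: ResponseWindow) -> np.ndarray:
    """Firing rate inside ``window`` for each trial, spikes/s."""
    width_s = window.width_ms / 1000.0
    return np.array([np.sum((t >= window.start_ms) & (t < window.end_ms)) / width_s
                     for t in trials.trials])


def per_trial_window_counts(trials: TrialSet, window: ResponseWindow) -> np.ndarray:
    return np.array([int(np.sum((t >= window.start_ms) & (t < window.end_ms)))
                     for t in trials.trials])


def evoked_rate_syllables(
    trials: TrialSet,
    call: CallStimulus,
    window_rule: Literal["fixed-100", "syllable-length"] = "fixed-100",
) -> tuple[np.ndarray, float]:
    """Per-syllable evoked firing rates and their mean, spikes/s.

    Per-syllable rate = spikes in the syllable window across trials divided by
    (window width x n_trials); the cell's evoked rate is the mean over
    syllables.
    """
    rates = np.array([
        float(np.mean(per_trial_window_rates(trials, w)))
        for w in syllable_windows(call, window_rule)
    ])
    return rates, float(np.mean(rates))


# ---------------------------------------------------------------------------
# FWHM window and significance


def fwhm_window(psth: PSTH, smoothing_sd: float = 5.0) -> ResponseWindow:
    """Full-width-half-maximum evoked-response window on the smoothed PSTH.

    Baseline is the mean pre-stimulus (t < 0) smoothed bin height; the window
    runs from the first post-onset bin reaching half of (peak - baseline)
    above baseline to one past the last such bin. A flat PSTH (peak <=
    baseline) has no response window and raises.
    """
    sm = psth.smoothed(smoothing_sd)
    t = sm.t
    pre = sm.counts[t < 0]
    baseline = float(np.mean(pre)) if pre.size else 0.0
    post_mask = t >= 0
    post = sm.counts[post_mask]
    if post.size == 0:
        raise ValueError("PSTH has no post-onset bins")
    peak = float(np.max(post))
    if peak <= baseline:
        raise ValueError("flat PSTH: peak does not exceed baseline, "
                         "no response window")
    half = baseline + 0.5 * (peak - baseline)
    above = post >= half
    idx = np.flatnonzero(above)
    t_post = t[post_mask]
    start = float(t_post[idx[0]])
    end = float(t_post[idx[-1]] + sm.bin_ms)  # half-open
    return ResponseWindow(start_ms=start, end_ms=end, rule="FWHM")


def syllable_significance(
    trials: TrialSet,
    window: ResponseWindow,
    spont_per_trial: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-sided Mann-Whitney U between evoked and spontaneous per-trial rates.

    Returns the p-value and whether the syllable is flagged significant at
    ``alpha``.
    """
    if trials.n_trials < 2:
        raise ValueError("significance test needs >= 2 trials")
    evoked = per_trial_window_rates(trials, window)
    spont = np.asarray(spont_per_trial, dtype=float)
    if np.all(evoked == evoked[0]) and np.all(spont == evoked[0]):
        return 1.0, False  # identical constant samples: no evidence
    res = stats.mannwhitneyu(evoked, spont, alternative="two-sided")
    return float(res.pvalue), bool(res.pvalue < alpha)


# ---------------------------------------------------------------------------
# tone-protocol metrics


def compute_fra(
    tone_trials: dict[tuple[float, float], TrialSet],
    window: ResponseWindow,
) -> FRA:
    """Mean evoked firing rate for each (frequency, level) combination.

    The matrix is levels x freqs; the normalized variant divides by the
    cell's maximum rate (undefined, left None, for an all-zero matrix).
    """
    freqs = np.array(sorted({f for f, _ in tone_trials}))
    levels = np.array(sorted({lv for _, lv in tone_trials}))
    mat = np.full((len(levels), len(freqs)), np.nan)
    for (f, lv), ts in tone_trials.items():
        i = int(np.searchsorted(levels, lv))
        j = int(np.searchsorted(freqs, f))
        mat[i, j] = float(np.mean(per_trial_window_rates(ts, window)))
    mmax = np.nanmax(mat)
    normalized = mat / mmax if mmax > 0 else None
    return FRA(freqs_hz=freqs, levels_db=levels, matrix=mat, normalized=normalized)


def best_frequency(fra: FRA) -> float:
    """Frequency of the global FRA maximum (ties: lowest frequency)."""
    if np.nanmax(fra.matrix) <= 0:
        raise ValueError("all-zero FRA: best frequency undefined")
    with np.errstate(invalid="ignore"):
        col_max = np.nanmax(fra.matrix, axis=0)
    return float(fra.freqs_hz[int(np.argmax(col_max))])


def characteristic_frequency(fra: FRA) -> float:
    """Frequency maximizing the level-averaged response (ties: lowest freq)."""
    if np.nanmax(fra.matrix) <= 0:
        raise ValueError("all-zero FRA: characteristic frequency undefined")
    col_mean = np.nanmean(fra.matrix, axis=0)
    return float(fra.freqs_hz[int(np.argmax(col_mean))])


def response_latency(psth: PSTH, smoothing_sd: float = 5.0,
                     method: Literal["peak", "2sd"] = "peak") -> float:
    """Response latency in ms after stimulus onset.

    ``peak``: time of the smoothed-PSTH maximum after onset (the headline
    definition). ``2sd``: first post-onset bin where the smoothed PSTH exceeds
    baseline + 2 SD of the pre-stimulus bins (the robustness check).
    Ties resolve to the earliest time.
    """
    sm = psth.smoothed(smoothing_sd)
    t = sm.t
    post_mask = t >= 0
    post = sm.counts[post_mask]
    t_post = t[post_mask]
    pre = sm.counts[t < 0]
    baseline = float(np.mean(pre)) if pre.size else 0.0
    if float(np.max(post)) <= baseline:
        raise ValueError("no response: post-onset PSTH never exceeds baseline")
    if method == "peak":
        return float(t_post[int(np.argmax(post))])
    elif method == "2sd":
        sd = float(np.std(pre)) if pre.size else 0.0
        thr = baseline + 2.0 * sd
        idx = np.flatnonzero(post > thr)
        if idx.size == 0:
            raise ValueError("PSTH never reaches 2 SD above baseline")
        return float(t_post[idx[0]])
    raise ValueError(f"unknown latency method {method!r}")


# ---------------------------------------------------------------------------
# inclusion filter and group statistics


def exclude_nonresponsive(
    profiles: Sequence[NeuronProfile],
) -> tuple[list[NeuronProfile], dict]:
    """Drop cells with no significant response to any syllable of any call.

    A cell is retained iff at least one syllable of at least one call is
    flagged significant. The report lists excluded ids and per-group counts.
    """
    retained, excluded = [], []
    for p in profiles:
        (retained if p.responds_to_any_call() else excluded).append(p)
    by_group: dict[str, int] = {}
    for p in excluded:
        by_group[p.group] = by_group.get(p.group, 0) + 1
    report = {
        "n_input": len(profiles),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "excluded_ids": [p.neuron_id for p in excluded],
        "excluded_by_group": by_group,
    }
    return retained, report


def group_comparison(groups: dict[str, Sequence[float]],
                     alpha: float = 0.05) -> dict:
    """Kruskal-Wallis omnibus with omnibus-gated pairwise rank tests.

    Pairwise Mann-Whitney comparisons (two-sided, unadjusted — the
    least-significant-difference convention) are reported only when the
    omnibus test is significant at ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has < 2 values")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    samples = list(arrays.values())
    if all(np.array_equal(samples[0], s) for s in samples[1:]):
        omnibus_p = 1.0
    else:
        omnibus_p = float(stats.kruskal(*samples).pvalue)
    pairwise: dict[tuple[str, str], float] = {}
    if omnibus_p < alpha:
        names = list(arrays)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                p = float(stats.mannwhitneyu(arrays[a], arrays[b],
                                             alternative="two-sided").pvalue)
                pairwise[(a, b)] = p
    return {"omnibus_p": omnibus_p, "pairwise_p": pairwise,
            "gated": omnibus_p >= alpha}


# ---------------------------------------------------------------------------
# profile serialization


def profiles_to_frame(profiles: Sequence[NeuronProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "neuron_id": p.neuron_id,
            "group": p.group,
            "spont_rate": p.spont_rate,
            "evoked_rate": p.evoked_rate,
            "latency_ms": p.latency_ms,
            "bf_hz": p.bf_hz,
            "cf_hz": p.cf_hz,
            "n_responded_syllables": p.n_responded_syllables,
        })
    return pd.DataFrame(rows)
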