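"""Synthetic recordings and micrographs with the structure the pipeline assumes.

No public recordings accompany the study design this pipeline targets, so
this module generates the three kinds of raw data every downstream stage
consumes:

* spike trains — inhomogeneous Poisson: a constant spontaneous rate plus a
  rectangular evoked-rate kernel of fixed duration starting one latency
  (with truncated-Gaussian jitter) after each syllable onset;
* loose-patch voltage traces — a biphasic 1 ms spike template summed at the
  spike times plus Gaussian noise and optional slow drift, at the 10 kHz
  acquisition rate;
* fluorescence micrographs — disc-shaped nuclei on a background with a
  multiplicative linear illumination gradient and Poisson noise, with a
  controllable fraction of touching cells.

Every generated artifact comes with its ground truth, and all randomness
flows from one seed per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .detection import VoltageTrace
from .histology import FluorImage
from .metrics import TrialSet
from .stimuli import CallStimulus, StimSchedule, Syllable

__all__ = ["NeuronModel", "PopulationConfig", "GroundTruth", "make_call",
           "simulate_spike_trains", "biphasic_template", "synthesize_trace",
           "simulate_fluorescence_image", "sample_population",
           "simulate_experiment"]


@dataclass
class NeuronModel:
    """Generative parameters of one neuron.

    ``evoked_rates`` maps a stimulus id to the *additional* firing rate
    (spikes/s) during the response window following each of its syllables.
    """

    spont_rate: float  # spikes/s
    evoked_rates: dict[str, np.ndarray] = field(default_factory=dict)
    latency_ms: float = 15.0
    latency_jitter_sd_ms: float = 3.0
    response_duration_ms: float = 50.0
    label: str = "nonTRAP"  # "TRAP" | "nonTRAP"
    tone_tuning: Callable[[float, float], float] | None = None  # (freq, level) -> rate

    def __post_init__(self) -> None:
        if self.spont_rate < 0:
            raise ValueError("spont_rate must be >= 0")
        if self.response_duration_ms <= 0:
            raise ValueError("response_duration_ms must be > 0")
        self.evoked_rates = {k: np.asarray(v, dtype=float)
                             for k, v in self.evoked_rates.items()}
        for k, v in self.evoked_rates.items():
            if np.any(v < 0):
                raise ValueError(f"negative evoked rate for stimulus {k!r}")


@dataclass
class GroundTruth:
    """What the generator actually produced, for estimator validation."""

    spike_times: dict[str, list[np.ndarray]] = field(default_factory=dict)
    cell_centroids: np.ndarray | None = None  # (n, 2) row/col
    params: dict = field(default_factory=dict)


def make_call(name: str, n_syllables: int, syllable_duration: float = 0.08,
              gap: float = 0.15, total_duration: float = 3.0) -> CallStimulus:
    """A regular synthetic call: n equispaced syllables from 100 ms onward."""
    period = syllable_duration + gap
    syls = [Syllable(onset=0.1 + i * period, duration=syllable_duration)
            for i in range(n_syllables)]
    return CallStimulus(name=name, syllables=syls, total_duration=total_duration)


def _poisson_times(rate: float, t0: float, t1: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) on [t0, t1)."""
    if rate <= 0 or t1 <= t0:
        return np.array([])
    n = rng.poisson(rate * (t1 - t0) / 1000.0)
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_spike_trains(
    neuron: NeuronModel,
    schedule: StimSchedule,
    calls: Sequence[CallStimulus] = (),
    seed: int = 0,
    pre_ms: float = 1000.0,
    post_ms: float = 500.0,
) -> tuple[dict[str, TrialSet], GroundTruth]:
    """Per-stimulus stimulus-aligned spike trains for one neuron.

    Each schedule event yields one trial on ``[-pre_ms, duration + post_ms)``:
    baseline spikes at ``spont_rate`` over the whole window, plus evoked
    spikes at the stimulus' per-syllable rate for ``response_duration_ms``
    starting ``latency_ms`` (+ truncated-Gaussian jitter) after each syllable
    onset. Tone events use ``tone_tuning(freq, level)`` when provided.
    """
    rng = np.random.default_rng(seed)
    call_map = {c.name: c for c in calls}
    by_stim: dict[str, list[np.ndarray]] = {}
    for ev in schedule.events:
        dur_ms = ev.duration * 1000.0
        spikes = [_poisson_times(neuron.spont_rate, -pre_ms, dur_ms + post_ms, rng)]
        # per-syllable evoked windows
        if ev.stimulus_id in neuron.evoked_rates and ev.stimulus_id in call_map:
            call = call_map[ev.stimulus_id]
            rates = neuron.evoked_rates[ev.stimulus_id]
            if len(rates) != call.n_syllables:
                raise ValueError(
                    f"{ev.stimulus_id!r}: {len(rates)} rates for "
                    f"{call.n_syllables} syllables")
            onsets = [s.onset * 1000.0 for s in call.syllables]
        elif ev.freq is not None and neuron.tone_tuning is not None:
            rates = np.array([neuron.tone_tuning(ev.freq, ev.level)])
            onsets = [0.0]
        else:
            rates, onsets = np.array([]), []
        for rate, onset in zip(rates, onsets):
            jitter = rng.normal(0.0, neuron.latency_jitter_sd_ms)
            lat = max(0.0, neuron.latency_ms + jitter)
            t0 = onset + lat
            spikes.append(_poisson_times(rate, t0,
                                         t0 + neuron.response_duration_ms, rng))
        by_stim.setdefault(ev.stimulus_id, []).append(
            np.sort(np.concatenate(spikes)))
    trialsets = {}
    for stim, trials in by_stim.items():
        ev = next(e for e in schedule.events if e.stimulus_id == stim)
        trialsets[stim] = TrialSet(trials=trials, stimulus_id=stim,
                                   pre_ms=pre_ms, post_ms=post_ms,
                                   stimulus_duration_ms=ev.duration * 1000.0)
    gt = GroundTruth(spike_times={k: list(v.trials) for k, v in trialsets.items()},
                     params={"spont_rate": neuron.spont_rate,
                             "label": neuron.label})
    return trialsets, gt


def biphasic_template(sample_rate: float = 10_000.0, width_ms: float = 1.0,
                      amplitude: float = 1.0) -> np.ndarray:
    """A biphasic extracellular spike shape: positive lobe then negative.

    The positive peak (= ``amplitude``) sits at the template argmax, which
    ``synthesize_trace`` aligns to the spike time.
    """
    n = max(4, int(round(width_ms / 1000.0 * sample_rate)))
    t = np.linspace(0, 1, n)
    shape = np.sin(2 * np.pi * t) * np.exp(-3 * t)
    return amplitude * shape / shape.max()


def synthesize_trace(
    spike_times_ms: np.ndarray,
    duration_s: float,
    sample_rate: float = 10_000.0,
    template: np.ndarray | None = None,
    noise_sd: float = 0.1,
    drift_amplitude: float = 0.0,
    drift_freq_hz: float = 1.0,
    seed: int = 0,
) -> VoltageTrace:
    """Template-plus-noise loose-patch trace.

    The template peak lands within one sample of each spike time; Gaussian
    noise and an optional sinusoidal low-frequency drift are added on top
    (the drift is what the 100 Hz high-pass is there to remove).
    """
    if template is None:
        template = biphasic_template(sample_rate)
    template = np.asarray(template, dtype=float)
    if template.max() <= 0:
        raise ValueError("template peak amplitude must be > 0")
    n_samples = int(round(duration_s * sample_rate))
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    if spike_times_ms.size and (spike_times_ms.max() / 1000.0) >= duration_s:
        raise ValueError("spike time beyond trace length")
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else np.zeros(n_samples)
    if drift_amplitude > 0:
        t = np.arange(n_samples) / sample_rate
        trace += drift_amplitude * np.sin(2 * np.pi * drift_freq_hz * t)
    peak_off = int(np.argmax(template))
    for t_ms in spike_times_ms:
        center = int(round(t_ms / 1000.0 * sample_rate))
        i0 = center - peak_off
        i1 = i0 + len(template)
        s0, s1 = max(i0, 0), min(i1, n_samples)
        trace[s0:s1] += template[s0 - i0:s1 - i0]
    return VoltageTrace(samples=trace, sample_rate=sample_rate)


def simulate_fluorescence_image(
    n_cells: int,
    size: tuple[int, int] = (512, 512),
    cell_radius: float = 6.0,
    intensity: float = 150.0,
    background: float = 30.0,
    illumination_gradient: float = 0.0,
    overlap_fraction: float = 0.0,
    noise: str = "poisson",
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[FluorImage, GroundTruth]:
    """Disc nuclei on an unevenly illuminated noisy background.

    A fraction ``overlap_fraction`` of cells is placed touching a neighbor
    (center distance 1.7 radii); the rest keep at least one diameter of
    clearance. The illumination gradient multiplies the clean image by
    ``1 + g * (x + y)/(W + H)`` so corner-to-corner background brightness
    differs by the factor ``1 + g``. Poisson shot noise is applied unless
    ``noise='none'``.
    """
    if intensity <= background:
        raise ValueError("cell intensity must exceed background")
    h, w = size
    rng = np.random.default_rng(seed)
    margin = int(np.ceil(2.5 * cell_radius))
    n_pairs = int(round(n_cells * overlap_fraction / 2.0))
    centers: list[tuple[float, float]] = []
    min_sep = 2.0 * cell_radius + 4.0

    def far_enough(r, c, sep):
        return all((r - r0) ** 2 + (c - c0) ** 2 >= sep ** 2 for r0, c0 in centers)

    # touching pairs first
    for _ in range(n_pairs):
        for attempt in range(max_retries):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            theta = rng.uniform(0, 2 * np.pi)
            d = 1.7 * cell_radius
            r1, c1 = r0 + d * np.sin(theta), c0 + d * np.cos(theta)
            if (margin <= r1 <= h - margin and margin <= c1 <= w - margin
                    and far_enough(r0, c0, min_sep + d)
                    and far_enough(r1, c1, min_sep + d)):
                centers += [(r0, c0), (r1, c1)]
                break
        else:
            raise RuntimeError("could not place touching pair within retry budget")
    # remaining isolated cells
    while len(centers) < n_cells:
        for attempt in range(max_retries):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if far_enough(r0, c0, min_sep):
                centers.append((r0, c0))
                break
        else:
            raise RuntimeError("could not place cell without overlap "
                               "within retry budget")
    centers_arr = np.array(centers[:n_cells]).reshape(-1, 2)

    rr, cc = np.mgrid[0:h, 0:w]
    clean = np.full((h, w), float(background))
    for r0, c0 in centers_arr:
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= cell_radius ** 2
        clean[disc] = intensity
    if illumination_gradient:
        clean *= 1.0 + illumination_gradient * (rr + cc) / (h + w - 2)
    if noise == "poisson":
        img = rng.poisson(clean).astype(float)
    elif noise == "none":
        img = clean
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    img = np.clip(img, 0, 255).astype(np.uint8)
    fi = FluorImage(pixels=img)
    gt = GroundTruth(cell_centroids=centers_arr,
                     params={"n_cells": n_cells, "cell_radius": cell_radius,
                             "intensity": intensity, "background": background,
                             "gradient": illumination_gradient})
    return fi, gt


# ---------------------------------------------------------------------------
# population- and experiment-level generation


@dataclass
class PopulationConfig:
    """Distributions of neuron parameters per population label.

    Defaults emulate the qualitative population structure the analyses test
    for: spontaneous rates of a few spikes/s in both populations, and tagged
    (TRAP) neurons carrying roughly twice the mean evoked rate of non-tagged
    neurons to the tagging stimulus and its kin.
    """

    n_trap: int = 30
    n_nontrap: int = 30
    spont_mean: float = 4.0  # spikes/s, both labels
    spont_sd: float = 2.0
    evoked_mean: dict[str, float] = field(
        default_factory=lambda: {"TRAP": 24.0, "nonTRAP": 12.0})
    evoked_sd: dict[str, float] = field(
        default_factory=lambda: {"TRAP": 8.0, "nonTRAP": 4.0})
    latency_ms: float = 15.0
    latency_jitter_sd_ms: float = 3.0
    response_duration_ms: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_trap < 1 or self.n_nontrap < 1:
            problems.append("n_trap/n_nontrap must be >= 1")
        if self.spont_sd < 0:
            problems.append("spont_sd must be >= 0")
        for lbl in ("TRAP", "nonTRAP"):
            if lbl not in self.evoked_mean or lbl not in self.evoked_sd:
                problems.append(f"evoked_mean/evoked_sd missing label {lbl}")
            elif self.evoked_sd[lbl] < 0:
                problems.append(f"evoked_sd[{lbl}] must be >= 0")
        if problems:
            raise ValueError("invalid PopulationConfig: " + "; ".join(problems))


def sample_population(config: PopulationConfig,
                      calls: Sequence[CallStimulus]) -> list[NeuronModel]:
    """Draw neuron models for both labels.

    Spontaneous rates are truncated-Gaussian; each neuron's per-syllable
    evoked rates are independent truncated-Gaussian draws around its label's
    mean, giving every neuron an idiosyncratic (hence decodable) response
    pattern across stimuli and syllables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    neurons = []
    for label, n in (("TRAP", config.n_trap), ("nonTRAP", config.n_nontrap)):
        for _ in range(n):
            spont = max(0.2, rng.normal(config.spont_mean, config.spont_sd))
            rates = {
                c.name: np.clip(
                    rng.normal(config.evoked_mean[label],
                               config.evoked_sd[label], size=c.n_syllables),
                    0.0, None)
                for c in calls
            }
            neurons.append(NeuronModel(
                spont_rate=spont, evoked_rates=rates,
                latency_ms=config.latency_ms,
                latency_jitter_sd_ms=config.latency_jitter_sd_ms,
                response_duration_ms=config.response_duration_ms,
                label=label))
    return neurons


def simulate_experiment(
    config: PopulationConfig,
    calls: Sequence[CallStimulus],
    schedule_builder,
    image_settings: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """A full session bundle: trains per neuron, images per condition, truth.

    ``schedule_builder(call, seed)`` must return the presentation schedule for
    one call. Images per (condition, region) are generated when
    ``image_settings`` is provided (keys: conditions -> region -> n_cells,
    plus any :func:`simulate_fluorescence_image` keyword). The bundle is fully
    reproducible from ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    neurons = sample_population(config, calls)
    schedules = {c.name: schedule_builder(c, seed=config.seed) for c in calls}
    sessions = []
    for i, neuron in enumerate(neurons):
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        trains: dict[str, TrialSet] = {}
        truths: dict[str, GroundTruth] = {}
        for c in calls:
            ts, gt = simulate_spike_trains(neuron, schedules[c.name], calls,
                                           seed=sub + hash(c.name) % 10_000)
            trains.update(ts)
            truths[c.name] = gt
        sessions.append({"neuron_id": f"{neuron.label}_{i:03d}",
                         "label": neuron.label, "model": neuron,
                         "trains": trains, "truth": truths})
    images = {}
    if image_settings:
        kwargs = {k: v for k, v in image_settings.items() if k != "conditions"}
        for cond, regions in image_settings.get("conditions", {}).items():
            for region, n_cells in regions.items():
                sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                img, gt = simulate_fluorescence_image(n_cells=n_cells,
                                                      seed=sub, **kwargs)
                img.region = region
                images[(cond, region)] = {"image": img, "truth": gt}
    bundle = {"config": config, "calls": list(calls), "schedules": schedules,
              "sessions": sessions, "images": images}
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    import pandas as pd
    import tifffile

    from .stimuli import write_call_annotations

    out_dir.mkdir(parents=True, exist_ok=True)
    write_call_annotations(bundle["calls"], out_dir / "calls.csv")
    for name, sched in bundle["schedules"].items():
        sched.to_csv(out_dir / f"schedule_{name}.csv")
    rows = []
    for s in bundle["sessions"]:
        for stim, ts in s["trains"].items():
            for trial, times in enumerate(ts.trials):
                for t in times:
                    rows.append({"neuron_id": s["neuron_id"], "label": s["label"],
                                 "stimulus_id": stim, "trial": trial,
                                 "time_ms": int(round(t))})
    pd.DataFrame(rows).to_csv(out_dir / "spikes.csv", index=False)
    for (cond, region), rec in bundle["images"].items():
        safe = cond.replace(" ", "_")
        tifffile.imwrite(out_dir / f"img_{safe}_{region}.tif",
                         rec["image"].pixels)
        np.savetxt(out_dir / f"centroids_{safe}_{region}.csv",
                   rec["truth"].cell_centroids, delimiter=",",
                   header="row,col", comments="")
    manifest = {"seed": bundle["config"].seed,
                "n_trap": bundle["config"].n_trap,
                "n_nontrap": bundle["config"].n_nontrap,
                "calls": [c.name for c in bundle["calls"]]}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
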