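"""End-to-end orchestration from a single config.

A run simulates (or loads) a session bundle, then executes the requested
stages in dependency order: spike-train extraction -> response metrics ->
d' matrices and group comparison -> pseudo-population decoding -> nuclei
counting and fold induction. Outputs are CSV/JSON per stage plus a manifest
(config hash, package version, seeds) so a rerun with the same config and
seed reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoder import accuracy_curve
from .dprime import dprime_matrix, compare_matrices, evoked_distribution
from .histology import (DensityResult, SectionCount, compute_density,
                        fold_induction, preprocess_image, segment_nuclei)
from .metrics import (compute_psth, evoked_rate_syllables, fwhm_window,
                      group_comparison, matched_spont_rates,
                      spontaneous_rate, spontaneous_rate_per_trial,
                      syllable_significance, syllable_windows,
                      exclude_nonresponsive, NeuronProfile, profiles_to_frame)
from .simulate import PopulationConfig, make_call, simulate_experiment
from .stimuli import build_call_protocol

log = logging.getLogger("trapcode")

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "population", "calls", "protocol",
    "metrics", "decoder", "imaging",
}
_DEFAULT_STAGES = ["simulate", "metrics", "dprime", "decode", "count"]


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "trapcode_run"
    stages: list[str] = dataclasses.field(
        default_factory=lambda: list(_DEFAULT_STAGES))
    population: dict = dataclasses.field(default_factory=dict)
    calls: dict = dataclasses.field(
        default_factory=lambda: {"USV": 6, "USV2": 6, "WC": 6})
    protocol: dict = dataclasses.field(
        default_factory=lambda: {"n_reps_per_level": 20,
                                 "attenuations": [0, 15, 30], "isi": 1.0})
    metrics: dict = dataclasses.field(
        default_factory=lambda: {"window_rule": "syllable-length", "smoothing_sd": 5.0})
    decoder: dict = dataclasses.field(
        default_factory=lambda: {"n_iterations": 200, "n_syllables": [1, 2, 3, 4, 5, 6],
                                 "reference": "USV"})
    imaging: dict = dataclasses.field(
        default_factory=lambda: {
            "conditions": {"No Stim": {"A1": 20, "S1": 20},
                           "USV": {"A1": 40, "S1": 20}},
            "n_sections": 2, "size": [256, 256], "cell_radius": 6.0,
            "intensity": 150.0, "background": 30.0,
            "illumination_gradient": 0.3, "overlap_fraction": 0.1})

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a report bundle.

    Returns a dict with per-stage results; every stage also writes its CSV
    outputs under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    timings: dict[str, float] = {}
    stages = config.stages

    for required, needs in [("metrics", "simulate"), ("dprime", "metrics"),
                            ("decode", "simulate")]:
        if required in stages and needs not in stages:
            raise ValueError(f"stage {required!r} requires stage {needs!r}")

    calls = [make_call(name, n) for name, n in config.calls.items()]
    call_map = {c.name: c for c in calls}

    bundle = None
    if "simulate" in stages:
        t0 = time.perf_counter()
        pop = PopulationConfig(**{**config.population, "seed": config.seed})

        def builder(call, seed):
            return build_call_protocol(call, config.protocol["n_reps_per_level"],
                                       config.protocol["attenuations"],
                                       config.protocol["isi"], seed=seed)

        img_settings = None
        if "count" in stages:
            imaging = dict(config.imaging)
            img_settings = {
                "conditions": imaging.pop("conditions"),
                "size": tuple(imaging.get("size", (256, 256))),
                "cell_radius": imaging.get("cell_radius", 6.0),
                "intensity": imaging.get("intensity", 150.0),
                "background": imaging.get("background", 30.0),
                "illumination_gradient": imaging.get("illumination_gradient", 0.3),
                "overlap_fraction": imaging.get("overlap_fraction", 0.1),
            }
        bundle = simulate_experiment(pop, calls, builder,
                                     image_settings=img_settings,
                                     out_dir=out / "data")
        timings["simulate"] = time.perf_counter() - t0
        log.info("simulate: %d sessions in %.1fs", len(bundle["sessions"]),
                 timings["simulate"])

    profiles: list[NeuronProfile] = []
    if "metrics" in stages:
        t0 = time.perf_counter()
        rule = config.metrics.get("window_rule", "syllable-length")
        sd = config.metrics.get("smoothing_sd", 5.0)
        for s in bundle["sessions"]:
            prof = NeuronProfile(neuron_id=s["neuron_id"], group=s["label"])
            spont_all, evoked_all = [], []
            for name, ts in s["trains"].items():
                call = call_map[name]
                spont_pt = spontaneous_rate_per_trial(ts, mode="natural")
                rates, mean_rate = evoked_rate_syllables(ts, call, rule)
                prof.syllable_rates[name] = rates
                pvals, flags = [], []
                for win in syllable_windows(call, rule):
                    spont_matched = matched_spont_rates(ts, win.width_ms)
                    p, flag = syllable_significance(ts, win, spont_matched)
                    pvals.append(p)
                    flags.append(flag)
                prof.syllable_pvalues[name] = np.array(pvals)
                prof.syllable_flags[name] = np.array(flags)
                spont_all.append(float(np.mean(spont_pt)))
                evoked_all.append(mean_rate)
            prof.spont_rate = float(np.mean(spont_all))
            prof.evoked_rate = float(np.mean(evoked_all))
            profiles.append(prof)
        retained, excl_report = exclude_nonresponsive(profiles)
        profiles_to_frame(profiles).to_csv(out / "profiles.csv", index=False)
        (out / "exclusion.json").write_text(json.dumps(excl_report, indent=1))
        groups = {}
        for p in retained:
            groups.setdefault(p.group, []).append(p.evoked_rate)
        stats = group_comparison(groups) if len(groups) >= 2 else {}
        report["metrics"] = {"n_profiles": len(profiles),
                             "exclusion": excl_report,
                             "group_stats": {
                                 "omnibus_p": stats.get("omnibus_p"),
                                 "pairwise_p": {f"{a}|{b}": p for (a, b), p
                                                in stats.get("pairwise_p", {}).items()}}}
        profiles = retained
        timings["metrics"] = time.perf_counter() - t0

    if "dprime" in stages:
        t0 = time.perf_counter()
        stim_names = [c.name for c in calls]
        mats = {}
        for label in ("TRAP", "nonTRAP"):
            cells = []
            for p in profiles:
                if p.group != label:
                    continue
                cells.append({name: evoked_distribution(p.syllable_rates[name],
                                                        stimulus_id=name,
                                                        neuron_id=p.neuron_id)
                              for name in stim_names})
            if cells:
                mats[label] = dprime_matrix(cells, stim_names, group=label)
                pd.DataFrame(mats[label].matrix, index=stim_names,
                             columns=stim_names).to_csv(
                    out / f"dprime_{label}.csv")
        report["dprime"] = {lbl: m.matrix.tolist() for lbl, m in mats.items()}
        if len(mats) == 2:
            cmp = compare_matrices(mats["TRAP"], mats["nonTRAP"])
            pd.DataFrame(cmp["p_matrix"], index=stim_names,
                         columns=stim_names).to_csv(out / "dprime_pvalues.csv")
            report["dprime_comparison_p"] = cmp["p_matrix"].tolist()
        timings["dprime"] = time.perf_counter() - t0

    if "decode" in stages:
        t0 = time.perf_counter()
        ref = config.decoder.get("reference", calls[0].name)
        comps = [c.name for c in calls if c.name != ref]
        pops = {"TRAP": [], "nonTRAP": []}
        for s in bundle["sessions"]:
            pops[s["label"]].append(s["trains"])
        curves, diffs = accuracy_curve(
            pops, call_map, ref, comps,
            n_syllables_range=config.decoder.get("n_syllables", [1, 2, 3, 4, 5, 6]),
            n_iterations=config.decoder.get("n_iterations", 200),
            seed=config.seed)
        rows = [{"population": c.population, "reference": c.pair[0],
                 "comparison": c.pair[1], "n_syllables": int(k),
                 "accuracy": float(a)}
                for c in curves for k, a in zip(c.n_syllables, c.accuracy)]
        pd.DataFrame(rows).to_csv(out / "decoder_curves.csv", index=False)
        report["decoder"] = {"curves": rows,
                             "difference": {f"{a}|{b}": d.tolist()
                                            for (a, b), d in diffs.items()}}
        timings["decode"] = time.perf_counter() - t0

    if "count" in stages:
        t0 = time.perf_counter()
        report["counting"] = _run_counting(bundle, config, out)
        timings["count"] = time.perf_counter() - t0

    manifest = {"config_hash": config.content_hash(), "seed": config.seed,
                "version": __version__, "stages": stages, "timings_s": timings}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    report["manifest"] = manifest
    return report


def _run_counting(bundle: dict, config: RunConfig, out: Path) -> dict:
    rows = []
    animals: dict[str, dict] = {}
    for (cond, region), rec in bundle["images"].items():
        img = preprocess_image(rec["image"])
        _, count = segment_nuclei(img)
        rows.append({"condition": cond, "region": region, "count": count,
                     "volume_mm3": rec["image"].masked_volume_mm3})
        animal = animals.setdefault(cond, {"counts": {}, "vols": {}})
        animal["counts"][region] = animal["counts"].get(region, 0) + count
        animal["vols"][region] = (animal["vols"].get(region, 0.0)
                                  + rec["image"].masked_volume_mm3)
    pd.DataFrame(rows).to_csv(out / "section_counts.csv", index=False)
    results = [DensityResult(animal=f"{cond}_m0", condition=cond,
                             counts=a["counts"], volumes_mm3=a["vols"])
               for cond, a in animals.items()]
    if any(r.condition == "No Stim" for r in results):
        df = fold_induction(results, baseline="No Stim")
        df.to_csv(out / "fold_induction.csv", index=False)
        return {"fold": df.to_dict(orient="records")}
    return {"sections": rows}
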