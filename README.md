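# trapcode

Analysis pipeline for activity-dependent neural tagging (TRAP) experiments in
auditory cortex: from raw loose-patch voltage traces and fluorescence
micrographs to spike times, stimulus-locked response metrics, single-neuron
discriminability (d′), cumulative-syllable population decoding, and
tagged-cell density quantification — with a synthetic-data generator that
reproduces the statistical structure every stage assumes, so the whole chain
is testable without experimental recordings.

## Who this is for

Systems-neuroscience labs running TRAP-style experiments: neurons active
during playback of a natural vocalization (e.g., pup ultrasonic
vocalizations, USVs, or wriggling calls, WCs) are permanently labeled, then
characterized electrophysiologically and histologically. The package covers
the full measurement chain:

| stage | module | what it does |
|---|---|---|
| stimulus design | `trapcode.stimuli` | tone / FRA / call playback schedules; syllable-wise waveform reversal |
| raw data | `trapcode.simulate` | inhomogeneous-Poisson spike trains, template-plus-noise traces, nuclei images — with ground truth |
| spike extraction | `trapcode.detection` | 100 Hz zero-phase high-pass, robust thresholding, one spike per suprathreshold segment at 1 ms resolution |
| response metrics | `trapcode.metrics` | 1-ms PSTHs, spontaneous/evoked rates, FWHM windows, per-syllable rank-sum significance, FRA/BF/CF/latency, responsiveness filter, group statistics |
| discriminability | `trapcode.dprime` | d′ between evoked-rate distributions; population matrices; per-pixel group comparison |
| decoding | `trapcode.decoder` | linear-SVM pseudo-population decoding with cumulative syllables (1–6) |
| histology | `trapcode.histology` | top-hat + median preprocessing, >50 binarization, watershed splitting, density and fold induction |
| orchestration | `trapcode.pipeline`, `trapcode` CLI | end-to-end runs from a YAML config with a reproducibility manifest |

## The statistics at the core

**Evoked rate.** For each syllable, spikes are counted in a window of 100 ms
after syllable onset (or the syllable length, if longer); a cell's evoked
rate to a call is the mean over its syllables. Spontaneous rate comes from
the 800 ms preceding each presentation (−1 to −0.2 s).

**Discriminability.** For one neuron and two stimuli with syllable-wise
evoked-rate means μ₁, μ₂ and SDs σ₁, σ₂:

    d′ = (μ₁ − μ₂) / √(½(σ₁² + σ₂²))

d′ = 0 means identical response intensity to the two stimuli. Population
matrices show mean |d′| across neurons for every stimulus pair.

**Decoding.** Population response vectors are assembled from separately
recorded neurons by randomly pairing their trials ("pseudo-trials"): each
neuron contributes its spike counts to the first k syllables (k = 1…6,
cumulative). A linear SVM is trained on 18 of 20 trials per class and scored
on the held-out 2, re-splitting and re-pairing 1000 times.

**Fold induction.** Labeled-cell density in auditory cortex (A1) is
normalized to the somatosensory control region (S1) per animal, then to the
mean A1/S1 ratio of the no-stimulation group — whose mean fold is therefore
exactly 1.

## Worked example

One synthetic neuron responding strongly to a USV and weakly to a WC
(20 trials × 3 attenuation levels per call):

```python
import numpy as np
from trapcode.simulate import NeuronModel, make_call, simulate_spike_trains
from trapcode.stimuli import build_call_protocol
from trapcode.metrics import evoked_rate_syllables, spontaneous_rate
from trapcode.dprime import dprime, evoked_distribution

usv, wc = make_call("USV", 6), make_call("WC", 6)
neuron = NeuronModel(spont_rate=4.0,
                     evoked_rates={"USV": np.full(6, 24.0),
                                   "WC": np.array([4., 6., 8., 10., 12., 14.])})
trains = {}
for i, call in enumerate([usv, wc]):
    sched = build_call_protocol(call, 20, [0, 15, 30], isi=1.0, seed=i)
    ts, _ = simulate_spike_trains(neuron, sched, [usv, wc], seed=7 + i)
    trains.update(ts)

print(f"spontaneous rate: {spontaneous_rate(trains['USV'], 'natural'):.2f} sp/s")
dists = {}
for name, call in [("USV", usv), ("WC", wc)]:
    rates, mean = evoked_rate_syllables(trains[name], call, "syllable-length")
    dists[name] = evoked_distribution(rates, stimulus_id=name, neuron_id="n0")
    print(f"{name}: mean evoked rate {mean:.2f} sp/s "
          f"(per-syllable SD {dists[name].sigma:.2f})")
print(f"d'(USV, WC) = {dprime(dists['USV'], dists['WC']):.2f}")
```

prints

```
spontaneous rate: 4.23 sp/s
USV: mean evoked rate 17.14 sp/s (per-syllable SD 2.28)
WC: mean evoked rate 8.31 sp/s (per-syllable SD 2.13)
d'(USV, WC) = 4.00
```

The estimated spontaneous rate (4.23 sp/s) recovers the generator's 4 sp/s.
Evoked estimates sit between the spontaneous and generator rates because the
50 ms response kernel occupies half of each 100 ms counting window; the large
d′ of 4.0 reflects the clear separation between the two calls' syllable-rate
distributions for this neuron.

A full pipeline run (simulation → metrics → d′ → decoding → counting):

```bash
trapcode run --seed 1 --out-dir run1
```

writes per-stage CSVs (`profiles.csv`, `dprime_*.csv`, `decoder_curves.csv`,
`fold_induction.csv`) and a `manifest.json`; rerunning with the same seed
reproduces the files byte for byte.

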