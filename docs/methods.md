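# Methods

This note documents the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Stimulus protocols

Schedules are deterministic closed forms of their parameters. The
inter-stimulus interval (ISI) is offset-to-onset everywhere; a fixed-period
protocol therefore contains `floor(total_time / (duration + ISI))` events
(partial final periods are dropped): one hour of 100 ms tones with a 900 ms
ISI gives 3600 presentations, one hour of 3 s calls with a 1 s ISI gives 900.
The frequency-response-area (FRA) grid crosses log-spaced frequencies with
sound levels; each combination appears exactly `n_reps` times and the trial
list is shuffled once with the supplied seed (30 × 4 × 12 = 1440 trials).
Call characterization presents one call `n_reps_per_level` times per
attenuation (20 × 3 = 60 trials). Attenuation is stored in dB relative to the
maximum playback level; absolute SPL is metadata.

Syllable windows are half-open `[onset, onset + duration)`; in samples, a
boundary sample belongs to the earlier window. `flip_syllables` reverses the
waveform inside each window and touches nothing else, so it is an involution
and preserves signal energy exactly.

## Synthetic data

The generator produces the minimal statistical structure the analyses assume,
not biophysics:

* **Spike trains** are inhomogeneous Poisson: a constant spontaneous rate
  over the whole trial plus a rectangular evoked kernel (default 50 ms) that
  starts one latency (default 15 ms) after each syllable onset. Latency
  jitter is Gaussian (default SD 3 ms), truncated at zero. Defaults put
  spontaneous rates at a few spikes/s and give the tagged (TRAP) population
  roughly twice the mean evoked rate of the non-tagged population — the
  qualitative contrast the downstream comparisons are designed to detect.
  No public recordings accompany this experimental design, so the defaults
  are illustrative study conditions, not fitted values.
* **Voltage traces** are a biphasic 1 ms spike template summed at the spike
  times plus Gaussian noise and optional sinusoidal drift, at the 10 kHz
  acquisition rate. The template peak lands within one sample of the spike
  time, so detector timing can be validated against ground truth.
* **Micrographs** are disc-shaped nuclei on a uniform background with a
  multiplicative linear illumination gradient (`1 + g·(x+y)/(W+H)`, so
  corner-to-corner brightness differs by the factor `1 + g`) and Poisson shot
  noise. A configurable fraction of nuclei is placed touching a neighbor
  (center distance 1.7 radii) to exercise watershed splitting; the remainder
  keep at least one diameter of clearance.

What the generator does **not** emulate: bursting and refractoriness, rate
adaptation across trials, correlated noise between neurons, realistic
vocalization audio, irregular nucleus morphology, or 3-D image stacks.
Passing tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to every property of real recordings.

All randomness flows from one explicit seed per call; experiment-level
generation derives per-neuron and per-image sub-seeds deterministically from
the config seed.

## Spike detection

Traces are high-pass filtered at 100 Hz with a 4th-order Butterworth applied
forward–backward (zero phase), since the recording hardware's built-in filter
order is not part of the data and spike times must not shift. Detection
thresholds default to `median + 5·MAD/0.6745` of the (polarity-corrected)
trace — the standard robust noise-SD convention; at 5 estimated SDs a pure
Gaussian noise trace crosses threshold well under once per 10 s at 10 kHz.
Polarity is auto-selected by a symmetric tail-extremity statistic, which
makes detection invariant to the sign convention of the amplifier. One spike
is assigned per contiguous suprathreshold segment at its extremum sample;
segments separated by less than 1 ms of sub-threshold samples are merged (a
refractory floor, and a deterministic resolution of multi-peaked segments).
Spike times are rounded to the nearest millisecond and deduplicated.

## Response metrics

PSTHs are binned at 1 ms, counts summed over trials, origin at stimulus
onset; bin counts always sum to the number of spikes in range. Smoothing
before peak/half-max extraction uses a Gaussian kernel (default SD 5 ms,
recorded in outputs); raw 1 ms bins are too noisy for stable half-maximum
crossings, and the SD can be set to 0 to disable smoothing.

* **Spontaneous rate:** natural-call protocols use the 800 ms from −1000 to
  −200 ms before each presentation; tone protocols the 100 ms before onset.
* **Evoked rate:** per-syllable windows of 100 ms (`fixed-100`) or
  `max(100 ms, syllable length)` (`syllable-length`); windows that would overrun the
  next syllable are truncated at its onset with a warning. The cell value is
  the mean over syllables.
* **FWHM window:** on the smoothed PSTH, baseline = mean pre-stimulus bin
  height (the reference for "half maximum" must be defined somewhere;
  pre-stimulus mean is the estimator already in use for spontaneous
  activity). The window runs from the first post-onset bin reaching
  baseline + ½(peak − baseline) to one past the last such bin — two equal
  peaks yield a single spanning window. Flat PSTHs raise a no-response error.
  The window is scale-invariant by construction.
* **Significance per syllable:** two-sided Mann–Whitney U between per-trial
  evoked rates and per-trial spontaneous rates at α = 0.05. The spontaneous
  sample is drawn from a pre-stimulus window **matched in width** to the
  response window (`matched_spont_rates`): with unequal window lengths the
  two count distributions differ in discreteness even at equal rates, and
  direct simulation shows the test then rejects ~56% of true nulls at 60
  trials instead of 5%. With matched windows the type-I error calibrates at
  0.05 (verified on >2000 simulated null syllables).
* **Tone parameters:** six per cell — spontaneous rate, evoked rate in the
  FWHM window, latency (smoothed-PSTH peak; a 2-SD-above-baseline crossing
  variant is also computed), best frequency (global FRA maximum),
  characteristic frequency (maximum of the level-averaged response), and the
  FRA matrix normalized by the cell's maximum (left unnormalized if
  all-zero). Ties resolve to the earliest time and lowest frequency —
  deterministic and order-independent.
* **Inclusion filter:** cells with no significant response to any syllable
  of any call are excluded before population analyses; the report lists
  excluded ids and per-group counts.
* **Group statistics:** Kruskal–Wallis omnibus; pairwise two-sided
  Mann–Whitney comparisons are reported only when the omnibus test is
  significant, and are unadjusted — the least-significant-difference
  convention transplanted to rank tests. This is the closest nonparametric
  analogue of LSD-after-omnibus gating; it controls the familywise rate only
  through the gate.

## Discriminability

d′ = (μ₁ − μ₂)/√(½(σ₁² + σ₂²)) over syllable-wise evoked rates, with σ the
sample SD (n − 1). Population matrices average |d′| across neurons: averaging
signed d′ would cancel under the arbitrary ordering of stimulus pairs, and
the population quantity of interest is discriminability magnitude. When both
SDs are zero, equal means give 0 and unequal means give an undefined value
that is excluded from pixel averages and counted. Pixels of two groups'
matrices are compared with two-sided Mann–Whitney tests on the per-neuron
|d′| values.

## Decoding

Linear SVM (scikit-learn `LinearSVC`, cost C = 1.0, configurable) on
pseudo-population vectors: columns are neuron × syllable spike counts in the
`syllable-length` windows, rows are pseudo-trials built by independently permuting each
neuron's 20 highest-intensity trials. Per iteration the pairing is refreshed
and a fresh random 18/2 train/test split is drawn within each class; features
are standardized using training-set statistics only (spike-count scales
differ by an order of magnitude across neurons, and the test set must not
leak into the scaler). Accuracy is the fraction of the 4 held-out
pseudo-trials classified correctly, averaged over iterations (default 1000).
Iteration randomness derives from one base seed, so results are fully
deterministic under (seed, config). Cells with fewer than 20 trials for
either stimulus are excluded with a warning; stimuli with fewer syllables
than requested truncate the cumulative curve at their count.

## Cell quantification

Preprocessing: white top-hat with a disc structuring element (default radius
25 px — larger than a nucleus, smaller than illumination structure) removes
slowly varying background; a 3 × 3 median filter removes isolated noise
pixels. Segmentation: binary mask of pixels strictly above 50 (8-bit scale),
components below 20 px removed, touching nuclei split by watershed on the
negated distance transform with markers from h-maxima of the distance map
(h = 2 px) to suppress over-segmentation from pixel-level roughness. All
values are configurable and logged. Sections are 2-D; confocal z-stacks are
collapsed by maximum projection before counting. Density = summed counts /
summed masked volumes (mask area × nominal thickness, no shrinkage
correction) over an animal's sections; fold induction divides each animal's
A1/S1 density ratio by the baseline ("No Stim") group mean, making the
baseline mean exactly 1. Animals with zero control-region density are
excluded with a warning.

## Problem sizes used in the checks

The test suite validates estimator calibration on 200 simulated neurons
(60 trials each) and type-I error on ~2000 null syllables; decoder
calibration uses 8-neuron pseudo-populations at 1000 iterations, and the
tagged-vs-untagged decoding comparison 6 neurons per population × 100
iterations averaged over 10 seeds; counting fidelity uses 512 × 512 images
with 40–50 nuclei at 10% touching fraction. These sizes give stable
statistics for the stated tolerances while keeping the default suite quick to
run.

## Known limitations

* The Poisson generator has no refractory period, so synthetic traces can
  contain near-coincident spikes that merge into one detection; ground-truth
  matching in the tests accounts for this.
* The FWHM convention (smoothing, baseline reference, per-call vs
  per-syllable scope) is exposed as configuration; different conventions
  change window extents on noisy PSTHs.
* The LSD-after-Kruskal–Wallis gate does not control the familywise error
  rate beyond the omnibus gate.
* Decoding assumes exchangeable trials within a stimulus (pseudo-populations
  discard trial-to-trial co-fluctuations, which separately recorded neurons
  cannot provide anyway).
* Counting accuracy degrades when nuclei overlap more than ~30% of a radius
  or the disc/background intensity ratio falls below ~4; the defaults are
  tuned for well-stained sparse labeling.
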