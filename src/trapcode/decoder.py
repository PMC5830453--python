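"""Cumulative-syllable pseudo-population decoding.

Call identity is decoded from population activity with a linear support
vector machine. Because neurons are recorded in separate sessions, population
"pseudo-trials" are assembled by randomly pairing each neuron's own trials:
a response vector holds each neuron's spike count to each of the first k
syllables of a stimulus (k = 1..6, cumulative), counted in a window of 100 ms
or the syllable length, whichever is longer.

Protocol per stimulus pair: 20 trials per class at the highest sound
intensity; per iteration a fresh pseudo-trial pairing and a random 18/2
train/test split per class; features standardized with training-set
statistics; accuracy averaged over iterations (1000 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .metrics import TrialSet, per_trial_window_counts, syllable_windows
from .stimuli import CallStimulus

__all__ = ["FeatureMatrix", "DecoderResult", "AccuracyCurve",
           "syllable_count_tensor", "build_feature_matrix", "decode_pair",
           "accuracy_curve"]

N_TRAIN_PER_CLASS = 18
N_TEST_PER_CLASS = 2


@dataclass
class FeatureMatrix:
    """Assembled pseudo-trials plus the raw per-neuron count tensors.

    ``X`` is one realization of the pseudo-trial pairing (rows = 2 x 20
    pseudo-trials, columns = neuron x syllable counts); ``counts_a/b`` retain
    the per-neuron (trials x syllables) tensors so the pairing can be
    refreshed every decoder iteration.
    """

    X: np.ndarray
    y: np.ndarray  # 0 = class A, 1 = class B
    counts_a: np.ndarray  # neurons x trials x syllables
    counts_b: np.ndarray
    pair: tuple[str, str]
    n_syllables: int
    neuron_ids: list[str] = field(default_factory=list)

    @property
    def n_trials_per_class(self) -> int:
        return self.counts_a.shape[1]


@dataclass
class DecoderResult:
    accuracy: float
    per_iteration: np.ndarray
    pair: tuple[str, str]
    population: str
    n_syllables: int
    n_iterations: int


@dataclass
class AccuracyCurve:
    pair: tuple[str, str]
    population: str
    n_syllables: np.ndarray
    accuracy: np.ndarray


def syllable_count_tensor(
    trials: TrialSet,
    call: CallStimulus,
    n_syllables: int,
    window_rule: str = "syllable-length",
) -> np.ndarray:
    """Spike counts per (trial, syllable) for the first ``n_syllables``."""
    wins = syllable_windows(call, window_rule)[:n_syllables]
    if len(wins) < n_syllables:
        raise ValueError(f"call {call.name!r} has only {len(wins)} syllables, "
                         f"{n_syllables} requested")
    return np.stack([per_trial_window_counts(trials, w) for w in wins], axis=1)


def _assemble(counts_a: np.ndarray, counts_b: np.ndarray,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One pseudo-trial pairing: an independent trial permutation per neuron."""
    n_neurons, n_trials, n_syl = counts_a.shape
    xa = np.empty((n_trials, n_neurons * n_syl))
    xb = np.empty((n_trials, n_neurons * n_syl))
    for n in range(n_neurons):
        xa[:, n * n_syl:(n + 1) * n_syl] = counts_a[n, rng.permutation(n_trials)]
        xb[:, n * n_syl:(n + 1) * n_syl] = counts_b[n, rng.permutation(n_trials)]
    X = np.vstack([xa, xb])
    y = np.r_[np.zeros(n_trials, dtype=int), np.ones(n_trials, dtype=int)]
    return X, y


def build_feature_matrix(
    cells: Sequence[dict[str, TrialSet]],
    calls: dict[str, CallStimulus],
    pair: tuple[str, str],
    n_syllables: int,
    seed: int,
    window_rule: str = "syllable-length",
    n_trials_required: int = 20,
) -> FeatureMatrix:
    """Pseudo-trial feature matrix for one stimulus pair.

    Each cell must have ``n_trials_required`` trials for both stimuli (cells
    with fewer are excluded with a warning); columns are neuron x syllable
    spike counts; rows are pseudo-trials from a seeded independent trial
    permutation per neuron.
    """
    import warnings

    sa, sb = pair
    ca_list, cb_list, ids = [], [], []
    for idx, cell in enumerate(cells):
        ta, tb = cell[sa], cell[sb]
        if ta.n_trials < n_trials_required or tb.n_trials < n_trials_required:
            warnings.warn(f"cell {idx} excluded: needs {n_trials_required} "
                          f"trials per stimulus", stacklevel=2)
            continue
        ca = syllable_count_tensor(ta, calls[sa], n_syllables, window_rule)
        cb = syllable_count_tensor(tb, calls[sb], n_syllables, window_rule)
        ca_list.append(ca[:n_trials_required])
        cb_list.append(cb[:n_trials_required])
        ids.append(f"cell{idx}")
    if not ca_list:
        raise ValueError("no cell has enough trials")
    counts_a = np.stack(ca_list)
    counts_b = np.stack(cb_list)
    rng = np.random.default_rng(seed)
    X, y = _assemble(counts_a, counts_b, rng)
    return FeatureMatrix(X=X, y=y, counts_a=counts_a, counts_b=counts_b,
                         pair=pair, n_syllables=n_syllables, neuron_ids=ids)


def decode_pair(
    features: FeatureMatrix,
    n_iterations: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    population: str = "",
) -> DecoderResult:
    """Repeated random-split linear-SVM decoding of one stimulus pair.

    Per iteration: refresh the pseudo-trial pairing, draw a random 18/2
    train/test split within each class, standardize columns on the training
    set, fit a linear SVM (cost ``C``) and score the 4 held-out pseudo-trials.
    The result is the mean accuracy over iterations.
    """
    n_trials = features.n_trials_per_class
    n_test = max(1, round(n_trials * N_TEST_PER_CLASS / 20))
    rng = np.random.default_rng(seed)
    acc = np.empty(n_iterations)
    clf = LinearSVC(C=C)
    for it in range(n_iterations):
        X, y = _assemble(features.counts_a, features.counts_b, rng)
        test_idx = np.concatenate([
            rng.choice(n_trials, size=n_test, replace=False),
            n_trials + rng.choice(n_trials, size=n_test, replace=False),
        ])
        mask = np.zeros(2 * n_trials, dtype=bool)
        mask[test_idx] = True
        scaler = StandardScaler()
        Xtr = scaler.fit_transform(X[~mask])
        Xte = scaler.transform(X[mask])
        ytr, yte = y[~mask], y[mask]
        if len(np.unique(ytr)) < 2 or np.allclose(Xtr.std(axis=0), 0):
            acc[it] = 0.5  # degenerate training set: chance
            continue
        clf.fit(Xtr, ytr)
        acc[it] = float(np.mean(clf.predict(Xte) == yte))
    return DecoderResult(accuracy=float(np.mean(acc)), per_iteration=acc,
                         pair=features.pair, population=population,
                         n_syllables=features.n_syllables,
                         n_iterations=n_iterations)


def accuracy_curve(
    populations: dict[str, Sequence[dict[str, TrialSet]]],
    calls: dict[str, CallStimulus],
    reference: str,
    comparisons: Sequence[str],
    n_syllables_range: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_iterations: int = 1000,
    seed: int = 0,
    window_rule: str = "syllable-length",
) -> tuple[list[AccuracyCurve], dict[tuple[str, str], np.ndarray]]:
    """Decoding accuracy vs cumulative syllable count for every population x pair.

    The full design decodes the tagging stimulus against each comparison
    stimulus for each population (2 populations x 5 comparisons = 10 curves of
    6 points). Curves for a stimulus with fewer syllables than requested are
    truncated at its syllable count. Difference curves (first population minus
    second, pointwise) are returned when exactly two populations are given.
    """
    curves: list[AccuracyCurve] = []
    ss = np.random.SeedSequence(seed)
    for pop_name, cells in populations.items():
        for comp in comparisons:
            pair = (reference, comp)
            max_syl = min(calls[reference].n_syllables, calls[comp].n_syllables)
            ks = [k for k in n_syllables_range if k <= max_syl]
            accs = []
            for k in ks:
                sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                fm = build_feature_matrix(cells, calls, pair, k, seed=sub_seed,
                                          window_rule=window_rule)
                res = decode_pair(fm, n_iterations=n_iterations,
                                  seed=sub_seed, population=pop_name)
                accs.append(res.accuracy)
            curves.append(AccuracyCurve(pair=pair, population=pop_name,
                                        n_syllables=np.array(ks),
                                        accuracy=np.array(accs)))
    diffs: dict[tuple[str, str], np.ndarray] = {}
    pop_names = list(populations)
    if len(pop_names) == 2:
        a, b = pop_names
        for comp in comparisons:
            ca = next(c for c in curves if c.population == a and c.pair[1] == comp)
            cb = next(c for c in curves if c.population == b and c.pair[1] == comp)
            m = min(len(ca.accuracy), len(cb.accuracy))
            diffs[(reference, comp)] = ca.accuracy[:m] - cb.accuracy[:m]
    return curves, diffs
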