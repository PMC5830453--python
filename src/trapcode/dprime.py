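"""Single-neuron stimulus discriminability (d').

For each neuron and each stimulus the evoked response is summarized by the
mean and SD of its syllable-wise evoked firing rates; the discriminability of
two stimuli is

    d' = (mu_1 - mu_2) / sqrt((sigma_1^2 + sigma_2^2) / 2)

i.e., the difference of means normalized by the root-mean of the two
variances. d' = 0 means the two stimuli evoke exactly the same response
intensity. Population matrices average |d'| across neurons per stimulus pair
(signed values would cancel under arbitrary stimulus ordering), and matched
pixels of two groups' matrices are compared with rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["EvokedDistribution", "DPrimeMatrix", "dprime", "dprime_matrix",
           "compare_matrices", "evoked_distribution"]


@dataclass(frozen=True)
class EvokedDistribution:
    """Mean/SD over syllable-wise evoked rates, one per neuron per stimulus."""

    mu: float  # spikes/s
    sigma: float  # spikes/s, sample SD (n-1) over syllables
    n: int  # syllable count
    stimulus_id: str = ""
    neuron_id: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 1:
            raise ValueError("syllable count must be >= 1")


def evoked_distribution(syllable_rates: Sequence[float], stimulus_id: str = "",
                        neuron_id: str = "") -> EvokedDistribution:
    """Summarize syllable-wise evoked rates (sample SD, n-1 denominator)."""
    r = np.asarray(syllable_rates, dtype=float)
    sigma = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    return EvokedDistribution(mu=float(np.mean(r)), sigma=sigma, n=r.size,
                              stimulus_id=stimulus_id, neuron_id=neuron_id)


def dprime(a: EvokedDistribution, b: EvokedDistribution) -> float:
    """d' between two evoked-rate distributions of the same neuron.

    Antisymmetric in its arguments. When both SDs are zero: equal means give
    0, unequal means give NaN (undefined; excluded from population averages).
    """
    if a.neuron_id and b.neuron_id and a.neuron_id != b.neuron_id:
        raise ValueError("d' compares two stimuli within one neuron")
    denom = np.sqrt(0.5 * (a.sigma ** 2 + b.sigma ** 2))
    if denom == 0.0:
        return 0.0 if a.mu == b.mu else float("nan")
    return float((a.mu - b.mu) / denom)


@dataclass
class DPrimeMatrix:
    """Stimulus x stimulus mean |d'| across neurons, with the per-neuron tensor."""

    stimuli: list[str]
    matrix: np.ndarray  # mean |d'|; diagonal 0; NaN where no valid neuron
    per_neuron: np.ndarray  # neurons x stimuli x stimuli, signed d' (NaN = undefined)
    neuron_ids: list[str]
    group: str = ""
    n_undefined: int = 0


def dprime_matrix(
    cells: Sequence[dict[str, EvokedDistribution]],
    stimuli: Sequence[str],
    group: str = "",
) -> DPrimeMatrix:
    """Average |d'| over neurons for every stimulus pair.

    Each cell must supply an :class:`EvokedDistribution` for every stimulus.
    Undefined per-neuron values (both SDs zero with unequal means) are
    excluded from the pixel average and counted.
    """
    stimuli = list(stimuli)
    n_stim = len(stimuli)
    per = np.full((len(cells), n_stim, n_stim), np.nan)
    neuron_ids = []
    for c, dists in enumerate(cells):
        missing = [s for s in stimuli if s not in dists]
        if missing:
            raise ValueError(f"cell {c} lacks distributions for {missing}")
        neuron_ids.append(next(iter(dists.values())).neuron_id or f"n{c}")
        for i, si in enumerate(stimuli):
            per[c, i, i] = 0.0
            for j in range(i + 1, n_stim):
                d = dprime(dists[si], dists[stimuli[j]])
                per[c, i, j] = d
                per[c, j, i] = -d
    n_undefined = int(np.isnan(per).sum() // 2)
    with np.errstate(invalid="ignore"):
        mat = np.nanmean(np.abs(per), axis=0)
    np.fill_diagonal(mat, 0.0)
    return DPrimeMatrix(stimuli=stimuli, matrix=mat, per_neuron=per,
                        neuron_ids=neuron_ids, group=group,
                        n_undefined=n_undefined)


def compare_matrices(group_a: DPrimeMatrix, group_b: DPrimeMatrix,
                     alpha: float = 0.05) -> dict:
    """Per-pixel rank-sum comparison of two groups' per-neuron |d'| values.

    Returns the p-value matrix (NaN on the diagonal and where a group is
    empty) and the boolean significance mask at ``alpha``.
    """
    if group_a.stimuli != group_b.stimuli:
        raise ValueError("matrices must share the same stimulus set")
    n = len(group_a.stimuli)
    pmat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            va = np.abs(group_a.per_neuron[:, i, j])
            vb = np.abs(group_b.per_neuron[:, i, j])
            va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
            if va.size == 0 or vb.size == 0:
                continue
            if np.all(va == va[0]) and np.all(vb == va[0]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(va, vb,
                                             alternative="two-sided").pvalue)
            pmat[i, j] = pmat[j, i] = p
    return {"p_matrix": pmat, "significant": pmat < alpha,
            "stimuli": list(group_a.stimuli)}
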