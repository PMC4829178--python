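"""Conditional response distributions and mixture-prior diagnostics.

A conditional response distribution (CRD) tabulates P(response | stimulus)
from post-burn-in trials; its shape separates the candidate priors and
decision rules qualitatively (a categorical prior with posterior sampling
yields bimodal columns confined to the trained range, a mean decision yields
unimodal columns, a Gaussian prior with sampling spills outside the range).

The quadrimodal-design diagnostics test whether responses betray a mixture
prior: an exact binomial test of low-probability responses against a 1/3
null, the probability of zero just-outside-the-range responses in a session,
and the across-participant exact binomial tail for that zero count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, binomtest, norm

from .core import DEFAULT_SUPPORT, PriorState, SupportGrid
from .fitting import CandidateModel, response_pmf
from .synthetic import TrainingDistribution

__all__ = [
    "CRD",
    "empirical_crd",
    "predicted_crd",
    "low_probability_response_test",
    "zero_outside_probability",
    "group_zero_count_tail",
    "mixture_outside_range_rate",
    "build_asymptotic_prior",
]


@dataclass
class CRD:
    """Conditional response distribution: columns are stimuli, rows responses."""

    stimuli: np.ndarray
    responses: np.ndarray
    matrix: np.ndarray  # shape (len(responses), len(stimuli)); columns sum to 1

    def column(self, stimulus: int) -> np.ndarray:
        return self.matrix[:, int(np.where(self.stimuli == stimulus)[0][0])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.responses, columns=self.stimuli)

    def plot(self, ax=None, scale: float = 0.95):
        """Hinton-style area plot (square area proportional to probability)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, s in enumerate(self.stimuli):
            for i, r in enumerate(self.responses):
                p = self.matrix[i, j]
                if p <= 0:
                    continue
                half = scale * np.sqrt(p) / 2
                ax.add_patch(
                    plt.Rectangle((s - half, r - half), 2 * half, 2 * half, color="k")
                )
        ax.set_xlim(self.stimuli.min() - 1, self.stimuli.max() + 1)
        ax.set_ylim(self.responses.min() - 1, self.responses.max() + 1)
        ax.set_xlabel("stimulus")
        ax.set_ylabel("response")
        return ax


def empirical_crd(
    trial_table: pd.DataFrame,
    burn_in: int = 300,
    support: SupportGrid = DEFAULT_SUPPORT,
) -> CRD:
    """CRD from trials with 1-based index greater than ``burn_in``."""
    late = trial_table[trial_table["trial"] > burn_in]
    if len(late) == 0:
        raise ValueError(f"no trials after burn-in {burn_in}")
    stimuli = np.sort(late["stimulus"].unique())
    responses = support.values
    mat = np.zeros((len(responses), len(stimuli)))
    for j, s in enumerate(stimuli):
        resp = late.loc[late["stimulus"] == s, "response"]
        counts = np.bincount(
            np.clip(resp.to_numpy(int) - support.lo, 0, support.size - 1),
            minlength=support.size,
        )
        mat[:, j] = counts / counts.sum()
    return CRD(stimuli=stimuli, responses=responses, matrix=mat)


def build_asymptotic_prior(
    prior_kind: str,
    training: TrainingDistribution,
    psi: float = 1.0,
    support: SupportGrid = DEFAULT_SUPPORT,
) -> np.ndarray:
    """Idealized fully-learned prior of each family, discretized on the support.

    ``categorical``: the training probabilities exactly.
    ``gaussian``: one normal moment-matched to the training distribution.
    ``mixture``: one normal per mode cluster (values grouped by proximity to
    the local peaks), each moment-matched; near-delta clusters get a small
    floor width so the discretization stays proper.
    ``kernel``: Gaussian kernel density over the trained values with
    bandwidth ``psi``, weighted by the training probabilities.
    """
    v = np.asarray(training.values, dtype=float)
    p = np.asarray(training.probs, dtype=float)
    grid = support.values.astype(float)
    if prior_kind == "categorical":
        return training.pmf_on(support)
    if prior_kind == "gaussian":
        mu = float(v @ p)
        sd = float(np.sqrt(((v - mu) ** 2) @ p))
        w = norm.pdf(grid, mu, max(sd, 0.5))
        return w / w.sum()
    if prior_kind == "kernel":
        bw = max(psi, 1e-6)
        w = (norm.pdf(grid[:, None], v[None, :], bw) * p[None, :]).sum(axis=1)
        return w / w.sum()
    if prior_kind == "mixture":
        clusters = _mode_clusters(v, p)
        w = np.zeros_like(grid)
        for idx in clusters:
            cw = p[idx].sum()
            mu = float(v[idx] @ p[idx]) / cw
            sd = float(np.sqrt(((v[idx] - mu) ** 2) @ p[idx] / cw))
            w += cw * norm.pdf(grid, mu, max(sd, 0.5))
        return w / w.sum()
    raise ValueError(f"unknown prior_kind {prior_kind!r}")


def _mode_clusters(values: np.ndarray, probs: np.ndarray) -> list:
    """Group support values around the local peaks of the training pmf."""
    peaks = [
        i
        for i in range(len(values))
        if (i == 0 or probs[i] >= probs[i - 1])
        and (i == len(values) - 1 or probs[i] >= probs[i + 1])
        and probs[i] == probs.max()
    ]
    if len(peaks) < 2:  # fall back: split at the largest gap / lowest point
        peaks = [0, len(values) - 1]
    assignment = [
        int(np.argmin([abs(values[i] - values[k]) for k in peaks]))
        for i in range(len(values))
    ]
    return [
        np.array([i for i, a in enumerate(assignment) if a == c])
        for c in range(len(peaks))
    ]


def predicted_crd(
    prior_kind: str,
    training: TrainingDistribution,
    sigma: float,
    decision: str = "sample",
    mc_samples: int = 2000,
    seed: int = 0,
    psi: float = 1.0,
    support: SupportGrid = DEFAULT_SUPPORT,
    lapse: float = 0.001,
) -> CRD:
    """Predicted CRD: the asymptotic prior of the given family combined with
    one decision function, integrating over the lognormal estimate draws."""
    prior = build_asymptotic_prior(prior_kind, training, psi=psi, support=support)
    # anchor the prior in a PriorState (scaled to pseudo-counts) for response_pmf
    state = PriorState(np.maximum(prior, 0) * 1000.0 + 1e-12, support)
    model = CandidateModel("dirichlet", decision, "none")
    stimuli = np.asarray(training.values, dtype=int)
    mat = np.zeros((support.size, len(stimuli)))
    for j, s in enumerate(stimuli):
        mat[:, j] = response_pmf(
            model,
            {"lapse": lapse},
            state,
            int(s),
            sigma,
            mc_samples=mc_samples,
            seed=seed + j,
        )
    return CRD(stimuli=stimuli, responses=support.values, matrix=mat)


def low_probability_response_test(
    responses, low_set=(24, 30), null_prop: float = 1.0 / 3.0
) -> float:
    """Exact one-sided binomial test: are responses in ``low_set`` rarer than
    the null proportion (1/3 under equal use of the six trained numbers)?"""
    responses = np.asarray(responses, dtype=int)
    if len(responses) == 0:
        raise ValueError("no responses to test")
    k = int(np.isin(responses, list(low_set)).sum())
    return float(binomtest(k, len(responses), null_prop, alternative="less").pvalue)


def zero_outside_probability(p_trial: float, T: int) -> float:
    """Probability of zero outside-range responses in T trials: (1-p)^T."""
    if not 0 <= p_trial <= 1:
        raise ValueError("p_trial must lie in [0, 1]")
    return float((1.0 - p_trial) ** T)


def group_zero_count_tail(k: int, n_participants: int, p_zero: float) -> float:
    """Exact binomial upper tail P(X >= k), X ~ Binomial(n_participants, p_zero)."""
    if not 0 <= k <= n_participants:
        raise ValueError("k must lie in [0, n_participants]")
    return float(binom.sf(k - 1, n_participants, p_zero))


def mixture_outside_range_rate(
    merged_pair: tuple[int, int],
    sigma: float,
    training: TrainingDistribution,
    mc_samples: int = 2000,
    seed: int = 0,
    singleton_sd: float = 0.05,
    support: SupportGrid = DEFAULT_SUPPORT,
) -> float:
    """Per-trial probability of responding exactly one unit outside the
    trained range for a sampling observer whose prior is a mixture with
    separate near-delta components for every trained value except one merged
    pair of adjacent numbers (sharing a moment-matched Gaussian component).
    """
    v = list(training.values)
    a, b = sorted(int(x) for x in merged_pair)
    if a not in v or b not in v or b - a != 1 or v.index(b) - v.index(a) != 1:
        raise ValueError("merged_pair must be adjacent numbers in the training support")
    p = np.asarray(training.probs, dtype=float)
    grid = support.values.astype(float)
    w = np.zeros_like(grid)
    for val, prob in zip(v, p):
        if val == a:
            pw = p[v.index(a)] + p[v.index(b)]
            mu = (a * p[v.index(a)] + b * p[v.index(b)]) / pw
            sd = np.sqrt(
                ((a - mu) ** 2 * p[v.index(a)] + (b - mu) ** 2 * p[v.index(b)]) / pw
            )
            w += pw * norm.pdf(grid, mu, max(sd, singleton_sd))
        elif val == b:
            continue  # folded into the merged component
        else:
            w += prob * norm.pdf(grid, float(val), singleton_sd)
    prior = w / w.sum()
    state = PriorState(prior * 1000.0 + 1e-12, support)
    model = CandidateModel("dirichlet", "sample", "none")
    outside = [training.lowest - 1, training.highest + 1]
    rate = 0.0
    for j, (s, ps) in enumerate(zip(v, p)):
        pmf = response_pmf(
            model, {"lapse": 0.0}, state, int(s), sigma, mc_samples, seed + j
        )
        rate += ps * sum(pmf[support.index(o)] for o in outside if support.contains(o))
    return float(rate)
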