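"""Synthetic trial generation and observer simulation.

Reproduces the trial structures of the three estimation experiments (bimodal
narrow/medium/wide dot-count distributions and the quadrimodal design) and
simulates observers with known parameters so that every downstream fitting
stage can be exercised and validated without external data.

Display rendering (dot radius, density, rectangle geometry, luminance,
timing) is deliberately not simulated: the observer model consumes only the
numeric stimulus value, which is all the analysis uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SUPPORT,
    ObserverSpec,
    PriorState,
    SupportGrid,
    apply_response_noise,
    compute_posterior,
    decide,
    dirichlet_update,
    kernel_update,
    softmax_transform,
    supermodel_response,
)

__all__ = [
    "TrainingDistribution",
    "TRAINING_DISTRIBUTIONS",
    "make_training_distribution",
    "sample_stimulus_sequence",
    "simulate_estimation_session",
    "make_discrimination_trials",
    "simulate_discrimination",
    "DISCRIMINATION_OFFSETS",
]

DISCRIMINATION_OFFSETS = (-8, -4, -2, -1, 1, 2, 4, 8)


@dataclass(frozen=True)
class TrainingDistribution:
    """Named categorical stimulus distribution (the experimental prior)."""

    name: str
    values: tuple
    probs: tuple

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError(f"probabilities of {self.name!r} sum to {p.sum()}")
        if min(self.values) < 1 or max(self.values) > 100:
            raise ValueError("training support must lie within [1:100]")

    @property
    def lowest(self) -> int:
        return int(min(self.values))

    @property
    def highest(self) -> int:
        return int(max(self.values))

    def pmf_on(self, support: SupportGrid = DEFAULT_SUPPORT) -> np.ndarray:
        """Probabilities embedded on the full support grid (zeros elsewhere)."""
        out = np.zeros(support.size)
        for v, p in zip(self.values, self.probs):
            out[support.index(int(v))] = p
        return out


def _spec(name, values, probs):
    return TrainingDistribution(name, tuple(values), tuple(probs))


# Bimodal designs: the two endpoint values carry the peaks, interior values
# share the remaining mass uniformly.  Quadrimodal: peaks at 23/25/29/31 with
# half-height shoulders at 24/30.
TRAINING_DISTRIBUTIONS = {
    "narrow": _spec("narrow", range(23, 30), [0.3] + [0.08] * 5 + [0.3]),
    "medium": _spec("medium", range(23, 33), [0.3] + [0.05] * 8 + [0.3]),
    "wide": _spec("wide", range(23, 36), [0.28] + [0.04] * 11 + [0.28]),
    "quadrimodal": _spec(
        "quadrimodal", (23, 24, 25, 29, 30, 31), (0.2, 0.1, 0.2, 0.2, 0.1, 0.2)
    ),
}


def make_training_distribution(name: str) -> TrainingDistribution:
    try:
        return TRAINING_DISTRIBUTIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown training distribution {name!r}; "
            f"valid names: {sorted(TRAINING_DISTRIBUTIONS)}"
        ) from None


def sample_stimulus_sequence(
    dist: TrainingDistribution, T: int, seed: int | np.random.Generator
) -> np.ndarray:
    """``T`` iid stimulus draws from the training distribution."""
    if T < 1:
        raise ValueError("T must be at least 1")
    rng = np.random.default_rng(seed)
    return rng.choice(np.asarray(dist.values), size=T, p=np.asarray(dist.probs))


def simulate_estimation_session(
    spec: ObserverSpec,
    stimuli,
    feedback_schedule=None,
    seed: int | np.random.Generator = 0,
    prior: PriorState | None = None,
) -> pd.DataFrame:
    """Simulate one observer through an ordered sequence of estimation trials.

    Per trial: draw ``log X ~ Normal(log S, sigma^2)``; form the posterior from
    the current predictive prior; produce a response through the spec's
    decision and noise stages; then, if feedback is scheduled, update the prior
    with the true stimulus.  Returns a trial table with 1-based indices.

    ``feedback_schedule`` is a boolean flag per trial (default: all True, as in
    the feedback blocks of the experiments; the final no-feedback test block is
    expressed by trailing False flags).
    """
    stimuli = np.asarray(stimuli, dtype=int)
    T = len(stimuli)
    if feedback_schedule is None:
        feedback_schedule = np.ones(T, dtype=bool)
    feedback_schedule = np.asarray(feedback_schedule, dtype=bool)
    if feedback_schedule.shape != (T,):
        raise ValueError("feedback_schedule length must match stimuli")
    support = spec.support
    for s in stimuli:
        support.index(int(s))  # raises if out of support
    rng = np.random.default_rng(seed)
    state = prior.copy() if prior is not None else PriorState.uniform(support)

    rows = []
    lo, hi = support.lo, support.hi
    for t in range(T):
        s = int(stimuli[t])
        X = float(s) * np.exp(spec.sigma * rng.standard_normal())
        post = compute_posterior(state.predictive(), X, spec.sigma, support)
        if spec.decision == "supermodel":
            resp = supermodel_response(post, spec.n_samples, spec.beta, rng, support)
        else:
            beta = spec.beta if spec.noise == "softmax" else 1.0
            q = softmax_transform(post, beta) if beta != 1.0 else post
            resp = decide(q, spec.decision, rng, support)
        resp = apply_response_noise(resp, spec, rng)
        if spec.inject_lapse and spec.lapse > 0 and rng.random() < spec.lapse:
            resp = int(rng.integers(lo, hi + 1))
        resp = int(np.clip(resp, lo, hi))
        fb = bool(feedback_schedule[t])
        rows.append((t + 1, s, fb, s if fb else -1, resp))
        if fb:
            if spec.prior_update == "kernel" and spec.psi > 0:
                state = kernel_update(state, s, spec.psi)
            else:
                state = dirichlet_update(state, s)

    return pd.DataFrame(
        rows, columns=["trial", "stimulus", "feedback_given", "feedback", "response"]
    )


def make_discrimination_trials(
    lowest_training_value: int,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    anchors: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Build 2AFC discrimination trials around low/high anchor numerosities.

    Anchors default to 11 below and 11 above the lowest training value; the
    experiments' alternative placement (11 above the *highest* value) can be
    requested via ``anchors``.  Each trial pairs an anchor with anchor+offset,
    the offset drawn uniformly from {-8,-4,-2,-1,1,2,4,8}, and the display
    order (which stimulus appears first) is randomized.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if anchors is None:
        anchors = (lowest_training_value - 11, lowest_training_value + 11)
    offsets = np.asarray(DISCRIMINATION_OFFSETS)
    if min(anchors) + offsets.min() < 1:
        raise ValueError("anchor + offset would fall below 1")
    rng = np.random.default_rng(seed)
    anchor = rng.choice(np.asarray(anchors), size=n_trials)
    offset = rng.choice(offsets, size=n_trials)
    other = anchor + offset
    first_is_anchor = rng.random(n_trials) < 0.5
    s1 = np.where(first_is_anchor, anchor, other)
    s2 = np.where(first_is_anchor, other, anchor)
    return pd.DataFrame(
        {
            "s1": s1.astype(int),
            "s2": s2.astype(int),
            "anchor": anchor.astype(int),
            "offset": offset.astype(int),
            "choice": np.zeros(n_trials, dtype=int),  # filled by a responder
        }
    )


def simulate_discrimination(
    sigma: float, trials: pd.DataFrame, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Simulate 2AFC choices: pick the display with the larger internal estimate.

    ``log X_k ~ Normal(log S_k, sigma^2)`` independently for the two displays;
    the chosen display (1 or 2) is the one whose draw is larger.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    n = len(trials)
    z = rng.standard_normal((n, 2))
    x1 = np.log(trials["s1"].to_numpy(float)) + sigma * z[:, 0]
    x2 = np.log(trials["s2"].to_numpy(float)) + sigma * z[:, 1]
    return np.where(x1 > x2, 1, 2)
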