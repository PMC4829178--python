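"""Estimating the lognormal noise scale sigma from 2AFC discrimination data.

Each trial shows two numerosities S1, S2; the participant picks the larger.
Under lognormal noise the internal estimates are log X_k ~ N(log S_k, sigma^2)
and the most-likely-response rule gives the closed-form choice probability
P(choose 1) = Phi((log S1 - log S2) / (sigma * sqrt(2))).  The fitting
procedure instead estimates this probability by Monte Carlo (as the original
analysis did) and maximizes the summed log-likelihood over sigma with a
bounded scalar search; the closed form serves as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "SigmaFit",
    "choice_probability_exact",
    "choice_probability_mc",
    "fit_sigma",
    "weber_to_sigma",
]


@dataclass(frozen=True)
class SigmaFit:
    sigma_hat: float
    neg_log_lik: float
    n_trials: int
    mc_samples: int
    seed: int
    flat_likelihood: bool = False
    at_bound: bool = False


def _check_sigma(sigma: float):
    if not sigma > 0:
        raise ValueError("sigma must be positive")


def choice_probability_exact(s1: float, s2: float, sigma: float) -> float:
    """Closed-form probability of choosing display 1: Phi(dlog/(sigma*sqrt(2)))."""
    _check_sigma(sigma)
    return float(norm.cdf((np.log(s1) - np.log(s2)) / (sigma * np.sqrt(2.0))))


def choice_probability_mc(
    s1: float, s2: float, sigma: float, mc_samples: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo probability of choosing display 1.

    Simulates ``mc_samples`` fictitious trials (one lognormal draw per display,
    pick the larger) and clips the frequency away from {0, 1} by
    ``1/(2*mc_samples)`` so downstream log-likelihoods stay finite.
    """
    _check_sigma(sigma)
    if mc_samples < 1:
        raise ValueError("mc_samples must be at least 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((mc_samples, 2))
    p = float(
        np.mean(np.log(s1) + sigma * z[:, 0] > np.log(s2) + sigma * z[:, 1])
    )
    eps = 1.0 / (2.0 * mc_samples)
    return float(np.clip(p, eps, 1.0 - eps))


def fit_sigma(
    trials: pd.DataFrame,
    bounds: tuple[float, float] = (0.01, 2.0),
    mc_samples: int = 10_000,
    seed: int = 0,
) -> SigmaFit:
    """Bounded maximum-likelihood estimate of sigma from 2AFC trials.

    ``trials`` must provide columns ``s1``, ``s2`` and ``choice`` (1 or 2).
    One fixed matrix of standard-normal draws is reused for every sigma
    evaluation (common random numbers), which makes the MC objective a smooth
    deterministic function of sigma and the bounded search well-posed.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("bounds must satisfy 0 < lo < hi")
    if len(trials) < 1:
        raise ValueError("need at least one discrimination trial")
    ls1 = np.log(trials["s1"].to_numpy(float))
    ls2 = np.log(trials["s2"].to_numpy(float))
    chose1 = trials["choice"].to_numpy(int) == 1
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(trials), mc_samples, 2))
    dz = z[:, :, 0] - z[:, :, 1]  # only the difference matters
    dls = (ls1 - ls2)[:, None]
    clip = 1.0 / (2.0 * mc_samples)

    def nll(sigma: float) -> float:
        p1 = np.clip((dls + sigma * dz > 0).mean(axis=1), clip, 1.0 - clip)
        p_obs = np.where(chose1, p1, 1.0 - p1)
        return -float(np.log(p_obs).sum())

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    sigma_hat = float(res.x)
    # Flatness diagnostic: a degenerate session (e.g. all ties, or perfect
    # accuracy at every offset) leaves the likelihood nearly constant or pinned
    # at a bound.
    grid = np.linspace(lo, hi, 9)
    vals = np.array([nll(s) for s in grid])
    flat = bool(vals.max() - vals.min() < 1.0)
    at_bound = bool(
        sigma_hat - lo < 0.02 * (hi - lo) or hi - sigma_hat < 0.02 * (hi - lo)
    )
    return SigmaFit(
        sigma_hat=sigma_hat,
        neg_log_lik=float(res.fun),
        n_trials=len(trials),
        mc_samples=mc_samples,
        seed=int(seed) if np.isscalar(seed) else 0,
        flat_likelihood=flat,
        at_bound=at_bound,
    )


def weber_to_sigma(w: float) -> float:
    """Convert a Weber fraction to the lognormal scale: sigma = sqrt(log(w^2+1))."""
    if w < 0:
        raise ValueError("Weber fraction must be nonnegative")
    return float(np.sqrt(np.log(w * w + 1.0)))
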