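"""Inference and response machinery of the Bayesian observer.

The observer perceives a positive integer stimulus ``S`` through lognormal
sensory noise: the internal estimate ``X`` satisfies
``log X ~ Normal(log S, sigma^2)`` (Weber's law on magnitudes).  On each trial
the observer combines the resulting likelihood over the integer response
support with a learned categorical prior via Bayes' rule, optionally sharpens
the posterior with a softmax exponent, and maps it to a single integer
response with one of three decision functions (MAP, posterior mean, or a
posterior sample) or with the nested "super-model" (rounded mean of ``n``
samples from the exponentiated posterior).

The prior is a Dirichlet pseudo-count vector over the support.  After each
feedback trial it is updated either conjugately (add 1 at the feedback value)
or with a Gaussian kernel of width ``psi`` spread over neighbouring integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator

__all__ = [
    "SupportGrid",
    "PriorState",
    "ObserverSpec",
    "DEFAULT_SUPPORT",
    "likelihood_over_support",
    "compute_posterior",
    "dirichlet_update",
    "kernel_update",
    "softmax_transform",
    "decide",
    "supermodel_response",
    "apply_response_noise",
    "round_half_up",
]


def round_half_up(x) -> np.ndarray | int:
    """Round to the nearest integer, halves away from zero is not needed:
    responses are positive, so floor(x + 0.5) implements round-half-up."""
    r = np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
    return int(r) if np.isscalar(x) or r.ndim == 0 else r


@dataclass(frozen=True)
class SupportGrid:
    """Contiguous integer response support ``lo..hi`` (inclusive)."""

    lo: int = 1
    hi: int = 100

    def __post_init__(self):
        if self.lo < 1 or self.hi < self.lo:
            raise ValueError(f"invalid support bounds [{self.lo}:{self.hi}]")

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1

    def index(self, value: int) -> int:
        if not self.contains(value):
            raise ValueError(f"value {value} outside support [{self.lo}:{self.hi}]")
        return int(value) - self.lo

    def contains(self, value) -> bool:
        return self.lo <= value <= self.hi


DEFAULT_SUPPORT = SupportGrid(1, 100)


@dataclass
class PriorState:
    """Dirichlet pseudo-counts ``alpha`` over a support grid.

    The categorical predictive prior is ``P(S = i) = alpha_i / sum(alpha)``.
    """

    alpha: np.ndarray
    support: SupportGrid = field(default_factory=lambda: DEFAULT_SUPPORT)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.support.size,):
            raise ValueError(
                f"alpha length {self.alpha.shape} does not match support size "
                f"{self.support.size}"
            )
        if np.any(self.alpha < 0) or not self.alpha.sum() > 0:
            raise ValueError("alpha must be nonnegative with positive total mass")

    @classmethod
    def uniform(cls, support: SupportGrid = DEFAULT_SUPPORT, weight: float = 1.0):
        """Symmetric prior: ``weight`` pseudo-counts on every support value."""
        return cls(np.full(support.size, float(weight)), support)

    def predictive(self) -> np.ndarray:
        """Categorical predictive prior (normalized alpha)."""
        return self.alpha / self.alpha.sum()

    def copy(self) -> "PriorState":
        return PriorState(self.alpha.copy(), self.support)


@dataclass(frozen=True)
class ObserverSpec:
    """A complete generative observer.

    Parameters
    ----------
    sigma
        Lognormal noise scale (SD of ``log X``), dimensionless.
    prior_update
        ``"dirichlet"`` (conjugate pseudo-count increment) or ``"kernel"``
        (Gaussian kernel increment of width ``psi`` over neighbouring values).
    decision
        ``"max"``, ``"mean"``, ``"sample"``, or ``"supermodel"`` (rounded mean
        of ``n_samples`` draws from the beta-exponentiated posterior).
    noise
        ``"none"``, ``"softmax"`` (posterior raised to ``beta``), or
        ``"trembling"`` (response replaced by a uniform draw w.p. ``epsilon``).
    lapse
        Uniform-response mixture applied in the model *likelihood*; the
        simulator injects it only if ``inject_lapse`` is set.
    """

    sigma: float
    prior_update: str = "dirichlet"
    psi: float = 0.0
    decision: str = "sample"
    noise: str = "none"
    beta: float = 1.0
    epsilon: float = 0.0
    n_samples: int = 1
    lapse: float = 0.001
    inject_lapse: bool = False
    support: SupportGrid = field(default_factory=lambda: DEFAULT_SUPPORT)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.prior_update not in ("dirichlet", "kernel"):
            raise ValueError(f"unknown prior_update {self.prior_update!r}")
        if self.decision not in ("max", "mean", "sample", "supermodel"):
            raise ValueError(f"unknown decision {self.decision!r}")
        if self.noise not in ("none", "softmax", "trembling"):
            raise ValueError(f"unknown noise {self.noise!r}")
        if self.psi < 0:
            raise ValueError("psi must be nonnegative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must lie in [0, 1]")

    def with_(self, **kwargs) -> "ObserverSpec":
        return replace(self, **kwargs)


def likelihood_over_support(
    X: float, sigma: float, support: SupportGrid = DEFAULT_SUPPORT
) -> np.ndarray:
    """Unnormalized likelihood of each integer ``S`` given internal estimate ``X``.

    ``L(S) = exp(-(log X - log S)^2 / (2 sigma^2))``; strictly positive on the
    whole support.
    """
    if not X > 0:
        raise ValueError("internal estimate X must be positive")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    d = np.log(X) - np.log(support.values)
    return np.exp(-(d * d) / (2.0 * sigma * sigma))


def compute_posterior(
    prior_predictive: np.ndarray,
    X: float,
    sigma: float,
    support: SupportGrid = DEFAULT_SUPPORT,
) -> np.ndarray:
    """Posterior ``P(S | X)`` proportional to likelihood times prior.

    Entries where the prior is exactly zero stay zero.  Raises
    ``ArithmeticError`` if the product underflows to an all-zero vector
    (possible only for extreme ``sigma`` with a prior disjoint from the
    likelihood's numerically supported region).
    """
    prior = np.asarray(prior_predictive, dtype=float)
    if prior.shape != (support.size,):
        raise ValueError("prior length does not match support")
    post = likelihood_over_support(X, sigma, support) * prior
    total = post.sum()
    if not total > 0:
        raise ArithmeticError("posterior underflowed to zero; check sigma and prior")
    return post / total


def dirichlet_update(state: PriorState, feedback: int) -> PriorState:
    """Conjugate update: add one pseudo-count at the feedback value."""
    idx = state.support.index(feedback)
    alpha = state.alpha.copy()
    alpha[idx] += 1.0
    return PriorState(alpha, state.support)


def kernel_increment(
    feedback: int, psi: float, support: SupportGrid = DEFAULT_SUPPORT
) -> np.ndarray:
    """Normalized Gaussian-kernel increment centred at the feedback value.

    ``delta_alpha_j = N(j; i, psi^2) / sum_j N(j; i, psi^2)`` over support
    integers ``j``; sums to exactly 1.  ``psi = 0`` degenerates to the
    Dirichlet indicator.
    """
    if psi < 0:
        raise ValueError("psi must be nonnegative")
    idx = support.index(feedback)
    if psi == 0:
        delta = np.zeros(support.size)
        delta[idx] = 1.0
        return delta
    d = support.values - float(feedback)
    logk = -(d * d) / (2.0 * psi * psi)
    logk -= logk.max()  # stabilize; normalization removes the constant
    delta = np.exp(logk)
    return delta / delta.sum()


def kernel_update(state: PriorState, feedback: int, psi: float) -> PriorState:
    """Kernel-density prior update: spread a unit increment over neighbours."""
    delta = kernel_increment(feedback, psi, state.support)
    return PriorState(state.alpha + delta, state.support)


def softmax_transform(posterior: np.ndarray, beta: float) -> np.ndarray:
    """Exponentiate the posterior (``p^beta``, renormalized).

    ``beta > 1`` sharpens toward the MAP, ``beta < 1`` flattens; rank order is
    preserved for every positive ``beta``.  Computed in log space for
    stability at large ``beta``.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    p = np.asarray(posterior, dtype=float)
    if beta == 1.0:
        return p / p.sum()
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
    logw = beta * logp
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def decide(
    posterior: np.ndarray,
    rule: str,
    rng: Generator | None = None,
    support: SupportGrid = DEFAULT_SUPPORT,
) -> int:
    """Map a posterior to one integer response.

    ``max``: index of the largest entry (smallest index on ties).
    ``mean``: posterior mean rounded half-up.
    ``sample``: one draw from the posterior pmf (requires ``rng``).
    """
    p = np.asarray(posterior, dtype=float)
    if rule == "max":
        return int(support.values[int(np.argmax(p))])
    if rule == "mean":
        return round_half_up(float(support.values @ p) / p.sum())
    if rule == "sample":
        if rng is None:
            raise ValueError("sample decision requires a random generator")
        return int(rng.choice(support.values, p=p / p.sum()))
    raise ValueError(f"unknown decision rule {rule!r}")


def supermodel_response(
    posterior: np.ndarray,
    n: int,
    beta: float,
    rng: Generator,
    support: SupportGrid = DEFAULT_SUPPORT,
) -> int:
    """Rounded mean of ``n`` draws from the beta-exponentiated posterior.

    Nests the three classic decision functions: ``n=1`` is posterior sampling,
    very large ``n`` approximates the mean, very large ``beta`` the MAP.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    q = softmax_transform(posterior, beta)
    draws = rng.choice(support.values, size=n, p=q)
    return round_half_up(float(draws.mean()))


def apply_response_noise(
    response: int,
    spec: ObserverSpec,
    rng: Generator,
) -> int:
    """Trembling hand: with probability ``epsilon`` replace the response by a
    uniform draw on the support.  (The lapse mixture lives in the likelihood,
    not here.)"""
    if spec.noise == "trembling" and spec.epsilon > 0:
        if rng.random() < spec.epsilon:
            return int(rng.integers(spec.support.lo, spec.support.hi + 1))
    return int(response)
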