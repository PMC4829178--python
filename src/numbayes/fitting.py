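"""Trial likelihoods by ancestral sampling, model fitting and BIC comparison.

The internal estimate ``X_t`` is latent, so the probability of each response
is approximated by simulating the generative chain: draw ``X_t`` from the
lognormal noise distribution around the stimulus, run the observer's
inference (current prior, Bayes' rule, optional softmax sharpening), apply
the decision function, and accumulate the resulting response distribution.
A fixed 0.001 uniform lapse over [1:100] is mixed into every trial pmf so no
observed response has zero probability.

Sixteen candidate models arise factorially from two prior-update rules
(Dirichlet, Gaussian kernel), three decision functions (max, mean, sample)
and three noise models (none, trembling hand, softmax; softmax is undefined
for max).  Each is fit by maximum likelihood over its 0-2 free parameters and
ranked by BIC = -2 logL + N log(M).  The nested super-model replaces the
discrete decision functions by the rounded mean of ``n`` samples from the
beta-exponentiated posterior, fitting (psi, beta) for each ``n`` on a fixed
grid.

Numerics: one fixed set of standard-normal draws per participant is reused
across all parameter values and all models (common random numbers), so BIC
differences between models are not Monte-Carlo noise.  Sample-decision
likelihoods average the (exponentiated) posterior over the X draws instead of
histogramming single response draws - same expectation, lower variance.  The
max and mean decisions are deterministic given X, so their response counts
are exactly the literal ancestral-sampling procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr

from .core import DEFAULT_SUPPORT, PriorState, SupportGrid, kernel_increment

__all__ = [
    "CandidateModel",
    "FitResult",
    "SuperModelFit",
    "AncestralEvaluator",
    "candidate_models",
    "response_pmf",
    "session_log_lik",
    "fit_model",
    "compare_models",
    "fit_supermodel",
    "SUPERMODEL_N_GRID",
    "MIN_RESPONSE",
]

MIN_RESPONSE = 5  # responses below this are treated as erroneous key presses
SUPERMODEL_N_GRID = (1, 2, 3, 4, 5, 10, 30, 100, 1000)

PSI_BOUNDS = (1e-3, 50.0)
BETA_BOUNDS = (0.05, 1000.0)
EPS_BOUNDS = (1e-6, 0.999)

# Evaluator caches the full (trials x mc x support) likelihood tensors only
# below this element count; above it, blocks are recomputed on the fly.
_CACHE_LIMIT = 1.5e8


@dataclass(frozen=True)
class CandidateModel:
    prior_update: str  # dirichlet | kernel
    decision: str  # max | mean | sample
    noise: str  # none | trembling | softmax

    def __post_init__(self):
        if self.prior_update not in ("dirichlet", "kernel"):
            raise ValueError(f"unknown prior_update {self.prior_update!r}")
        if self.decision not in ("max", "mean", "sample"):
            raise ValueError(f"unknown decision {self.decision!r}")
        if self.noise not in ("none", "trembling", "softmax"):
            raise ValueError(f"unknown noise {self.noise!r}")
        if self.noise == "softmax" and self.decision == "max":
            raise ValueError("softmax noise is not defined for a max decision")

    @property
    def free_params(self) -> tuple:
        params = []
        if self.prior_update == "kernel":
            params.append("psi")
        if self.noise == "trembling":
            params.append("epsilon")
        elif self.noise == "softmax":
            params.append("beta")
        return tuple(params)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def label(self) -> str:
        return f"{self.prior_update}-{self.decision}-{self.noise}"


def candidate_models() -> list:
    """The 16-model factorial (2 priors x 3 decisions x 3 noises, minus the
    two undefined softmax+max combinations)."""
    models = []
    for pu, dec, nz in itertools.product(
        ("dirichlet", "kernel"), ("max", "mean", "sample"), ("none", "trembling", "softmax")
    ):
        if nz == "softmax" and dec == "max":
            continue
        models.append(CandidateModel(pu, dec, nz))
    return models


@dataclass
class FitResult:
    model: CandidateModel
    params: dict
    log_lik: float
    bic: float
    n_trials_used: int
    converged: bool = True

    def to_record(self) -> dict:
        rec = {
            "model": self.model.label,
            "prior_update": self.model.prior_update,
            "decision": self.model.decision,
            "noise": self.model.noise,
            "log_lik": self.log_lik,
            "bic": self.bic,
            "n_trials_used": self.n_trials_used,
            "converged": self.converged,
        }
        rec.update({f"param_{k}": v for k, v in self.params.items()})
        return rec


@dataclass
class SuperModelFit:
    per_n: dict  # n -> {"psi": .., "beta": .., "log_lik": ..}
    best_n: int
    n_trials_used: int

    @property
    def best(self) -> dict:
        return self.per_n[self.best_n]


class AncestralEvaluator:
    """Per-participant engine for ancestral-sampling trial likelihoods.

    Precomputes, once per participant, the internal-estimate draws
    ``log X_{t,m} = log S_t + sigma * z_{t,m}`` for every usable trial
    (``z`` fixed: common random numbers) and the resulting per-trial
    likelihood tensors over the response support.  Every model/parameter
    evaluation then reduces to dense array arithmetic on these tensors.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        sigma: float,
        support: SupportGrid = DEFAULT_SUPPORT,
        mc_samples: int = 10_000,
        seed: int = 0,
        lapse: float = 0.001,
        min_response: int = MIN_RESPONSE,
        alpha0: float = 1.0,
    ):
        if not sigma > 0:
            raise ValueError("sigma must be positive")
        self.support = support
        self.sigma = float(sigma)
        self.mc = int(mc_samples)
        self.lapse = float(lapse)
        self.alpha0 = float(alpha0)
        self.values = support.values.astype(np.float32)

        self.stimuli = trials["stimulus"].to_numpy(int)
        self.responses = trials["response"].to_numpy(int)
        self.fb_given = trials["feedback_given"].to_numpy(bool)
        self.fb_value = trials["feedback"].to_numpy(int)
        usable = (self.responses >= min_response) & np.array(
            [support.contains(r) for r in self.responses]
        )
        if not usable.any():
            raise ValueError("no usable trials after exclusions")
        self.usable = usable
        self.n_usable = int(usable.sum())
        self.resp_idx = np.array(
            [support.index(r) for r in self.responses[usable]], dtype=np.int64
        )
        self.resp_val = self.responses[usable].astype(np.float32)

        rng = np.random.default_rng(seed)
        z = rng.standard_normal((self.n_usable, self.mc)).astype(np.float32)
        self.logX = (
            np.log(self.stimuli[usable].astype(np.float32))[:, None]
            + np.float32(sigma) * z
        )
        self._inner_rng = np.random.default_rng(rng.integers(2**31))
        self._inner_u = None  # lazy uniforms for small-n super-model sampling

        n_elem = self.n_usable * self.mc * support.size
        self._cache_tensors = n_elem <= _CACHE_LIMIT
        if self._cache_tensors:
            self._logL = self._likelihood_block(slice(0, self.n_usable))
            self._expL = np.exp(self._logL)
        else:
            self._logL = self._expL = None
        self._prior_cache: dict = {}
        self._prob_cache: dict = {}

    # ----- likelihood tensors -------------------------------------------------

    def _likelihood_block(self, sl: slice) -> np.ndarray:
        # per-trial 2-D ops: large broadcast tensors are memory-bound here
        lv = np.log(self.values)
        c = np.float32(-1.0 / (2.0 * self.sigma**2))
        n = sl.stop - sl.start
        out = np.empty((n, self.mc, self.support.size), dtype=np.float32)
        for i, t in enumerate(range(sl.start, sl.stop)):
            d = self.logX[t][:, None] - lv
            np.multiply(d, d, out=out[i])
            out[i] *= c
        return out

    def _blocks(self):
        """Yield (slice, logL, expL) over usable trials, from cache or on the fly."""
        if self._cache_tensors:
            yield slice(0, self.n_usable), self._logL, self._expL
            return
        step = max(1, int(_CACHE_LIMIT / 4 / (self.mc * self.support.size)))
        for start in range(0, self.n_usable, step):
            sl = slice(start, min(start + step, self.n_usable))
            logL = self._likelihood_block(sl)
            yield sl, logL, np.exp(logL)

    # ----- prior trajectory ---------------------------------------------------

    def prior_trajectory(self, psi: float | None = None) -> np.ndarray:
        """Predictive prior before each usable trial, shape (n_usable, support).

        ``psi=None`` (or 0) is the Dirichlet update; otherwise the kernel
        update of width psi.  Feedback trials update the pseudo-counts after
        the trial; no-feedback trials leave them unchanged.
        """
        key = None if psi is None or psi == 0 else round(float(psi), 10)
        if key in self._prior_cache:
            return self._prior_cache[key]
        n = self.support.size
        alpha = np.full(n, self.alpha0)
        increments = {}
        out = np.empty((self.n_usable, n), dtype=np.float32)
        u = 0
        for t in range(len(self.stimuli)):
            if self.usable[t]:
                out[u] = alpha / alpha.sum()
                u += 1
            if self.fb_given[t]:
                fb = int(self.fb_value[t])
                if key is None:
                    alpha[self.support.index(fb)] += 1.0
                else:
                    if fb not in increments:
                        increments[fb] = kernel_increment(fb, key, self.support)
                    alpha += increments[fb]
        self._prior_cache[key] = out
        return out

    # ----- per-trial response probabilities ----------------------------------

    def trial_probs(
        self,
        prior_update: str = "dirichlet",
        psi: float = 0.0,
        decision: str = "sample",
        beta: float = 1.0,
    ) -> np.ndarray:
        """Decision-stage probability of each observed response (before the
        trembling/lapse mixtures), one entry per usable trial."""
        key = (prior_update, round(float(psi), 10), decision, round(float(beta), 10))
        if key in self._prob_cache:
            return self._prob_cache[key]
        prior = self.prior_trajectory(psi if prior_update == "kernel" else None)
        p = np.empty(self.n_usable)
        for sl, logL, expL in self._blocks():
            p[sl] = self._block_probs(sl, logL, expL, prior[sl], decision, beta)
        self._prob_cache[key] = p
        return p

    def _block_probs(self, sl, logL, expL, prior, decision, beta) -> np.ndarray:
        ridx = self.resp_idx[sl]
        n = prior.shape[0]
        if beta == 1.0:
            rowsum = np.einsum("umj,uj->um", expL, prior)
            if decision == "sample":
                rows = np.arange(n)
                num = expL[rows, :, ridx] * prior[rows, ridx][:, None]
                return (num / rowsum).mean(axis=1)
            if decision == "max":
                p = np.empty(n)
                for i in range(n):
                    p[i] = ((expL[i] * prior[i]).argmax(axis=1) == ridx[i]).mean()
                return p
            if decision == "mean":
                num = np.einsum("umj,uj->um", expL, prior * self.values[None, :])
                resp = np.floor(num / rowsum + 0.5)
                return (resp == self.resp_val[sl][:, None]).mean(axis=1)
            raise ValueError(f"unknown decision {decision!r}")
        # softmax-exponentiated posterior: q propto (L * prior)^beta; the
        # posterior normalizer cancels, so work with W = exp(beta*(logL+logprior))
        logprior = self._log_prior(prior)
        b = np.float32(beta)
        p = np.empty(n)
        rv = self.resp_val[sl]
        for i in range(n):
            W, rowsum = self._exp_posterior_row(logL[i], logprior[i], b)
            if decision == "sample":
                p[i] = (W[:, ridx[i]] / rowsum).mean()
            elif decision == "mean":
                p[i] = (np.floor((W @ self.values) / rowsum + 0.5) == rv[i]).mean()
            else:
                raise ValueError("softmax noise supports sample/mean decisions only")
        return p

    @staticmethod
    def _log_prior(prior: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(prior > 0, np.log(np.where(prior > 0, prior, 1.0)), -np.inf)

    @staticmethod
    def _exp_posterior_row(logL_t, logprior_t, beta):
        """W = (L*prior)^beta for one trial (mc x support), row-stabilized."""
        A = logL_t + logprior_t
        A *= beta
        A -= A.max(axis=1, keepdims=True)
        W = np.exp(A)
        return W, W.sum(axis=1)

    # ----- super-model --------------------------------------------------------

    def _inner_uniforms(self, n_small: int = 5) -> np.ndarray:
        if self._inner_u is None or self._inner_u.shape[2] < n_small:
            self._inner_u = self._inner_rng.random(
                (self.n_usable, self.mc, n_small), dtype=np.float32
            )
        return self._inner_u

    def supermodel_probs(self, psi: float, beta: float, n: int) -> np.ndarray:
        """Probability of each observed response under the super-model
        (rounded mean of ``n`` draws from the beta-exponentiated posterior).

        ``n=1`` is exact (Rao-Blackwellized over the single draw); ``2<=n<=5``
        uses literal seeded inner sampling of the n draws; larger ``n`` uses a
        CLT normal approximation with continuity correction for the mean.
        """
        key = ("super", round(float(psi), 10), round(float(beta), 10), int(n))
        if key in self._prob_cache:
            return self._prob_cache[key]
        prior = self.prior_trajectory(psi if psi and psi > 0 else None)
        p = np.empty(self.n_usable)
        for sl, logL, expL in self._blocks():
            p[sl] = self._block_supermodel(sl, logL, prior[sl], beta, n)
        self._prob_cache[key] = p
        return p

    def _block_supermodel(self, sl, logL, prior, beta, n) -> np.ndarray:
        ridx = self.resp_idx[sl]
        rv = self.resp_val[sl]
        logprior = self._log_prior(prior)
        b = np.float32(beta)
        v = self.values
        nt = prior.shape[0]
        p = np.empty(nt)
        u_all = self._inner_uniforms() if 2 <= n <= 5 else None
        for i in range(nt):
            W, rowsum = self._exp_posterior_row(logL[i], logprior[i], b)
            if n == 1:
                p[i] = (W[:, ridx[i]] / rowsum).mean()
            elif n <= 5:
                cdf = np.cumsum(W, axis=1)
                cdf /= cdf[:, -1:]
                u = u_all[sl][i]
                total = np.zeros(self.mc, dtype=np.float32)
                for k in range(n):
                    idx = (u[:, k, None] > cdf).sum(axis=1)
                    total += v[np.minimum(idx, len(v) - 1)]
                p[i] = (np.floor(total / np.float32(n) + 0.5) == rv[i]).mean()
            else:
                # CLT on the mean of n draws, with continuity correction
                mu = (W @ v) / rowsum
                ex2 = (W @ (v * v)) / rowsum
                sd = np.sqrt(np.maximum(ex2 - mu * mu, 0.0) / n)
                degenerate = sd < 1e-6
                sd = np.where(degenerate, 1.0, sd)
                pr = ndtr((rv[i] + 0.5 - mu) / sd) - ndtr((rv[i] - 0.5 - mu) / sd)
                pr = np.where(degenerate, np.floor(mu + 0.5) == rv[i], pr)
                p[i] = pr.mean()
        return p

    # ----- log-likelihood -----------------------------------------------------

    def mix_and_sum(self, p: np.ndarray, epsilon: float = 0.0) -> float:
        """Apply the trembling mixture and the lapse floor, sum the logs."""
        K = self.support.size
        if epsilon > 0:
            p = (1.0 - epsilon) * p + epsilon / K
        p = (1.0 - self.lapse) * p + self.lapse / K
        return float(np.log(p).sum())

    def loglik(
        self,
        model: CandidateModel,
        psi: float = 0.0,
        beta: float = 1.0,
        epsilon: float = 0.0,
    ) -> float:
        p = self.trial_probs(
            model.prior_update,
            psi,
            model.decision,
            beta if model.noise == "softmax" else 1.0,
        )
        return self.mix_and_sum(p, epsilon if model.noise == "trembling" else 0.0)


# ----- public operations ------------------------------------------------------


def response_pmf(
    model: CandidateModel,
    params: dict,
    prior_state: PriorState,
    stimulus: int,
    sigma: float,
    mc_samples: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Full response pmf over the support for a single trial.

    Simulates ``mc_samples`` internal estimates for the stimulus, runs the
    observer's inference and decision per draw, and mixes in the trembling
    noise (if any) and the 0.001 uniform lapse.  Sums to 1; every entry is at
    least ``lapse / support_size``.
    """
    support = prior_state.support
    if not support.contains(stimulus):
        raise ValueError(f"stimulus {stimulus} outside support")
    rng = np.random.default_rng(seed)
    logX = np.log(float(stimulus)) + sigma * rng.standard_normal(mc_samples)
    d = logX[:, None] - np.log(support.values.astype(float))[None, :]
    logL = -(d * d) / (2.0 * sigma**2)
    prior = prior_state.predictive()
    with np.errstate(divide="ignore"):
        logprior = np.where(prior > 0, np.log(np.where(prior > 0, prior, 1.0)), -np.inf)
    beta = float(params.get("beta", 1.0)) if model.noise == "softmax" else 1.0
    A = beta * (logL + logprior[None, :])
    A -= A.max(axis=1, keepdims=True)
    W = np.exp(A)
    rowsum = W.sum(axis=1)
    v = support.values.astype(float)
    if model.decision == "sample":
        pmf = (W / rowsum[:, None]).mean(axis=0)
    elif model.decision == "max":
        pmf = np.bincount(np.argmax(W, axis=1), minlength=support.size) / mc_samples
    elif model.decision == "mean":
        resp = np.floor((W @ v) / rowsum + 0.5).astype(int)
        idx = np.clip(resp - support.lo, 0, support.size - 1)
        pmf = np.bincount(idx, minlength=support.size) / mc_samples
    else:
        raise ValueError(f"unknown decision {model.decision!r}")
    eps = float(params.get("epsilon", 0.0)) if model.noise == "trembling" else 0.0
    if eps > 0:
        pmf = (1 - eps) * pmf + eps / support.size
    lapse = float(params.get("lapse", 0.001))
    pmf = (1 - lapse) * pmf + lapse / support.size
    return pmf / pmf.sum()


def session_log_lik(
    model: CandidateModel,
    params: dict,
    trial_table: pd.DataFrame,
    sigma: float,
    mc_samples: int = 10_000,
    seed: int = 0,
    evaluator: AncestralEvaluator | None = None,
) -> float:
    """Summed log-probability of the observed responses over usable trials
    (responses below 5 are excluded; the prior follows the feedback schedule)."""
    ev = evaluator or AncestralEvaluator(
        trial_table, sigma, mc_samples=mc_samples, seed=seed
    )
    return ev.loglik(
        model,
        psi=float(params.get("psi", 0.0)),
        beta=float(params.get("beta", 1.0)),
        epsilon=float(params.get("epsilon", 0.0)),
    )


def _profile_epsilon(ev: AncestralEvaluator, p: np.ndarray) -> tuple[float, float]:
    """Best trembling rate for fixed decision-stage probabilities."""
    res = minimize_scalar(
        lambda e: -ev.mix_and_sum(p, e),
        bounds=EPS_BOUNDS,
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x), -float(res.fun)


_SCALAR_OPTS = {"xatol": 2e-2, "maxiter": 25}


def fit_model(
    model: CandidateModel,
    trial_table: pd.DataFrame | None = None,
    sigma: float | None = None,
    seed: int = 0,
    mc_samples: int = 10_000,
    evaluator: AncestralEvaluator | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    Free parameters (0-2 of psi, epsilon, beta) are optimized on log/logit
    scales with bounded derivative-free searches; the trembling rate epsilon
    enters the likelihood as an exact uniform mixture, so it is profiled out
    in closed form at every outer evaluation.  BIC uses the number of
    non-excluded trials.
    """
    ev = evaluator or AncestralEvaluator(
        trial_table, sigma, mc_samples=mc_samples, seed=seed
    )
    params: dict = {}
    converged = True

    def probs(psi=0.0, beta=1.0):
        return ev.trial_probs(
            model.prior_update, psi, model.decision, beta if model.noise == "softmax" else 1.0
        )

    if model.prior_update == "dirichlet":
        if model.noise == "none":
            log_lik = ev.mix_and_sum(probs())
        elif model.noise == "trembling":
            eps, log_lik = _profile_epsilon(ev, probs())
            params["epsilon"] = eps
        else:  # softmax
            res = minimize_scalar(
                lambda lb: -ev.mix_and_sum(probs(beta=np.exp(lb))),
                bounds=tuple(np.log(BETA_BOUNDS)),
                method="bounded",
                options=_SCALAR_OPTS,
            )
            params["beta"] = float(np.exp(res.x))
            log_lik = -float(res.fun)
    else:  # kernel prior: psi is always free
        if model.noise == "softmax":
            # joint (log psi, log beta) simplex search
            def nll(x):
                return -ev.mix_and_sum(probs(psi=np.exp(x[0]), beta=np.exp(x[1])))

            x0 = np.array([np.log(1.0), np.log(2.0)])
            res = minimize(
                nll,
                x0,
                method="Nelder-Mead",
                options={"xatol": 2e-2, "fatol": 0.05, "maxiter": 60},
            )
            x = np.clip(
                res.x,
                [np.log(PSI_BOUNDS[0]), np.log(BETA_BOUNDS[0])],
                [np.log(PSI_BOUNDS[1]), np.log(BETA_BOUNDS[1])],
            )
            params["psi"] = float(np.exp(x[0]))
            params["beta"] = float(np.exp(x[1]))
            log_lik = ev.mix_and_sum(probs(psi=params["psi"], beta=params["beta"]))
            converged = bool(res.success) or res.status == 2  # maxiter is tolerated
        else:

            def neg(lpsi):
                p = probs(psi=np.exp(lpsi))
                if model.noise == "trembling":
                    return -_profile_epsilon(ev, p)[1]
                return -ev.mix_and_sum(p)

            res = minimize_scalar(
                neg,
                bounds=tuple(np.log(PSI_BOUNDS)),
                method="bounded",
                options=_SCALAR_OPTS,
            )
            params["psi"] = float(np.exp(res.x))
            p = probs(psi=params["psi"])
            if model.noise == "trembling":
                eps, log_lik = _profile_epsilon(ev, p)
                params["epsilon"] = eps
            else:
                log_lik = ev.mix_and_sum(p)

    M = ev.n_usable
    bic = -2.0 * log_lik + model.n_free * np.log(M)
    return FitResult(model, params, log_lik, float(bic), M, converged)


def compare_models(
    trial_table: pd.DataFrame,
    sigma: float,
    seed: int = 0,
    mc_samples: int = 10_000,
    models: list | None = None,
    evaluator: AncestralEvaluator | None = None,
) -> list:
    """Fit every candidate model on one session and rank ascending by BIC."""
    ev = evaluator or AncestralEvaluator(
        trial_table, sigma, mc_samples=mc_samples, seed=seed
    )
    results = [fit_model(m, evaluator=ev) for m in (models or candidate_models())]
    results.sort(key=lambda r: r.bic)
    return results


def fit_supermodel(
    trial_table: pd.DataFrame | None = None,
    sigma: float | None = None,
    seed: int = 0,
    mc_samples: int = 10_000,
    n_grid: tuple = SUPERMODEL_N_GRID,
    n_inits: int = 5,
    maxiter: int = 60,
    evaluator: AncestralEvaluator | None = None,
) -> SuperModelFit:
    """Fit the nested super-model: for each ``n`` on the grid, maximize the
    likelihood over (psi, beta) with random restarts; report the per-n optima
    and the globally best ``n``."""
    ev = evaluator or AncestralEvaluator(
        trial_table, sigma, mc_samples=mc_samples, seed=seed
    )
    rng = np.random.default_rng(seed)
    lpsi_b = np.log(PSI_BOUNDS)
    lbeta_b = np.log(BETA_BOUNDS)
    per_n = {}
    for n in n_grid:

        def nll(x):
            psi = float(np.exp(np.clip(x[0], *lpsi_b)))
            beta = float(np.exp(np.clip(x[1], *lbeta_b)))
            return -ev.mix_and_sum(ev.supermodel_probs(psi, beta, n))

        best = None
        for i in range(n_inits):
            if i == 0:
                x0 = np.array([np.log(0.5), np.log(2.0)])
            else:
                x0 = np.array(
                    [rng.uniform(np.log(0.01), np.log(5.0)), rng.uniform(np.log(0.5), np.log(30.0))]
                )
            res = minimize(
                nll,
                x0,
                method="Nelder-Mead",
                options={"xatol": 2e-2, "fatol": 0.05, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        x = np.array([np.clip(best.x[0], *lpsi_b), np.clip(best.x[1], *lbeta_b)])
        per_n[int(n)] = {
            "psi": float(np.exp(x[0])),
            "beta": float(np.exp(x[1])),
            "log_lik": -float(best.fun),
        }
    best_n = max(per_n, key=lambda n: per_n[n]["log_lik"])
    return SuperModelFit(per_n=per_n, best_n=int(best_n), n_trials_used=ev.n_usable)
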