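# Methods

## Observer model

The observer estimates an integer magnitude under Weber-law sensory noise.
Given stimulus S, the internal estimate X is lognormal:
log X ~ N(log S, sigma^2), sigma dimensionless (typical fitted values for
numerosity lie around 0.14-0.5).  The likelihood over integer candidates S on
the fixed response support [1:100] is the pure exponential kernel
exp(-(log X - log S)^2 / (2 sigma^2)).  We deliberately do **not** include a
1/S Jacobian: the lognormal density's Jacobian is 1/X, which is constant in
S and cancels under normalization.  The likelihood is strictly positive on
the whole support, so the posterior never collapses for any proper prior.

The prior is a Dirichlet-categorical: pseudo-counts alpha over [1:100] whose
normalization is the predictive prior.  The initial state is uniform,
alpha_0 = 1 per value (100 virtual observations), configurable.  This choice
is symmetric and proper, and is dominated by a few hundred feedback trials,
but it has a visible signature in simulations: the out-of-trained-range
prior mass decays like 100/(100+t) over trials, so even a perfectly
categorical learner emits ~1% out-of-range responses over a 10^4-trial
session (see "What passing tests show" below).

Prior updates after feedback i:

* Dirichlet: alpha_i += 1.
* Kernel: alpha += delta, delta_j = N(j; i, psi^2) / sum_j N(j; i, psi^2),
  a normalized Gaussian kernel on the **linear** integer scale.  psi -> 0
  recovers the Dirichlet update exactly; very large psi updates all values
  indiscriminately.  (A log-space variant of the kernel appears in some
  descriptions of this mechanism but is dimensionally inconsistent with the
  delta-alpha formula; we implement the linear form.)

Updates occur only on feedback trials; the posterior from trial t is not
itself carried forward.  No-feedback test blocks therefore freeze the prior.

Decision stage: softmax sharpening P^beta (computed in log space), then max
(ties broken to the smallest value, a measure-zero event under continuous
X), rounded posterior mean (round-half-up, since responses are integers and
the convention is otherwise arbitrary), a posterior sample, or the
super-model (rounded mean of n draws from the beta-exponentiated posterior).
Trembling-hand noise replaces the response with a uniform draw on [1:100]
with probability epsilon.  The 0.001 uniform lapse is a mixture component of
the model **likelihood** (it prevents -inf log-likelihoods); the generative
simulator injects it only on request.

## Discrimination fitting

2AFC choice probabilities have the closed form
Phi((log S1 - log S2)/(sigma sqrt 2)) under the larger-internal-estimate
rule.  The fitting objective instead uses Monte-Carlo simulation of the two
draws (the procedure used with the original data), with one fixed matrix of
standard-normal draws reused across every sigma evaluation (common random
numbers), which makes the objective deterministic and smooth so a bounded
scalar search (scipy's bounded Brent) is well-posed.  MC probabilities are
clipped to [1/(2m), 1-1/(2m)] for m samples.  Defaults: bounds (0.01, 2.0),
10,000 MC samples.  Degenerate sessions (near-flat likelihood, estimates
pinned at a bound) are flagged on the returned fit rather than raised.

## Trial likelihoods and model comparison

Response probabilities are estimated by ancestral sampling: mc_samples
internal-estimate draws per trial (default 10,000; recovery studies here use
150-1000), each pushed through inference and decision.  Three exactness
refinements reduce variance without changing the estimand:

* sample decisions are Rao-Blackwellized (average the exponentiated
  posterior row over X draws rather than histogram one response per draw);
* max and mean decisions are deterministic given X, so their counts are the
  literal procedure;
* trembling noise enters as the exact mixture (1-eps) p + eps/100, so eps is
  profiled out by a cheap inner search instead of re-simulation.

Responses below 5 are excluded as erroneous key presses (the smallest
stimulus is 23); BIC = -2 logL + N log(M) uses M = non-excluded trials.
One set of X draws per participant is shared across all models and parameter
values (common random numbers), so BIC differences are not MC noise.

Free parameters are searched on transformed scales (log psi, log beta,
logit-bounded epsilon) with derivative-free methods: bounded Brent for one
parameter, Nelder-Mead for (psi, beta).  Tolerances are xatol ~ 2e-2 in
transformed space with capped iteration counts: the MC objective's sampling
noise is orders of magnitude larger than what finer tolerances would
resolve, so tighter settings only burn function evaluations.

Super-model: for each n in {1, 2, 3, 4, 5, 10, 30, 100, 1000}, (psi, beta)
is maximized with random restarts (5 by default).  The inner mean-of-n
response distribution is computed exactly for n=1 (Rao-Blackwell), by
literal seeded sampling of the n draws for 2 <= n <= 5, and by a CLT normal
approximation with continuity correction for n >= 10, where the mean of n
draws is close to normal even for bimodal posteriors.  At beta ~ 1000 the
exponentiated posterior is near-degenerate and n is inconsequential for the
per-trial response probabilities; session log-likelihoods can still differ
across n through near-tied posteriors (an X draw landing between the two
prior peaks makes the mean-of-many land between them, which a single sample
never does) — a real property of the model family, not an artifact.

## Synthetic data: what it emulates and what it does not

The generator reproduces the trial structure of the three experiment
designs: bimodal narrow (23-29, peaks 0.3/shoulders 0.08), medium (23-32,
0.3/0.05), wide (23-35, 0.28/0.04), and quadrimodal (0.2 at 23/25/29/31,
0.1 at 24/30); sessions of 700-800 trials with feedback (quadrimodal runs
append a 200-trial no-feedback test block); and 2AFC blocks pairing anchors
(11 below the lowest trained value, or optionally 11 above the highest —
placement is a parameter) with offsets from
{-8,-4,-2,-1,1,2,4,8}.  Observers are simulated with known (sigma,
prior-update, decision, noise) so recovery is checkable.

Not emulated: display rendering (dot radius/density, rectangle geometry,
luminance, durations), practice trials, response times, or any
sequential/attentional effects.  Passing recovery tests therefore shows the
pipeline is consistent (it identifies the parameters and model class of data
generated under its own assumptions); it cannot show that real participants
satisfy those assumptions.

## Diagnostics

Conditional response distributions (CRDs) are column-normalized
P(response | stimulus) tables from trials after a burn-in (default 300,
1-based).  Predicted CRDs combine an idealized fully-learned prior of each
family — categorical (training probabilities), moment-matched Gaussian,
per-mode moment-matched Gaussian mixture, or Gaussian KDE with bandwidth psi
(the mode partition and component widths are under-determined and exposed as
parameters) — with one decision rule, integrating over X draws.

Quadrimodal diagnostics: an exact one-sided binomial test of responses in
{24, 30} against a 1/3 null; the zero-outside-range session probability
(1-p)^T; and the across-participant exact binomial upper tail
P(X >= k | n, p).  With p = 0.006 and T = 200 the session probability is
0.300; the exact 11-of-21 tail at p_zero = 0.3 is 0.0264 (a printed value of
.027 reflects rounding or a slightly different approximation).  The
mixture-alternative rate (five-component prior with one merged adjacent
pair) depends strongly on the unspecified component widths; the operation
exposes them (singleton_sd) and we verify only its qualitative behaviour
(near-delta components give a negligible rate; the rate grows with
component width).

## Softmax-sharpening diagnostic (acceptance script)

After 300 Dirichlet updates from the medium (23-32) training design, the
posterior at X = 23, sigma = 0.22 raised to beta = 2.7 concentrates ~91-92%
of its mass on the MAP (replicate-averaged).  We use the 23-32 range because
the sharpening illustration is anchored to it ("largest value 32"); the
narrow 23-29 design gives only ~72% because its second peak (29) is too
close in log-space to be suppressed at beta = 2.7.  The often-quoted >95%
arises only under a lognpdf-style 1/S-weighted likelihood with a vanishing
initial prior, which is statistically incorrect for this generative model
(see above), so this package reports the lower, correct value.

## Problem sizes used in the automated checks

Recovery studies in the test suite use sessions of 220-300 trials with
mc_samples 150-1000, 25 replicates/participants, and 1-2 optimizer restarts;
sigma recovery uses 100 replicates of 256 2AFC trials at 2000 MC samples.
These sizes were chosen so the full pipeline (simulation, all 16 fits, and
the 9-point super-model grid) runs end to end in minutes while leaving the
statistical margins of the recovery claims intact; the generating conditions
(training distributions, sigma = 0.22, noise settings, lapse) are the study
conditions and are never scaled.

## Known limitations

* The MAT loader is best-effort behind a user-supplied mapping spec; the
  deposited file's internal layout is not documented.
* CLT approximation for the super-model's n >= 10 inner stage slightly
  smooths tail probabilities of "between-peak" responses.
* The mixture-prior outside-range rate is not identified without committing
  to component widths; treat its absolute value as illustrative.
* mc_samples below ~500 makes count-based (max/mean) trial probabilities
  noticeably noisy for rare responses; the lapse floor bounds the damage at
  log(1e-5) per trial.
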