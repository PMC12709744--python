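# Methods

## Model and assumptions

The package's design-stage calculations assume an exponential
proportional-hazards core model: individual *i* has a constant event rate
η<sub>i</sub> with ln(η<sub>i</sub>) = μ<sub>i</sub> = α + δ·Σ<sub>p</sub>
β<sub>p</sub>x<sub>pi</sub>, so event times are exponential and the risk
by horizon *t\** is F<sub>i</sub>(t\*) = 1 − exp(−η<sub>i</sub>t\*). The
constant-hazard assumption buys closed-form variance decompositions and an
equivalent accelerated-failure-time reading (ln t<sub>i</sub> =
−μ<sub>i</sub> + ε<sub>i</sub>, ε extreme-value); it is a design-stage
approximation, not a claim about the final model. Censoring is assumed
independent of predictors and event times. Epistemic (sampling)
uncertainty only is quantified; aleatoric uncertainty and shrinkage /
penalised-estimation effects are out of scope, and parameter estimates are
assumed unbiased.

Note the rate and the risk function place *t* inside the exponent,
F(t) = 1 − exp(−exp(μ)·t): this is the standard exponential survival
function and the only form consistent with a 0.39 five-year risk at a
~0.099/year rate.

## Unit information

For design rows x<sub>i</sub> = (1, x<sub>1i</sub>, …, x<sub>Pi</sub>) the
unit (per-participant) Fisher information is estimated as the cohort mean
I = mean(x<sub>i</sub>′x<sub>i</sub>·w<sub>i</sub>) with weight
w<sub>i</sub> = t<sub>i</sub>·exp(μ<sub>i</sub>) — follow-up time times
model rate, i.e. exp(y<sub>i</sub> + μ<sub>i</sub>) on the log-time scale.
μ<sub>i</sub> is taken from the assumed-true core model (an option allows
fitted values for post-fit work). No analytic integration over predictor
distributions is attempted: the cohort *is* the estimator of the
expectation. Inversion uses a symmetric positive-definite (Cholesky)
factorisation behind a condition-number guard of 1e10; a singular or
near-singular matrix is a hard error naming the columns loading on the
near-null eigenvector, because a silently ill-conditioned inverse would
corrupt every downstream interval.

The MLE module provides the internal cross-check: on data simulated at the
true parameters, the inverse observed information of the Newton–Raphson
exponential fit converges entrywise to n⁻¹I⁻¹. The test suite also checks
the fit against an independent route (a Poisson GLM with offset ln t,
which shares the exponential likelihood).

## Calibration

Given relative weights and targets (C, overall risk), the search exploits
two structural facts: the analytic no-censoring concordance
C = (2/n(n−1))·Σ<sub>i<j</sub> max(η_i,η_j)/(η_i+η_j) is invariant to α
and non-decreasing in δ, with C(0) = 0.5. So the solve is two nested
bracketed scalar root finds (Brent): δ on an expanding bracket
[0, 1·2<sup>k</sup>] capped at 64, then α for the mean risk (strictly
increasing, bracket widened from [−5, 5]). Defaults tol_C = tol_risk =
0.001, 200 iterations — tight enough to reproduce three-decimal reporting
of (α, δ). The analytic C was chosen over Harrell's C on simulated
censored times because it is deterministic, fast and exactly δ-monotone,
which guarantees a unique outer root; the uncensored simulated Harrell's C
agrees with it within Monte-Carlo error (asserted in tests). Calibration
against time-dependent C statistics is not supported.

## Simulation and the fixture generator

Event times use inverse-CDF sampling t = −ln(U)/η. Censoring schemes:
none, exponential(rate), administrative(t_max), and a window scheme — no
censoring before t_min, censoring times uniform on [t_min, t_max] for a
fraction p_uniform (default 1.0) of individuals, the rest cut
administratively at t_max. Event/censoring ties count as events
(measure-zero under continuous models; favours information). Every
stochastic call takes an explicit seed; child streams are derived with
`numpy.random.SeedSequence` so runs are exactly reproducible.

The `gbsg_like` preset emulates a node-positive breast-cancer cohort with
five predictors / six parameters: age ~ N(53, 10²); tumour size ~
N(30, 14²) floored at 3 mm; positive nodes ~ round(lognormal(1.0, 0.9))
floored at 1; menopausal status Bernoulli with 26% pre-menopausal; grade
with probabilities (0.07, 0.67, 0.26) against reference grade 1. The three
continuous predictors share a Gaussian copula with modest correlations
(age–size 0.10, size–nodes 0.30, age–nodes 0.05); categoricals are drawn
independently. Relative weights (−1, 0.5, 2) on the standardised
continuous scale and (3, 3, 4) for post-menopause/grade 2/grade 3 are
calibrated to C = 0.70 and overall 5-year risk 0.39; censoring is
window(2, 7.28) years. These choices reproduce the intended operating
characteristics (mean follow-up ≈ 3.6 years, event rate ≈ 0.10 per
person-year, maximum follow-up 7.28 years).

What the fixture does **not** emulate: real between-predictor dependence
beyond a copula (in a real cohort menopausal status is strongly tied to
age, so subgroup contrasts — e.g. which menopause group has the larger
MAPE — can differ in direction from a cohort with that dependence);
non-constant baseline hazards; measurement error; missingness. Passing
tests therefore demonstrate correctness of the machinery under the assumed
exponential world, not transportability of any specific number to a given
real dataset.

## Intervals, misclassification, errors

Uncertainty intervals are formed on the μ scale (μ ± z·√var, z the normal
quantile at the requested level, 1.96 at 95%) and mapped through the
monotone risk function, so they always lie in [0, 1] and contain the true
risk by construction; μ-scale half-widths scale exactly as 1/√n.
Misclassification against threshold p\* defaults to the analytic form
Φ(−|μ−μ\*|/√var) with μ\* = ln(−ln(1−p\*)/t\*); the sampling construction
(draw risks from the uncertainty distribution, count the wrong side) is
retained as a Monte-Carlo cross-check and converges to it. An individual
whose true risk sits exactly on the threshold is assigned 0.5, the
symmetric limit. MAPE/RMSPE use 1000 seeded draws by default. Uncertainty
distributions are sampled per individual on the μ scale, which is
marginally identical to joint sampling of β̂ and far cheaper; joint
sampling would only matter for cross-individual summaries.

Required-*n* inversion (Option B): a width target at a risk band is
converted to a variance target by a bracketed root find on the μ-scale
standard deviation (the width is strictly increasing in it; solved to
1e-10), then n = x I⁻¹ x′ / var_target per individual. Individuals are
assigned the band closest to their true risk, ties to the lower band. The
cohort recommendation is the ceiling of the **maximum** over the target
individuals — the only combining rule that guarantees the width target for
all of them; percentile-style alternatives can be had by summarising the
per-individual column directly.

## Numerical and interface choices

- Standardisation uses the sample SD (n−1), matching how baseline
  characteristics tables report spread; the (mean, SD) pair is stored on
  the model so raw new individuals score identically.
- Missing values are rejected outright (no imputation): a silently
  imputed cell would bias the information matrix.
- Categorical predictors are dummy-coded against an explicit declared
  reference level; cohort CSVs are comma-separated, header row, UTF-8.
- Newton–Raphson starts at the intercept-only closed form
  ln(events/person-years) (the exact null MLE) with step-halving on any
  likelihood decrease; convergence is max|score| < 1e-8.
- Instability plots smooth the upper and lower bounds separately with
  LOWESS (span 0.3); axes are fixed to [0, 1]².
- The acceptance script uses a 10,000-individual cohort for design-stage
  quantities (large enough that cohort means estimate the expectations
  stably) and a 220-individual cohort for the post-fit MLE illustration,
  mirroring a pilot-study-sized dataset.

## Known limitations

No interval censoring, left truncation, competing risks, time-varying
covariates, predictor-dependent censoring, Weibull/spline baselines, or
net-benefit quantification. Exact third-decimal reproduction of any
published three-decimal calibration depends on unstated choices (C-index
estimator, draw counts) in the source analyses; the package's own
tolerances are stated above.
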