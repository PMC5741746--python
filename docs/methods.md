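# Methods

This note records the statistical models occumix implements, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Sampling frame and data model

The sampling unit is the **site-year**: one transect surveyed K times
within a season. Site-years are treated as independent, including repeat
years of the same site — a deliberate simplification that buys effective
sample size at small scales at the cost of possibly understating model
error when the same site appears in multiple years. Observations are
rectangular site-by-visit matrices with an explicit missing mask (NaN in
memory, empty cells in CSV), so ragged designs (3–8 visits per site-year)
are handled uniformly; missing visits contribute nothing to any likelihood.

Continuous covariates are standardised to mean 0, SD 1 on the analysis
sample, and the (mean, SD) pair is stored so new design points ("10 cover
objects") can be projected onto the training scale at prediction time.
Quadratic terms are squares of the *scaled* linear term. Categorical
covariates (the four habitat classes) are dummy-coded against the first
level in sorted order. Transect length is never a regression covariate; it
enters only as a log offset.

## Occupancy model

Latent occupancy z_i ~ Bernoulli(ψ_i); detections y_it | z_i ~
Bernoulli(z_i p_it), independent across visits and sites. Both parameters
use logit links. The occupancy linear predictor optionally carries a
log transect-length offset, making the intercept the per-km log-odds:
ψ(L) = invlogit(β0 + ln L). The logit-plus-log-offset form was chosen over
a complementary-log-log alternative because it reproduces the per-transect
occupancy column of the reference study from its printed per-km estimate
at every transect length. Closure (constant occupancy within the season)
is assumed; under random temporary emigration the estimate reinterprets as
probability of *use*.

The site likelihood marginalises z_i in closed form. Computation is fully
vectorised on the (sites × visits) grid using `log_expit` and
`logaddexp` for stability; a site with all-zero history mixes the occupied
branch with (1 − ψ_i).

## N-mixture model

Latent abundance N_i ~ f(·; λ_i, θ) with log(λ_i) = b0 + b·z_i + ln L_i
(so b0 is log abundance per km), and y_it | N_i ~ Binomial(N_i, p_it).
Mixtures: Poisson; negative binomial with dispersion parameterised as
log(size), recovering Poisson as size → ∞; zero-inflated Poisson with the
zero-inflation weight on a logit scale, recovering Poisson at weight 0.
The infinite sum over N is truncated at Kmax = 50 by default; every fit
re-evaluates its own optimum at 2·Kmax and warns if the negative
log-likelihood moves by more than 1e-6 (at the study's abundance scale the
movement is ~0, confirming 50 is ample). Counts above Kmax are a hard
error rather than silent truncation. A boundary dispersion estimate
(|log size| > log 1e6) is flagged because near-boundary NB fits are known
to be unstable.

## Estimation numerics

Both models are maximised with L-BFGS-B (ftol 1e-12, gtol 1e-8) from a
zero-coefficient start plus four seeded N(0, 0.5²) random restarts; the
best optimum wins and the convergence flag is taken from the optimizer,
never silently upgraded. Warm-started refits (bootstrap and GOF loops) use
zero restarts from the parent optimum. The covariance matrix is the
inverse of a central finite-difference Hessian (relative step 1e-4) of the
negative log-likelihood; a singular or indefinite observed information
triggers a warning and a pseudo-inverse fallback. Degenerate data (no
detections anywhere; a detection on every visit; all-zero counts) produce
boundary warnings, and such fits are excluded from candidate ranking.

Probability-scale intervals (detection, occupancy) are computed as normal
intervals on the linear predictor via the delta method and back-transformed
through the inverse logit, which keeps them inside [0, 1] and asymmetric,
matching field convention. Abundance-intercept intervals are Wald on the
log scale.

## Model selection and goodness of fit

AICc = −2LL + 2k + 2k(k+1)/(n−k−1). The effective n follows the reference
workflow: the number of surveys (132 in the packaged design) for
detection-model comparisons, the number of site-years (19) for occupancy
and abundance. Akaike weights are exp(−Δ/2) normalised; rank ties break
toward fewer parameters.

Goodness of fit is Pearson's χ² over observed site-visit cells —
occupancy: mean ψ̂p̂ with Bernoulli variance; N-mixture: mean E[N]p̂ with
the mixture-marginal variance p(1−p)E[N] + p²Var(N) — referred to a
parametric-bootstrap null (simulate from the fit, refit, recompute).
The overdispersion ratio is ĉ = observed χ² / bootstrap mean, the standard
parametric-bootstrap estimator. When ĉ from the most complex candidate
exceeds 1, ranking switches to QAICc: the deviance is divided by ĉ and one
parameter is charged for estimating ĉ (so a 2-parameter model reports
k = 3). Published QAICc tables in this workflow tabulate the
*quasi-adjusted* log-likelihood LL/ĉ; occumix's `qaicc` takes the raw
log-likelihood and performs the division itself. Estimated ĉ below 1 is
clamped to 1 with a warning (underdispersion is not exploited).

## Empirical-Bayes abundance

P(N_i = n | y_i) ∝ f(n; λ̂_i, θ̂) ∏_t Bin(y_it | n, p̂_it) on n = 0..Kmax.
The point summary is the posterior mean (the empirical best unbiased
predictor); the interval is the central 95% posterior interval on the
integer support (0.025/0.975 quantiles of the posterior CDF). Because the
posterior has zero mass below the site's maximum observed count, the mean
never falls below it. Total abundance is the sum of posterior means; its
95% CI is the 2.5/97.5 percentile band of that sum over parametric-
bootstrap replicates (default 1000), each refit warm-started at the parent
optimum for speed and stability, with failed refits dropped, counted, and
warned about above a 10% failure rate. An independent minimum-known-alive
count (photo identification) may replace a lower confidence bound that
falls below it; a minimum above the upper bound is treated as a
contradiction, not clipped.

## Survey-effort and power calculators

Confidence of absence inverts p\* = 1 − (1−p)^K: K_min =
⌈ln(1−C)/ln(1−p)⌉, with a one-step floating-point guard around the
boundary. The ceiling convention reproduces the reference study's
low-effort requirement triple (8/11/15 surveys at p = 0.19 for 80/90/95%
confidence) exactly. Confidence bands map the detection CI endpoints
through K_min anti-monotonically (upper K from lower p). Planning grids
may extend beyond the observed effort range (e.g. to 500 cover objects);
this is permitted but flagged as extrapolation.

The decline power analysis uses the standard asymptotic variance of the
occupancy MLE under imperfect detection,
v(ψ, p, K) = ψ[(1−ψ) + (1−p\*)/(p\* − K p (1−p)^(K−1))], which reduces to
ψ(1−ψ) at p = 1 and blows up as the design approaches non-identifiability
(K = 1 is always non-identifiable and rejected). Sites per period:
S = ⌈(z_{1−α} + z_{1−β})² (v1 + v2) / (ψ1 − ψ2)²⌉ with ψ2 = ψ1(1−R),
equal site numbers in both periods, and a one-tailed test by default
(two-tailed available). Because no closed-form reference was printed for
this procedure, its correctness is arbitrated by a brute-force simulated
power search in the test suite (independent sufficient-statistic MLE,
plug-in variance z-test); the formula and the search agree within
simulation error on spot-checked cells. Site-count CI bands propagate the
(p, ψ1) interval endpoints jointly through the formula — the optimistic
band pairs both upper endpoints — matching the bracketed site ranges
convention rather than a delta method.

## Synthetic-data generator

`occumix.simulate` draws survey frames and observations with precisely the
models' generative structure. Defaults mirror the packaged study: 19
site-years, visits uniform on 3–8, cover-object counts and transect
lengths resampled with replacement from the fixture (preserving their
skew — parametric alternatives were rejected because the length
distribution is strongly right-skewed with a 19.1 km outlier that matters
for offset behaviour). Occupancy histories use ψ from the per-km intercept
plus offset; counts draw one N per site (closure by construction) and
binomially thin it per visit. An `availability < 1` option injects
temporary emigration (per-visit available subpopulation ~
Binomial(N, availability)) for robustness experiments; it is off by
default.

What the generator deliberately does **not** emulate: spatial structure
(sites are exchangeable; no point process for animals), individual
heterogeneity in detection, behavioural responses to surveying,
between-year dependence of repeated sites, and observation error in
covariates. Passing recovery and calibration tests therefore demonstrate
correctness of the estimators *under the models' own assumptions* at the
study's scale — not robustness to the assumption violations that real
snake data may carry.

## Packaged fixture

The fixture transcribes the 19 Jersey grass-snake site-year records
(habitat, area, visits, cover objects, transect length) plus the published
per-transect estimate columns used as regression anchors. Two documented
data decisions: (1) the source table's visit column sums to 134,
contradicting the study-wide totals (132 surveys, 12,335 cover-object
checks, 613 km); the single minimal edit that reconciles all three totals
simultaneously — J-2015 from 8 to 6 visits — is applied, with the printed
value preserved in `n_visits_printed`. (2) Site-level detected flags are
not printed as a list; they are derived from the published abundance
posterior intervals (the empirical-Bayes posterior has zero mass below the
maximum observed count, so a lower bound ≥ 1 holds exactly when the
site-year had a detection), yielding 11 detected site-years and naive
occupancy 0.58, both matching the published summary. Per-visit histories
were never published, so likelihood-level regression tests use synthetic
data.

## Problem sizes used in validation

Likelihood oracles enumerate ≤ 4 sites × ≤ 3 visits (exhaustive state
sums, agreement to 1e-10). Recovery/coverage experiments run 200 seeded
replicates at the 19-site-year design; GOF calibration uses 200 replicates
with 50-simulation bootstraps; total-abundance CI coverage uses 20
replicates with 40-simulation bootstraps; the power-formula search uses
250 simulated tests per candidate grid point on three cells. These sizes
make Monte-Carlo error small relative to the assertion bands while keeping
the whole suite a few minutes of single-core runtime.

## Known limitations

- Occupancy predictions are unconditional; detection-history-conditioned
  ("given we saw nothing in 5 visits") occupancy is not provided.
- Single-season only: no colonisation/extinction dynamics across years.
- Intervals are Wald/delta-method or percentile-bootstrap; no profile
  likelihood.
- N-mixture estimates from sparse counts carry a known small-sample
  positive bias and wide intervals, and the effective sampled area of a
  transect is unknown — abundance is "associated with the transect", not a
  density over a defined area; spatial capture-recapture or distance
  sampling would be needed for that.
- The candidate-set convention limits models to one covariate per
  parameter by default (relaxable via `max_one_covariate=False`).
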