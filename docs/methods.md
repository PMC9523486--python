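# Methods

## Problem

Tumor mutation burden (TMB, somatic mutations per megabase) is used to
stratify patients receiving immune-checkpoint inhibitors, but the number
of cutpoints and their locations are contested: the two standard
efficacy endpoints — objective response (CR/PR vs SD/PD under RECIST)
and a right-censored time-to-event (PFS/OS) — can disagree in strength
and even direction, the endpoints are correlated within a patient, and
TMB itself is measured with error.  `tmbcat` categorizes TMB by
maximizing the between-subgroup discrepancy of a *joint*
response-and-survival prognosis, selected by a minimal-p-value
criterion.

## Joint endpoint model

For patient *i* with observed burden `x_i`:

* response: `R_i ~ Bernoulli(expit(b0 + b1 x_i + u_i))`
* hazard: `h_i(t) = h0(t) exp(alpha x_i + v_i)` (Cox; Breslow ties and
  Breslow baseline `H0`)
* `(u_i, v_i)` zero-mean Gaussian with covariance `Sigma`.

Each patient contributes one Bernoulli draw and one censored time, so
the full bivariate pair `(u_i, v_i)` is weakly identified; the default
shares a single effect, `v_i = gamma * u_i` with `u_i ~ N(0, sigma_u^2)`
and the loading `gamma` estimated.  The endpoint correlation is then
`sign(gamma)`.  A full bivariate `Sigma` is available via
`FitOptions(random_effects="bivariate")` but is markedly harder to
identify at these data densities; only `gamma * sigma_u` (the hazard-side
effect scale) and the sign of the cross-correlation are well determined,
not the (sigma_u, gamma) split.

### Estimation

We maximize the Laplace-approximate marginal likelihood.  The inner
step solves for the posterior modes of the random effects by damped
Newton on the penalized joint log-likelihood (logistic log-likelihood +
Cox partial log-likelihood + Gaussian penalty); the outer quasi-Newton
(L-BFGS-B) step moves `(b0, b1, alpha, gamma, log sigma_u^2)` against
the profiled objective plus the curvature correction
`-0.5 * sum_i log(1 + sigma_u^2 (W_i + gamma^2 Q_i))`, with `W_i` the
Bernoulli weight and `Q_i` the diagonal Cox information.  Two points
matter here:

* the curvature term is not optional: the penalized likelihood alone is
  unbounded along `gamma -> inf, u -> 0` (the hazard frailty escapes the
  penalty), and the log-determinant term restores identifiability;
* the likelihood is bimodal in the sign of the endpoint correlation, so
  the loading is seeded from the sign of the correlation between
  logistic residuals and martingale residuals of a fixed-effects-only
  fit.

Defaults: outer tolerance 1e-6, at most 200 outer iterations, variance
floor 1e-6.  A parsimony rule compares the optimum against the
fixed-effects-only fit and collapses the random-effect structure to the
variance floor when its log-likelihood gain is below one point per
extra parameter (AIC-scale); without it, flat directions in
`(sigma_u^2, gamma)` leave spurious small heterogeneity in no-signal
data.  The accepted-iterate trace of the outer optimizer is stored and
is non-decreasing up to line-search tolerance.

With the random effects disabled the objective factorizes and the
estimates agree with separate logistic/Cox fits to ~1e-9 (tested
against statsmodels and lifelines).

### Joint probability modes

`Pr(R_i = 1, T_i* > T0)` is exposed in three forms:

* `integrate` — Gauss-Hermite marginal (15 nodes per axis) over the
  random-effect law; bounded in [0, 1], monotone non-increasing in
  `T0`, but a *deterministic function of TMB*;
* `plugin` — the literal product of the two component probabilities at
  the empirical-Bayes modes times the random-effect density factor; can
  exceed 1, intended only for rank-based statistics;
* `eb` (pipeline default) — the product of the component probabilities
  at the empirical-Bayes modes, without the density factor; bounded in
  [0, 1] and patient-specific.

The default matters.  Between-group testing needs probabilities that
carry each patient's own endpoint information: a deterministic monotone
function of TMB is *always* "significantly" different across TMB-defined
groups (the fitted-slope magnitude cancels from the F ratio), so the
marginal form is unsuitable for the discrepancy stage and is kept for
prognosis curves and landmark summaries.  `T0` defaults to the median
observed follow-up.

## Discrepancy statistics

Given per-patient probabilities and subgroup labels induced by a
threshold vector (half-open intervals; a TMB equal to a cutpoint joins
the upper group):

* **Variance ratio** `D = (SS_b/k) / (SS_w/(n-k-1))`, p from the upper
  tail of `F(k, n-k-1)` — one-way ANOVA.
* **Rank statistic** `D = 12/(n(n+1)) sum_j RA_j^2/n_j - 3(n+1)` with
  mid-ranks for ties, p from the upper tail of `chi^2(k)` — the
  Kruskal-Wallis form.  The classical tie-correction divisor is
  available but off by default.  A warning is issued when any subgroup
  has five or fewer patients.
* **Similarity statistic** on an `n x n` patient-distance matrix
  (Euclidean for scalar probabilities; Mahalanobis, by default with the
  sample covariance, for the weighted two-dimensional form
  `[w1 p_R, w2 p_T]`): rank all pairs, then
  `D = (r_between - r_within) / (n(n-1)/4)`, which lies in [-1, 1] and
  equals the classical ANOSIM R (cross-checked against scikit-bio).
  The p-value is a seeded label permutation test with the add-one
  estimator `(1 + #{D_perm >= D_obs}) / (1 + n_perm)`; default 9999
  permutations.

Rank-based statistics are invariant to strictly monotone transforms of
scalar probabilities.  The similarity statistic is *not* (distance
orderings between disjoint intervals can flip under non-affine monotone
maps); it is invariant to positive affine maps, relabeling, and patient
reordering, which is what the tests assert.

## Threshold search and number of thresholds

Candidate cutpoints are the distinct observed TMB values between the
5th and 95th percentiles, thinned to at most 20 quantile-spaced values
(configurable).  Because threshold vectors are ordered, the search
space is C(m, k) combinations, enumerated exhaustively for k up to 4;
candidates inducing any subgroup below `min_group_size` (default 6,
matching the rank-test validity guard) are skipped.  The winner is the
minimal p-value, ties broken by larger D and then smaller thresholds;
permutation p-values draw per-candidate seeds from one master seed, so
results are bit-reproducible.  A simulated-annealing strategy with
local index moves and restarts is available for large C(m, k) and
reaches the exhaustive optimum on ≥95% of benchmark instances
(tested).

The number of thresholds is chosen stepwise: move from k to k+1 only
while the minimal p decreases, stopping at the first non-improvement.
No multiplicity correction is applied across candidates — the minimal-p
criterion *is* the method — so the searched p-value is optimistic; the
studies below quantify this rather than hide it.

## Measurement error

Observed burden: `TMB = TMB* + e`, `e ~ N(0, sigma_e^2)`, homoscedastic
and independent of the endpoints; `sigma_e` is supplied by the user or
estimated from duplicate measurements (`var(W1 - W2) = 2 sigma_e^2`).
Two corrections:

* **Regression calibration** (default): replace observations by
  `mu + lambda (W - mu)` with `lambda = (s^2 - sigma_e^2)_+ / s^2` and
  refit.  If `s^2 <= sigma_e^2` the calibrated values collapse to the
  mean with a strong warning.
* **Corrected score**: Nakamura-type deflation `exp(alpha W - alpha^2
  sigma_e^2/2)` of the Cox risk terms with the shifted covariate
  `W - alpha sigma_e^2` in the score, and the first-order corrected
  logistic score; solved for the fixed effects with the random effects
  held at their calibration-fit modes, falling back to calibration when
  the root search diverges (e.g. large `alpha * sigma_e`).

Both reduce exactly to the naive fit at `sigma_e = 0`.

## Synthetic cohorts

The generator draws lognormal true burden (median 8 mut/Mb, log-SD 0.6
— a realistic pan-cancer shape), correlated effects `(u, v)`, the
Bernoulli response, an exponential-baseline proportional-hazards event
time by inverse transform (median ~6 months at the baseline rate
0.115/month), independent exponential censoring (rate 0.04/month)
capped administratively at 36 months, and observed burden with additive
normal error truncated at zero.  Effects of TMB on each endpoint scale
are declarative piecewise functions stored in versioned YAML presets:

* `consistent` — response +1.8 logit and hazard −1.2 log units above
  10 mut/Mb (n=150): one threshold is optimal;
* `inconsistent` — response +1.5 logit above 7; hazard +1.6 in the
  7–14 band and −0.8 above it (n=180): two thresholds are optimal;
* `null` — flat effects with realistic heterogeneity retained
  (sigma_u = 1, gamma = −0.8, ORR ~30%).

Effect sizes were fixed once to realize the intended qualitative
scenarios at moderate signal-to-noise and then frozen.  The generator
also exposes the latent-truth joint probabilities (computed from the
generative parameters and latent draws), used as the oracle input to
the calibration and recovery studies.

What the generator does *not* emulate: panel-size-dependent TMB noise,
heteroscedastic or multiplicative error, informative censoring,
covariates other than TMB, and multicategory response.  Passing tests
therefore demonstrate correctness of the machinery under the stated
generative model, not clinical performance.

## Study conditions and problem sizes

Chosen to characterize the method at desk scale; all seeds derive from
one integer via `SeedSequence`:

* permutation-null calibration: 200 replicates of n=30 with 999
  permutations; KS distance to U(0, 1) tested at the 1% level;
* type-I error: 1000 null-scenario replicates (n=100), ANOVA statistic
  on the latent-truth probabilities at a prespecified median cut
  (nominal 5% holds) and at the min-p-searched cut (inflated to
  roughly 25–30% — the selection optimism of the criterion, reported,
  not corrected);
* threshold-count recovery: 50 replicates per scenario, search over
  k = 1..3 at T0 = 6 months with 20 candidates and a minimum subgroup
  of 15 patients (~10% of the cohort, the study's operationalization of
  clinical meaningfulness);
* parameter recovery: 100 replicates at n = 200 and n = 1000 under a
  correctly specified shared-effect truth (b1 = 0.5, alpha = −0.3,
  sigma_u = 0.5, gamma = 1);
* error correction: 200 replicates at n = 1000, reliability 0.7 on a
  unit-SD burden scale, true response slope 0.6.

## Known limitations

* **Estimated probabilities re-use the data.**  Model-estimated
  per-patient probabilities contain the fitted TMB slope; even with a
  prespecified cut, between-group tests on them reject far above the
  nominal level (~44% measured at n=100 under the null).  Calibration
  statements in this package therefore refer to tests on probabilities
  that are exchangeable with respect to the grouping (e.g. the
  latent-truth oracle); p-values from the full estimated pipeline
  should be read as ranking scores, not calibrated error rates.
* **Smooth probabilities invite over-splitting.**  The probability
  model is linear in TMB, so planted step effects are smoothed into
  monotone trends, and the stepwise rule then tends to add a third
  subgroup when fed fitted probabilities.  The threshold-count studies
  characterize the selection machinery on the generative probabilities.
* **Correction overshoot at moderate information.**  Regression
  calibration rescales the naive slope by 1/lambda-hat, so whenever the
  naive estimate fluctuates above `2*lambda*beta/(1+lambda)` the
  corrected estimate is farther from the truth than the naive one.
  Under the study conditions (ORR ~31%) this happens in ~12% of
  replicates — the corrected estimator wins in ~88%, not ≥90%; only at
  higher Fisher information (response rates nearer 50%) does the rate
  clear 90%.  The corrected estimator's *mean* recovers the truth
  (0.594 vs 0.6 at reliability 0.7) while the naive mean sits at the
  attenuated value (0.418 vs 0.42).
* **Variance-split identifiability.**  With one observation per
  endpoint per patient, `sigma_u` and `gamma` trade off; inference
  should rely on `beta`, `alpha`, the product `gamma * sigma_u`, and
  the sign of the correlation.
* The plugin mode's density factor makes it a non-probability score; it
  is retained for fidelity to the formula and for rank-based use.
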