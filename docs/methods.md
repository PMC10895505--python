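# Methods

## Estimands

`intervmed` decomposes the total effect of a randomised treatment A ∈ {0, 1}
on a continuous outcome Y (12-month PHQ-9 score) into an interventional
direct effect and one interventional indirect effect per *mediator block*.
The default structure has three ordered blocks:

* **B1 sessions** — M1a, phase of counselling completed (0 none, 1–3 phases);
  M1b, proportion of homework completed (0 none, 1 ≤50%, 2 >50%);
* **B2 activation** — M2, behavioural activation (BADS-SF score, continuous);
* **B3 response** — M3a, responded to treatment (0/1); M3b, extra sessions
  offered on non-response (0, 1, 2).

M1a, M1b, M3a and M3b exist only under treatment; in the control arm they sit
at a degenerate "unexposed" reference category. Interventional effects handle
this naturally: instead of each subject's own counterfactual mediator value,
the estimand sets mediators to *random draws* from their counterfactual
distribution given baseline covariates. This keeps the effects identified
even when the causal ordering among mediators is unknown, at the price of a
population-level rather than individual-level interpretation.

With G_k(a) a draw of block k's mediators from its fitted distribution at arm
level a, and g the outcome model's prediction function, the per-subject,
per-copy contrasts are

```
TE  = g(1, G1(1), G2(1), G3(1)) − g(0, G1(0), G2(0), G3(0))
DE  = g(1, G1(0), G2(0), G3(0)) − g(0, G1(0), G2(0), G3(0))
IE1 = g(1, G1(1), G2(0), G3(0)) − g(1, G1(0), G2(0), G3(0))
IE2 = g(1, G1(1), G2(1), G3(0)) − g(1, G1(1), G2(0), G3(0))
IE3 = g(1, G1(1), G2(1), G3(1)) − g(1, G1(1), G2(1), G3(0))
```

averaged over all subjects and Monte-Carlo copies. Because every draw
G_k(a) is reused in each contrast in which it appears, the telescoping sum
DE + IE1 + IE2 + IE3 = TE holds *exactly* on every run, not just in
expectation — additivity is a structural property of the implementation,
verified to float accuracy in the tests. The proportion mediated through a
block is 100·IE_k/TE, refused (not returned as a number) when |TE| < 1e-6.

## Estimation

1. **Imputation.** Missing M2 and Y (assumed MAR) are filled by single
   stochastic chained-equation imputation, run separately by trial arm, with
   10 burn-in sweeps. Each chain step is a Bayesian linear regression:
   σ² drawn from its scaled inverse-χ² posterior, coefficients from their
   normal posterior, missing values from the posterior predictive — never
   conditional-mean fills. Default predictors: all baseline covariates, the
   other chained variable, and the treated-only mediators (which are
   constant, hence dropped, in the control stratum). Imputed Y is truncated
   to the score support [0, 27]. Imputation runs exactly once inside each
   bootstrap resample, with a resample-specific seed.
2. **Mediator models.** Linear for M1a (on its 0–3 codes) and M2,
   proportional-odds logit for M1b and M3b, logistic for M3a. Treated-only
   mediators are fitted on treated-arm records only; M2 is fitted on both
   arms with arm as a predictor. Within-block dependence is kept by
   including the declared parent as a predictor (M1b ← M1a, M3b ← M3a) and
   drawing parents first; across blocks, draws are conditionally independent
   given arm and covariates. All mediator models adjust for age, education,
   marital status (indicator contrasts), treatment expectations and baseline
   PHQ-9.
3. **Outcome model.** Linear in arm, all mediators (multi-level categorical
   mediators as indicator contrasts against the unexposed reference), and
   mediator–outcome confounders chosen by greedy forward AIC search among
   the baseline covariates. Interaction terms (arm×mediator or
   mediator×mediator) can be configured; the default is none. Effects are
   mean differences, so predictions use the linear predictor without integer
   clamping.
4. **Monte-Carlo integration.** Each subject is expanded into `m_copies`
   copies (default 1000). Common random numbers are on by default: the same
   uniform/normal variates drive a mediator's draws at both arm levels,
   which reduces variance and, for the continuous mediator under an
   additive outcome model, makes IE2 equal the product of the fitted
   arm→M2 and M2→Y coefficients exactly.
5. **Uncertainty.** Nonparametric bootstrap resampling *clinics* with
   replacement (the trial randomised individuals within ten clinics, and the
   bootstrap accounts for that clustering), keeping each drawn clinic's full
   membership, with the whole pipeline — fresh imputation, refits,
   decomposition — re-executed per resample. Intervals are bias-corrected
   percentile (BC, no acceleration): z0 = Φ⁻¹((#{θ* < θ̂} + ½#{θ* = θ̂})/B),
   bounds at the empirical quantiles Φ(2z0 + z_{α/2}) and Φ(2z0 + z_{1−α/2})
   with linear interpolation between order statistics. z0 is clamped to
   ±Φ⁻¹(1 − 1/(2B)) when all replicates fall on one side; failed resamples
   are dropped and counted, never retried.

## Numerical choices

* Proportional-odds fitting uses a damped Newton iteration on the analytic
  gradient and Hessian (the log-likelihood is concave in slopes and
  cutpoints), with an L-BFGS fallback on a log-difference cutpoint
  parametrisation. Separated fits — common in small bootstrap strata, and
  structural for M3b given M3a (responders never receive extra sessions) —
  are refitted with a weak ridge (1e-4) on the slopes and flagged.
  Logistic fits use statsmodels and fall back to the same ridged solver.
* Linear draws for M1a are rounded nearest-integer half-up and clamped to
  {0,…,3}; ordinal draws invert the cutpoint-implied CDF; logistic draws are
  Bernoulli at the predicted probability. A mediator constant in its fitting
  data yields a point-mass model with a warning.
* AIC forward selection adds the candidate with the largest AIC decrease and
  stops when no candidate strictly decreases AIC; for linear families the
  criterion is computed from cached design columns (ordering identical to
  the statsmodels value).
* Rank deficiency in the outcome design — e.g. treated-only indicators
  spanning the arm column when no treated subject sits at the reference —
  is detected by pivoted QR and reported with the offending columns named.
* All randomness flows from a single top-level seed expanded into named
  child streams (generator, imputation, Monte-Carlo, bootstrap); identical
  configuration and seed reproduce byte-identical outputs.

## Synthetic-data generator

The generator emulates the trial that motivates the package: n = 493
subjects (equal permuted allocation) across 10 clinics; baseline age,
education, marital status, expectations, and PHQ-9 > 14 (eligibility);
treated-only mediators with the structural zeros above (homework requires a
session; extra sessions only for non-responders); Gaussian clinic-level
outcome intercepts; MAR missingness targeting marginal rates of 5.7% (M2)
and 9.3% (Y).

Category mediators arise from latent Gaussian propensities cut at
thresholds; M1b depends on M1a, M2 on M1a/M1b, M3a on M2, M3b on M3a,
mirroring the intervention's temporal logic (coefficients configurable, so
independence is a special case). The outcome is linear and additive in the
mediator codes, which gives the ground truth the closed form
IE_k = Σ_m b_m·(E[m|a=1] − E[m|a=0]); the mediator mean shifts are
evaluated by a Monte-Carlo oracle over 200 000 simulated subjects (SE of
order 0.002), or in fully closed form when only the M2 path is active.
Default path coefficients were set so the true effects resemble the scale
of a real behavioural-activation trial: direct −2.3, sessions +2.0,
activation −0.7, response −1.0, total ≈ −2.0 PHQ-9 points, with ~65%
response and most completers reaching phase 3. PHQ-9 values are left
continuous by default so this closed form is exact; an `integer_scores`
flag rounds and clamps them to 0–27 for realism demonstrations.

What the generator does *not* emulate: the deposited dataset's exact
covariate distributions, the clinical non-response algorithm (M3a follows a
logistic model — only the joint distribution matters for testing the
estimator), informative missingness (MNAR), or measurement error in
counsellor-recorded mediators. Passing tests therefore certify the
estimation machinery under a known MAR, correctly-structured world, not
robustness to those real-data features.

## Known limitations

* **Draw-model approximation for M1a.** Modelling a skewed 4-category
  mediator as linear-with-rounded-Gaussian-draws cannot reproduce an
  arbitrary category distribution. Under the default generator this leaves
  a systematic offset of about −0.1 PHQ-9 points in the sessions indirect
  effect (and hence the Monte-Carlo total) in the large-sample limit —
  a property of the published family choice, visible in the consistency
  test against the regression-based total.
* Block attribution is order-dependent in principle; with the default
  additive outcome model the decomposition is invariant to block order up
  to Monte-Carlo error (tested), but configured interactions make the
  order (fixed to sessions → activation → response, matching the temporal
  logic) substantive.
* BC (not BCa) intervals: no acceleration correction, and the trial has
  only ten clinics to resample. Bootstrapping so few clusters is known to
  understate interval width; the package's own coverage simulation (200
  replicate trials) observes ~87–89% coverage for the total effect at
  nominal 95%, and a control run with an unbiased mean-difference
  estimator through the same bootstrap shows nearly all of the shortfall
  comes from the 10-cluster resampling itself. Interpret the intervals
  accordingly; acceleration or cluster-t corrections are out of scope.
* Single stochastic imputation nested in the bootstrap is the published
  design; Rubin's-rules multiple imputation is deliberately out of scope.

## Simulation sizes used in the test suite

The acceptance-style tests scale the published sizes down to stay
desk-runnable: product-of-coefficients at n = 5000, m = 2000; null-path
checks as 12 replicates at n = 2000, m = 150 per block; parameter recovery
as 100 replicates at n = 500, m = 200; bootstrap coverage as 200 replicate
trials with B = 150, m = 30 (complete data); imputation calibration as 100
replicates at n = 5000. `scripts/acceptance.py` runs the full published
protocol (B = 1000 resamples, m = 1000 copies) on the n = 493 default
trial.
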