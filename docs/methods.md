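# Methods

## Model and procedure

The core object is a linear protein score. For a cohort matrix **X**
(n patients × 5 concentrations in nM, columns Bak, Bax, Bcl2, BclXL, Mcl1)
and a weight row **W** ∈ [−1, 1]⁵, the per-patient score is β = XWᵀ. Risk
stratification is always *below-cutoff = high risk*: anti-apoptotic proteins
receive negative weights, so a low β means a high anti-apoptotic burden and
a poor prognosis. Raw clinical factors (single proteins, protein sums, age)
are stratified the other way around, *above-cutoff = high risk*; the
orientation is therefore an explicit argument everywhere and never inferred
from the data.

### Cross-validation by survival-time dealing

Patients are sorted by ascending overall survival time (stable sort; ties
keep their original row order) and dealt round-robin into k = 5 folds: the
patient with the i-th smallest OS goes to fold i mod k. Every fold spans the
whole survival range, so per-fold survival distributions are homogeneous by
construction. The scheme contains no randomness; each fold's set of OS ranks
is exactly an arithmetic progression with step k, which the tests assert.

### Weight search and objective

Each training set (4 of 5 folds) is searched exhaustively over the Cartesian
grid with one-decimal steps, 21⁵ = 4,084,101 candidates, enumerated
lexicographically from (−1, −1, −1, −1, −1). For each candidate, β is
stratified at its own mean and at its own median and a univariate Cox model
(Efron ties) is fitted to each split. The objective is

    min(HR_mean, HR_median)   if both Wald p < 0.05, else −∞.

The combination rule is a design choice of this package: requiring both
cutoffs to be simultaneously significant and maximizing the weaker of the
two HRs enforces weight vectors whose stratification is strong at *both*
cutoffs rather than only one, and it is the rule under which every per-fold
optimum also shows large HRs at both cutoffs on the full data. The objective
is pluggable (`alpha`, and `fold_objective` can be swapped). Ties on the
objective are broken by the larger HR_mean + HR_Median sum, then by the
lexicographically smallest candidate, making the search fully deterministic
and order-independent; the five fold searches are independent and give
identical results run sequentially or concurrently.

The five fold optima are averaged componentwise into W\* (two-decimal
components from one-decimal fold weights). β\* = XW\*ᵀ over the full cohort
is z-normalized — sample standard deviation, n−1 denominator, matching the
conventional z-score in the R/Python stacks — into the Risk Score RS. The
mean cutoff is 0 by construction; the median cutoff is stored from the
training cohort so that new patients are scored against the training
normalization. Because z-normalization is a positive affine map, RS-based
cutoff labels coincide exactly with β\*-based labels, which the tests assert
bit-for-bit.

### Cox fits, Kaplan-Meier, log-rank, t-tests

The univariate binary-covariate Cox fit is an in-package Newton maximization
of the Efron partial likelihood. With one binary covariate the risk-set sums
reduce to group counts, so the gradient and observed information have closed
forms and the solver runs *batched* across all grid candidates of a chunk at
once (suffix-sum risk-set statistics, one Newton iterate per candidate
vector) — the full 21⁵ grid on a 50-patient training set runs in about a
minute on one CPU. Convergence is |gradient| < 1e−12 (relative), step
clipped to ±2, coefficient clipped to ±30; an empty group, a no-event
stratum, or a diverging estimate (complete separation) yields a flagged
non-converged result, never an exception, and the search treats it as −∞.
The solver agrees with lifelines to ~1e−7 on the coefficient (lifelines
stops earlier near flat optima, so cross-solver test tolerances are 1e−3 on
HRs) and with a scalar golden-section oracle to ~1e−8. Confidence intervals
are Wald on the log scale with z = 1.959964; p-values are two-sided normal.

Multivariate Cox models are delegated to lifelines (same Efron convention),
with categorical covariates expanded against fixed reference levels female /
LVI no / T2&3 / N1 / left location, listwise deletion of missing covariates,
and constant-after-deletion covariates dropped with a warning. Kaplan-Meier
curves and two-group log-rank tests are lifelines; the Welch t-test is
scipy's `ttest_ind(equal_var=False)`.

### Regression baselines

Six linear models (OLS, ridge, lasso, LassoLars, elastic net with mixing 0.5,
Bayesian ridge) regress raw OS on the five concentrations under the OS-sorted
folds; out-of-fold predictions are assembled into a per-patient predicted OS
and stratified at its mean/median (below = high risk). Penalized methods
select their penalty *inside each training fold* with sklearn's CV-selector
classes (RidgeCV, LassoCV, LassoLarsCV, ElasticNetCV) and their default
candidate grids; the inner CV uses the estimators' default fold handling.
Censoring is ignored in the regression target — censored times enter as
observed survival — so predicted OS is a ranking marker, not a calibrated
survival time; this is a deliberate fidelity choice and a statistical caveat.

### Outcomes, hybrid score, single-protein predictor

Favorable outcome = censored/alive (event 0) and is the positive class;
RS ≥ 0 predicts favorable (the boundary is favorable). The confusion summary
satisfies accuracy = sensitivity·prevalence + specificity·(1−prevalence)
exactly. The hybrid score Comb = β\* + Σ wᵢ·featureᵢ adds clinical features
on their raw scales (age in years; categorical features contribute a
per-level weight) before z-normalization into RS_H; feature weights are
either supplied or grid-searched over the same [−1, 1] one-decimal grid with
the same objective. The single-protein predictor bins one protein's
concentrations into equal-count bins (default 10, ≥5 patients per bin; the
bin count is a config knob since no canonical value exists), computes the
fraction of patients with OS below the cohort median per bin — note this
"high risk" definition differs from the RS-based one — and fits a
least-squares line of bin risk vs bin mean concentration, clamped to
[0, 100]% at prediction time.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: correlated
log-normal concentrations (nM order of magnitude, medians ≈ 10–40 nM,
log-sds 0.4–0.5, modest positive correlations), exponential event times with
log-hazard = log(h₀) + s·(w_true·x), independent exponential censoring, and
a 60-month administrative cap. The default configuration targets the study
shape: n = 134, event fraction ≈ 0.29 (39/134), protective true weights
(0, 0, 0, −0.9, −0.5) with s = −0.09 so that the per-protein true log-hazard
coefficients s·w are **positive** for BclXL and Mcl1 (higher anti-apoptotic
concentration ⇒ higher hazard) — the orientation the recovery tests assert.
h₀ = 1.45e−4/month and censor rate 2e−3/month were calibrated once by Monte
Carlo against the 0.29 event-fraction target. A Weibull shape knob (default
1 = exponential) and an optional age–hazard coupling exist for
proportional-hazards-preserving variations.

What the generator does **not** emulate: real RPPA concentration scales and
their measurement error, protein–clinical-covariate dependence (covariates
are independent of proteins by default), non-proportional hazards, and
informative censoring. Passing tests therefore demonstrate correctness of
the machinery and recoverability under the assumed model, not clinical
performance on real cohorts.

## Problem sizes and tolerances in the tests

Grid-search/brute-force equivalence uses 3⁵-candidate grids on 30-patient
subsets (oracle: per-candidate lifelines loop). Parameter recovery runs 20
seeded n=500 cohorts with a 0.5-step grid, asserting negative recovered
BclXL/Mcl1 components in ≥95% of replicates and corr(β̂\*, true predictor)
> 0.9 in each. The complete 21⁵ grid is exercised once on a 50-patient
cohort as a scaled-down smoke test. Exact assertions (fold dealing,
z-normalization, label invariance, confusion identities) use 1e−10–1e−12
tolerances; Monte-Carlo assertions use ±0.02–0.05 bands chosen from the
binomial/normal sampling error of the stated replicate counts.

## Known limitations

- The search maximizes an in-sample hazard ratio; even with the fold scheme,
  full-data HRs of the averaged weights are optimistically biased, and the
  p < 0.05 admissibility gate adds a selection effect. The package reports
  what the procedure computes and leaves inference caveats to the user.
- Weight identifiability is only up to the grid resolution and protein
  scaling: multiplying one protein's concentrations by c > 0 maps the
  optimal weight region by 1/c (asserted exactly in the tests), so weights
  are comparable only within one assay calibration.
- No proportional-hazards diagnostics are performed.
- The regression baselines' treatment of censoring (ignored in the target)
  biases predicted OS downward for long survivors.
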