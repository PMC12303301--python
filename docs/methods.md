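# Methods

`hybridcox` derives and validates absolute-risk survival models of the kind
used for primary-prevention cardiovascular risk scoring on electronic health
records: a machine-learned risk score embedded in a classical proportional-
hazards frame, so the model both discriminates well and emits interpretable
hazard ratios and calibrated 10-year risks. This note records the model, its
assumptions, the defaults and why, what the synthetic cohorts do and do not
emulate, and the numerical choices made where the design was genuinely open.

## The hybrid model

Let `T` be time to the first composite event, `h(t|x) = h0(t) exp(lp(x))` a
proportional-hazards model. The package fits two flavors:

* **basic** — `lp(x) = β'x_m` over the eight *mandatory* clinical variables
  (age, sex, HDL-C, dyslipidemia, atrial fibrillation, hypertension,
  diabetes, chronic kidney disease), by ridge-penalized Cox partial
  likelihood (penalty `λ`, default `1e-4` per observation — numerically
  stabilizing, statistically negligible at derivation scale).
* **full** — `lp(x) = β'x_m + γ·s(x)` where `s(x)` is the *boosted risk
  score*: a gradient-boosted tree ensemble over all eligible covariates
  (~100), trained against the gradient and Hessian of the negative Cox
  partial log-likelihood with Breslow handling of ties. For subject `j`,

      grad_j = exp(lp_j) · Σ_{event times u ≤ t_j} d_u / S(u)  −  event_j
      hess_j = exp(lp_j) · Σ d_u/S(u)  −  exp(2·lp_j) · Σ d_u/S(u)²

  with `S(u) = Σ_{k: t_k ≥ u} exp(lp_k)`. Gradients sum to zero (the score
  identity); both are verified against finite differences of the partial
  log-likelihood in the test suite. The objective is a pluggable hook
  (`objective_fn`), so alternative losses can be substituted without
  touching the fitting code; the default is the plain Cox objective.

The score entering the stacking stage is **out-of-fold** by default
(10-fold, event-stratified): each subject is scored by an ensemble that
never saw them, which keeps the stacked coefficient `γ` honest. An
in-sample switch exists (`boosted_score=None` path).

Absolute risk uses the Breslow baseline: `risk(h) = 1 − S0(h)^exp(lp − c)`
with `S0` the baseline survival at the training-mean covariates and `c` the
training-mean linear predictor. The baseline is a right-continuous step
function; beyond the last observed time the last value is carried forward.

### Boosting defaults

Depth 3, learning rate 0.07, 300 rounds, `colsample_bytree` 0.8,
**no row subsampling** (`subsample = 1.0`), L2 leaf penalty 1.0, single
thread, histogram trees. Row subsampling was found to cripple greedy
splitting on interaction structure with weak marginal effects (on a pure
`x1·x2` hazard, out-of-fold C fell from ~0.67 to ~0.53 when subsampling
0.8 of rows), so the derivation default disables it; the grid used by
`tune` (depth {2,3,4} × rate {0.05,0.1} × rounds {100,300}) remains
available and configurable. `tune` selects by mean out-of-fold Harrell's C
with ties broken toward fewer rounds, then shallower trees.

### Hazard-ratio inference

Wald CIs and p-values come from the penalized information matrix and are
therefore approximate under ridge; output metadata flags them as such. The
boosted-score coefficient is reported per score unit (the score is itself a
log relative hazard, so a well-calibrated ensemble yields `γ ≈ 1`; a
constant-score ensemble is dropped with `γ = 0`, which makes the full model
collapse exactly to the basic one — property-tested).

## Preprocessing

* **Screening.** Numeric variables qualify below 10% missingness, binary
  flags above 1% prevalence; mandatory and mandatory-imputable fields are
  always kept. Screening is monotone in both thresholds (property-tested).
* **MICE.** Eligible numeric variables with missing values are completed by
  chained equations with predictive-mean-matching draws (statsmodels'
  engine; donor pool k = 5, 10 iterations between snapshots, m = 5 — none
  of these are dictated by the problem, all are config-exposed and follow
  common practice). Binary flags are treated as complete
  (absent-equals-zero EHR coding) and act as predictors only. Models
  downstream fit on the first completed dataset by default; a
  pool-across-m mode (coefficient averaging) exists for the linear stage.
  Boosted ensembles have no analogue of Rubin's rules, which is why
  per-dataset fitting is the default.
* **Prediction-time imputation.** A single subject with missing mandatory
  labs is completed with the derivation cohort's population means (computed
  over observed values only).
* **LASSO shortlisting.** L1-penalized Cox over a 40-point penalty path,
  penalty chosen by 5-fold cross-validated partial likelihood; surviving
  variables are refit unpenalized and the shortlist keeps refit p < 0.05
  plus all mandatory fields. "L1 selection with p-values" is contradictory
  on its face; the two-stage select-then-refit reading is the only one that
  produces both, and is what is implemented. Under a global null this
  two-stage procedure selects ~0 variables on average (the CV penalty
  collapses the path to the empty model), comfortably inside the nominal
  0.05 × p budget (tested over 20 seeds).

## Validation suite

* **Harrell's C** — usable pairs are those where the shorter follow-up ends
  in an event (a censored subject tied in time with an event counts as
  surviving at least as long); risk ties score ½. Equivalent to an O(n²)
  pair enumeration (tested on random instances with tied times and risks).
* **Decile calibration** — subjects ranked by predicted risk into 10
  equal-count groups (identical predictions stay together even if counts
  become unequal; fewer than 10 distinct values coarsens with a warning);
  observed risk is 1 − KM(h) per group with Greenwood CIs. The
  **calibration slope** is the OLS slope of observed on predicted over the
  decile points (ideal 1). **Calibration-in-the-large** is defined on the
  risk scale — overall KM risk minus mean predicted risk (ideal 0); other
  literatures use a logistic intercept, and the risk-scale choice is
  deliberate because the recalibration acceptance rule compares it
  directly before and after.
* **Brier score** — inverse-probability-of-censoring weighted at the
  horizon: events before `h` weighted by `1/G(T⁻)`, survivors by `1/G(h)`,
  early-censored subjects weighted out (`G` = censoring KM). Reduces
  exactly to the plain MSE without censoring; matches scikit-survival's
  implementation to 1e-10 on random instances.
* **Decision curves** — net benefit `TP/n − FP/n · p/(1−p)` on thresholds
  0.01–0.50 (step 0.01, the relevant range for 10-year primary
  prevention); TP/FP among flagged subjects are estimated with a KM fit
  inside the flagged group, so the curve is censoring-aware. Treat-all and
  treat-none references included; treat-none ≡ 0.
* **Bootstrap** — subject-level percentile CIs (not BCa), default B = 1000,
  seeds always recorded in report metadata.
* **Repeated CV** — event-stratified k-fold with a fresh shuffle per
  repeat; one pooled out-of-fold metric per repeat.
* **Recalibration** — a slope multiplier for the centered linear predictor
  (Cox fit of the original predictor on the target cohort) plus a target-
  cohort Breslow baseline; the intercept shift is reported on the
  log-cumulative-hazard scale at the horizon. The update is accepted only
  if neither |slope − 1| nor |CITL| worsens — an explicit operationalization
  of "recalibrate if it improves the calibration curve".

The out-of-fold comparison of flavors (`workflows.compare_flavors_oof`)
is symmetric: the boosted score is built 10-fold out-of-fold once, then
*both* flavors' ridge-Cox stages are evaluated by 5-fold stratified CV, so
neither flavor's concordance sees its own training labels.

## Synthetic study conditions

The generator (`simulate.default_params`) draws wide cohorts from a Weibull
proportional-hazards model (shape 1.1, scale calibrated once so the
cumulative event fraction sits near 13%), with covariates from per-block
Gaussian copulas (lipids, glycemic, blood-pressure, renal, liver, blood-
count blocks, exchangeable ρ 0.35–0.6), administrative censoring at 15
years plus exponential dropout (rate 0.085/yr → median follow-up ≈ 7 y).
It emulates a contemporary East-Asian primary-prevention EHR cohort: ~55%
female, median age 58, 103 covariates (8 mandatory, 8 mandatory-imputable,
supplementary labs/flags spanning 0.5–65% prevalence), labs mostly < 10%
missing plus three high-missingness fields (CRP, neutrophils, vitamin D at
45–60%), missingness MCAR or MAR through a logistic dependence on a fully
observed covariate (the mechanism under which chained-equation imputation
provably beats mean imputation — tested).

True effects: the eight mandatory log hazard ratios are fixed at the
field-typical values carried in `DEFAULT_TRUE_HR` (age 1.04/y, female 0.62,
HDL 0.70 per mmol/L, dyslipidemia 1.89, AF 1.60, hypertension 1.19,
diabetes 1.29, CKD 2.04). On top sit supplementary effects that only the
full model can exploit: a few concentrated linear effects (smoking, eGFR,
INR, creatine kinase), two U-shaped electrolyte effects
(`curvature·(x−center)²` on potassium and sodium) and two standardized
pairwise interactions (triglycerides×glucose, creatine kinase×potassium),
together ≈ 0.30 of log-hazard variance, kept statistically independent of
the mandatory block.

Two deliberate deviations from published-cohort descriptives, made at
design time and worth stating plainly:

* **Mandatory flag prevalences** (dyslipidemia 0.30, AF 0.15, hypertension
  0.45, diabetes 0.30, CKD 0.18) are set higher than typical *coded* EHR
  prevalences. Coded 1%-prevalence flags carry SE(log-HR) ≈ 0.2 at 20,000
  subjects and ~2,600 events — no estimator could recover their hazard
  ratios to ±10%; the chosen prevalences give every mandatory flag enough
  events for parameter-recovery testing to be meaningful at that scale.
* **Independence of the supplementary signal from the mandatory block.**
  Real supplementary biomarkers correlate with mandatory comorbidities;
  here they are kept independent so the mandatory-only fit stays a
  consistent estimator of its own coefficients. Even so, omitting real
  signal attenuates Cox coefficients toward the null (non-collapsibility);
  at these conditions the attenuation is ~3–7% of each log hazard ratio,
  which is the dominant systematic error in recovery checks.

What passing tests therefore show: the machinery is correct under a
well-specified proportional-hazards world with MAR labs and independent
supplementary signal. What they do not show: robustness to informative
censoring (an optional switch exists but is off by default), to
time-varying effects (out of scope), to correlated confounding between
supplementary and mandatory variables, or to real ICD/BNF coding noise —
the long-format path is exercised only by small hand-built record streams.

## Numerical choices and degenerate inputs

Ties in event times: Breslow throughout (objective, partial likelihood,
baseline). Time is internally days in cohort assembly, years = days/365.25.
Same-day entry and outcome: excluded (zero follow-up breaks the survival
machinery). KM at t = 0 is 1; beyond the last observed time the estimate is
carried forward. A constant risk vector collapses decile calibration to one
group and makes the slope an explicit error. A censoring KM that reaches 0
before the horizon makes the Brier score an explicit error with guidance.
The thresholds grid silently drops values outside (0, 1). All randomness
flows through explicit integer seeds; one pipeline seed is split into
per-stage substreams with `numpy.random.SeedSequence`. The chained-equation
engine uses numpy's legacy global generator internally, so
`mice_fit_transform` seeds it explicitly — calls are reproducible but do
perturb global RandomState.

## Problem sizes used in the shipped checks

Parameter recovery and the flavor comparison run at n = 20,000 (the scale
at which a single derivation fit is both informative and quick);
self-consistency calibration at n = 50,000 and miscalibration recovery at
n = 30,000 (large enough that Monte-Carlo noise in slope/CITL is an order
of magnitude below the acceptance bands); marginal checks of the generator
at n = 100,000. These sizes are the package's choices for a desk-scale
demonstration; derivation-scale EHR cohorts are one to two orders larger.
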