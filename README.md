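# hybridcox

Hybrid statistical/machine-learning survival risk modelling for EHR-style
cohorts: a gradient-boosted Cox risk score stacked into a ridge-penalized
Cox proportional-hazards model, with the full derivation and validation
machinery around it — cohort assembly from longitudinal records,
chained-equation imputation, penalized variable shortlisting,
discrimination/calibration/decision-curve validation, and a synthetic-cohort
generator with known ground truth so every stage is testable without
patient data.

It is written for biostatisticians and epidemiologists building
absolute-risk prediction models (e.g., 10-year cardiovascular risk for
primary prevention) who want machine-learned flexibility *and* the
classical outputs a clinical audience expects: hazard ratios with CIs,
calibrated absolute risks, decision curves.

## The model

With `h(t|x) = h0(t) exp(lp(x))`, the package fits:

* **basic** — `lp(x) = β'x_m` over eight mandatory clinical variables, by
  ridge-penalized Cox partial likelihood;
* **full** — `lp(x) = β'x_m + γ·s(x)`, where the boosted risk score `s(x)`
  is a tree ensemble over all eligible covariates trained with the Cox
  partial-likelihood objective (gradient `exp(lp_j)·Σ_{u≤t_j} d_u/S(u) −
  event_j`, Breslow ties), entered out-of-fold as a single covariate.

Absolute risk at horizon `h` is `1 − S0(h)^exp(lp − c)` with a Breslow
baseline `S0` and centering constant `c`. Validation covers Harrell's C
(bootstrap CIs), decile calibration against Kaplan–Meier observed risk
(slope, calibration-in-the-large), IPCW Brier score, decision-curve net
benefit, recalibration (intercept + slope, accepted only if calibration
does not worsen), and 100×10-fold CV / bootstrap machinery.

## Worked example

Derive both flavors on a synthetic cohort and validate on a fresh one
(`examples/03_derive_hybrid_model.py`, `examples/04_validate_and_compare.py`):

```python
from hybridcox import default_params, simulate, compare_models
from hybridcox.workflows import derive_models, impute_eligible

derivation, _ = simulate(default_params(n=8_000), seed=6)
models = derive_models(derivation, seed=7)

validation, _ = simulate(default_params(n=8_000), seed=8)
completed, _, _ = impute_eligible(validation, seed=9)
table, curves = compare_models({"basic": models.basic, "full": models.full},
                               completed.df, horizon=10, B=100, seed=10)
print(table.round(3))
```

prints

```
model     c  c_lo  c_hi  calibration_slope  citl  brier
basic 0.671 0.656 0.685              0.949 0.007  0.129
 full 0.709 0.695 0.724              1.005 0.008  0.123
```

— the full flavor discriminates better (C 0.71 vs 0.67) while both stay
calibrated (slope near 1, calibration-in-the-large near 0); the lower Brier
score means more accurate absolute risks overall. The basic model's hazard
ratios recover the generator's truth, e.g. age 1.04 (1.04–1.05) against a
true 1.04, dyslipidemia 1.78 (1.57–2.01) against 1.89.

The other examples cover simulation (`01`), screening + imputation (`02`)
and cohort assembly from long-format records with an exclusion ledger
(`05`). A thin CLI composes the same pipeline from a shell:

```bash
hybridcox simulate --n 20000 --seed 7 --out cohort.csv --catalog catalog.yaml
hybridcox preprocess --cohort cohort.csv --catalog catalog.yaml --seed 7 \
    --out completed.csv --report eligibility.json
hybridcox derive --cohort completed.csv --catalog catalog.yaml \
    --flavor full --seed 7 --out model.json
hybridcox validate --model model.json --cohort cohort.csv \
    --catalog catalog.yaml --seed 7 --B 1000 --out report.json
```

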