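"""End-to-end derivation workflows shared by the CLI, examples and scripts.

These compose the pipeline stages — eligibility screening, chained-equation
imputation, boosted-score construction, stacking — with the package's
derivation defaults, and provide the standard out-of-fold comparison of the
basic (mandatory-only) and full (mandatory + boosted score) flavors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable
from .hybrid import Hyperparams, StackedModel, fit_boosted, fit_stacked, oof_scores
from .preprocess import ImputationModel, mice_fit_transform, screen_variables
from .validate import harrells_c, repeated_cv

# Derivation defaults: full-sample bagging-free boosting (subsampling is
# counterproductive for weak-marginal interaction structure), mild learning
# rate, enough rounds to exhaust the partial-likelihood gradient signal.
DERIVATION_HP = Hyperparams(max_depth=3, learning_rate=0.07, n_rounds=300,
                            subsample=1.0, colsample=0.8)

SCORE_FOLDS = 10  # out-of-fold boosted-score construction
EVAL_FOLDS = 5  # out-of-fold model evaluation
STACK_RIDGE = 1e-4  # per-observation L2 penalty of the stacking Cox fit


@dataclass
class DerivedModels:
    completed: CohortTable
    imputation: ImputationModel
    eligible: list[str]
    basic: StackedModel
    full: StackedModel
    oof_score: np.ndarray


def impute_eligible(cohort: CohortTable, seed: int, m: int = 1,
                    iterations: int = 5) -> tuple[CohortTable, ImputationModel, list[str]]:
    """Screen variables and MICE-complete the eligible ones (first dataset)."""
    eligible = screen_variables(cohort).eligible_names
    completed, imp = mice_fit_transform(cohort, variables=eligible, m=m,
                                        iterations=iterations, seed=seed)
    return completed[0], imp, eligible


def derive_models(cohort: CohortTable, seed: int,
                  hp: Hyperparams = DERIVATION_HP) -> DerivedModels:
    """Full derivation: impute, boost out-of-fold, stack both flavors."""
    completed, imp, eligible = impute_eligible(cohort, seed)
    df = completed.df
    times, events = completed.times, completed.events
    mand = cohort.catalog.mandatory_names
    score = oof_scores(df, times, events, eligible, hp, folds=SCORE_FOLDS, seed=seed)
    boosted = fit_boosted(df, times, events, eligible, hp, seed=seed)
    means = {v: float(df[v].mean()) for v in cohort.catalog.numeric_names if v in df.columns}
    basic = fit_stacked(df, mand, lam=STACK_RIDGE, flavor="basic", imputation_means=means)
    full = fit_stacked(df, mand, boosted=boosted, boosted_score=score,
                       lam=STACK_RIDGE, flavor="full", imputation_means=means)
    return DerivedModels(completed=completed, imputation=imp, eligible=eligible,
                         basic=basic, full=full, oof_score=score)


def compare_flavors_oof(cohort: CohortTable, seed: int,
                        hp: Hyperparams = DERIVATION_HP) -> tuple[float, float]:
    """Out-of-fold Harrell's C of the basic and full flavors.

    The boosted score is built out-of-fold once; both flavors are then
    evaluated by event-stratified k-fold cross-validation of their ridge-Cox
    stage, so neither flavor's concordance sees its own training labels.
    """
    completed, _, eligible = impute_eligible(cohort, seed)
    df = completed.df.copy()
    times, events = completed.times, completed.events
    mand = cohort.catalog.mandatory_names
    # carried as a plain covariate column here so each CV fold can refit the
    # ridge-Cox stage over it like any other predictor
    df["oof_score"] = oof_scores(df, times, events, eligible, hp,
                                 folds=SCORE_FOLDS, seed=seed)

    def _fit_predict(columns):
        def fp(train, test):
            m = fit_stacked(train, columns, lam=STACK_RIDGE, flavor="basic")
            return m.predict_risk(test)
        return fp

    c_basic = repeated_cv(df, _fit_predict(mand), harrells_c,
                          k=EVAL_FOLDS, repeats=1, seed=seed)[0]
    c_full = repeated_cv(df, _fit_predict(mand + ["oof_score"]), harrells_c,
                         k=EVAL_FOLDS, repeats=1, seed=seed)[0]
    return float(c_basic), float(c_full)
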