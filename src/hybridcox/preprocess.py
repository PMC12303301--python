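"""Variable screening, imputation and penalized variable shortlisting.

The pipeline order mirrors common EHR risk-model derivation practice:

1. *screening* — numeric variables are eligible when under 10% missing,
   binary flags when their prevalence exceeds 1%; mandatory fields are always
   eligible;
2. *chained-equation imputation* (MICE with predictive-mean-matching draws)
   fills missing numeric labs to produce ``m`` completed datasets; binary
   history flags are treated as complete (absent-equals-zero coding);
3. *population-mean imputation* handles single subjects at prediction time:
   missing mandatory labs are replaced by derivation-cohort means;
4. *LASSO shortlisting* — an L1-penalized Cox path with the penalty chosen by
   cross-validated partial likelihood, followed by an unpenalized refit of
   the surviving variables; the shortlist keeps refit p < 0.05 plus every
   mandatory variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from sklearn.model_selection import KFold
from statsmodels.imputation.mice import MICEData

from .cohort import CohortTable
from .hybrid import cox_partial_loglik


# ---------------------------------------------------------------------------
# eligibility screening
# ---------------------------------------------------------------------------

@dataclass
class EligibilityReport:
    """Per-variable screening outcome."""

    table: pd.DataFrame  # variable, kind, rate, eligible, reason
    missing_threshold: float
    event_threshold: float

    @property
    def eligible_names(self) -> list[str]:
        return self.table.loc[self.table["eligible"], "variable"].tolist()


def screen_variables(
    cohort: CohortTable,
    missing_threshold: float = 0.10,
    event_threshold: float = 0.01,
) -> EligibilityReport:
    """Screen covariates on completeness (numeric) / prevalence (binary).

    Numeric: eligible iff missing rate < ``missing_threshold``.
    Binary: eligible iff prevalence > ``event_threshold``.
    Mandatory and mandatory-imputable fields are always eligible.
    """
    rows = []
    for var in cohort.catalog:
        col = cohort.df[var.name]
        forced = var.mandatory or var.mandatory_imputable
        if var.kind == "numeric":
            rate = float(col.isna().mean())
            ok = rate < missing_threshold
            reason = f"missing rate {rate:.3f} {'<' if ok else '>='} {missing_threshold}"
        else:
            rate = float((col == 1).mean())
            ok = rate > event_threshold
            reason = f"event rate {rate:.3f} {'>' if ok else '<='} {event_threshold}"
        if forced and not ok:
            ok, reason = True, "mandatory override"
        rows.append(dict(variable=var.name, kind=var.kind, rate=rate, eligible=ok, reason=reason))
    return EligibilityReport(pd.DataFrame(rows), missing_threshold, event_threshold)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationModel:
    """Fitted imputation state: chain settings plus derivation-cohort means.

    ``population_means`` are computed over observed values only and are the
    single-subject fallback at prediction time.
    """

    population_means: dict[str, float]
    m: int
    iterations: int
    pmm_donors: int
    seed: int
    imputed_variables: list[str] = field(default_factory=list)


def mice_fit_transform(
    cohort: CohortTable,
    variables: Sequence[str] | None = None,
    m: int = 5,
    iterations: int = 10,
    seed: int = 0,
    pmm_donors: int = 5,
) -> tuple[list[CohortTable], ImputationModel]:
    """Chained-equation imputation with predictive-mean-matching draws.

    Each numeric variable with missing values is regressed on all the other
    supplied variables; draws are taken by predictive mean matching with a
    ``pmm_donors``-nearest donor pool.  Returns ``m`` completed cohorts (the
    chain is advanced ``iterations`` steps between snapshots) plus the fitted
    :class:`ImputationModel`.  Observed cells are never altered.
    """
    names = list(variables) if variables is not None else cohort.catalog.names
    numeric = [n for n in names if n in cohort.catalog.numeric_names]
    data = cohort.df[names].copy()
    for n in numeric:
        if data[n].isna().all():
            raise ValueError(f"variable {n!r} is 100% missing; cannot initialize imputation")

    means = {n: float(data[n].mean(skipna=True)) for n in numeric}
    model = ImputationModel(
        population_means=means,
        m=m,
        iterations=iterations,
        pmm_donors=pmm_donors,
        seed=seed,
        imputed_variables=[n for n in numeric if data[n].isna().any()],
    )

    if not model.imputed_variables:
        completed = [cohort.df.copy() for _ in range(m)]
        return [CohortTable(c, cohort.catalog) for c in completed], model

    # statsmodels' chained-equation engine draws through the legacy global
    # RandomState; seed it once so the whole chain is reproducible.
    np.random.seed(seed % (2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mice_data = MICEData(data, k_pmm=pmm_donors)
        completed_tables: list[CohortTable] = []
        for _ in range(m):
            mice_data.update_all(iterations)
            out = cohort.df.copy()
            snap = mice_data.data
            for n in model.imputed_variables:
                out[n] = snap[n].to_numpy()
            completed_tables.append(CohortTable(out, cohort.catalog))
    return completed_tables, model


def mean_impute(features: Mapping[str, float], model: ImputationModel) -> dict[str, float]:
    """Fill missing numeric fields of one subject with derivation means."""
    out = dict(features)
    for name, value in features.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            if name not in model.population_means:
                raise KeyError(f"no population mean available for field {name!r}")
            out[name] = model.population_means[name]
    return out


# ---------------------------------------------------------------------------
# LASSO shortlisting
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Two-stage select-then-refit variable shortlist."""

    table: pd.DataFrame  # variable, lasso_coef, nonzero, refit_p, selected, mandatory
    chosen_penalty: float
    selected: list[str]


def lasso_screen(
    cohort: CohortTable,
    candidates: Sequence[str],
    seed: int = 0,
    cv_folds: int = 5,
    n_alphas: int = 40,
    alpha_min_ratio: float = 0.01,
    p_threshold: float = 0.05,
) -> SelectionReport:
    """Shortlist candidates by L1-penalized Cox + unpenalized refit p-values.

    The L1 penalty is chosen on a path by ``cv_folds``-fold cross-validated
    partial likelihood.  Variables with nonzero coefficients at the chosen
    penalty are refit in an unpenalized multivariable Cox model; the final
    shortlist is {refit p < ``p_threshold``} ∪ mandatory.  Candidate columns
    must be complete (post-imputation).
    """
    candidates = list(candidates)
    df = cohort.df
    if df["event"].sum() == 0:
        raise ValueError("no events: selection impossible")
    X = df[candidates]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"candidates contain missing values (impute first): {bad}")

    mandatory = [v for v in candidates if cohort.catalog[v].mandatory or cohort.catalog[v].mandatory_imputable] \
        if len(cohort.catalog) else []

    mu = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    Xs = ((X - mu) / sd).to_numpy()
    y = Surv.from_arrays(event=df["event"].astype(bool), time=df["followup_years"])

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Xs, y)
    alphas = np.asarray(path.alphas_)

    times = df["followup_years"].to_numpy(float)
    events = df["event"].to_numpy(int)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_ll = np.zeros(len(alphas))
    for tr, te in kf.split(Xs):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold.fit(Xs[tr], y[tr])
        coefs = fold.coef_  # (p, n_alphas)
        for j in range(coefs.shape[1]):
            lp = Xs[te] @ coefs[:, j]
            if events[te].sum() == 0:
                continue
            cv_ll[j] += cox_partial_loglik(lp, times[te], events[te])
    best_j = int(np.argmax(cv_ll))
    chosen_alpha = float(alphas[best_j])

    lasso_coef = path.coef_[:, best_j]
    nonzero = [c for c, b in zip(candidates, lasso_coef) if abs(b) > 0]

    refit_p: dict[str, float] = {}
    if nonzero:
        refit_cols = list(dict.fromkeys(nonzero))
        refit_df = df[["followup_years", "event"] + refit_cols]
        cph = CoxPHFitter()
        cph.fit(refit_df, duration_col="followup_years", event_col="event")
        refit_p = {k: float(v) for k, v in cph.summary["p"].items()}
        selected = sorted(
            set(v for v in refit_cols if refit_p[v] < p_threshold) | set(mandatory),
            key=candidates.index,
        )
    else:
        warnings.warn("penalty path collapsed to the empty model; returning mandatory-only shortlist")
        selected = list(mandatory)

    table = pd.DataFrame(
        dict(
            variable=candidates,
            lasso_coef=lasso_coef,
            nonzero=[c in nonzero for c in candidates],
            refit_p=[refit_p.get(c, np.nan) for c in candidates],
            mandatory=[c in mandatory for c in candidates],
            selected=[c in selected for c in candidates],
        )
    )
    return SelectionReport(table=table, chosen_penalty=chosen_alpha, selected=selected)
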