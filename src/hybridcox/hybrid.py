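"""The hybrid statistical/machine-learning survival model.

Two cooperating pieces:

* a gradient-boosted tree ensemble trained against the gradient and Hessian
  of the negative Cox partial log-likelihood (Breslow handling of tied event
  times), emitting a per-subject *boosted risk score* on the log-hazard
  scale; and
* a ridge-penalized Cox proportional-hazards model over a small set of
  mandatory clinical variables, optionally augmented with the boosted score
  as one extra covariate (*full* flavor vs mandatory-only *basic* flavor),
  with a Breslow baseline survival curve so the model emits absolute
  10-year risks, not just relative hazards.

The boosting objective is authored here and handed to xgboost as a custom
objective; xgboost's builtin ``survival:cox`` is never used by the fitting
path (tests use it as an independent cross-check).  The objective hook is
pluggable so an alternative loss can be substituted without touching the
fitting code.

Sign conventions: the per-subject score and linear predictor are log
relative hazards — higher means earlier expected failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# Cox partial-likelihood primitives
# ---------------------------------------------------------------------------

def _risk_set_sums(lp: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Per-subject cumulative risk-set terms, Breslow ties.

    Returns (A, B, order stats) where for subject j:
    ``A_j = sum_{event times u <= t_j} d_u / S(u)`` and
    ``B_j = sum_{event times u <= t_j} d_u / S(u)**2`` with
    ``S(u) = sum_{k: t_k >= u} exp(lp_k)``.
    """
    n = len(lp)
    order = np.argsort(times, kind="stable")
    ts = times[order]
    es = events[order]
    elp = np.exp(lp[order])
    # suffix sums of exp(lp) over the sorted order
    suffix = np.concatenate([np.cumsum(elp[::-1])[::-1], [0.0]])

    uniq, first_idx = np.unique(ts, return_index=True)
    A_sorted = np.zeros(n)
    B_sorted = np.zeros(n)
    a = b = 0.0
    for u, start in zip(uniq, first_idx):
        stop = np.searchsorted(ts, u, side="right")
        d = float(es[start:stop].sum())
        if d > 0:
            S = suffix[start]
            a += d / S
            b += d / S**2
        A_sorted[start:stop] = a
        B_sorted[start:stop] = b
    A = np.empty(n)
    B = np.empty(n)
    A[order] = A_sorted
    B[order] = B_sorted
    return A, B


def cox_partial_loglik(lp: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood of a linear predictor."""
    lp = np.asarray(lp, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() == 0:
        raise ValueError("no events: partial likelihood undefined")
    order = np.argsort(times, kind="stable")
    ts, es, lps = times[order], events[order], lp[order]
    suffix = np.concatenate([np.cumsum(np.exp(lps)[::-1])[::-1], [0.0]])
    ll = 0.0
    uniq, first_idx = np.unique(ts, return_index=True)
    for u, start in zip(uniq, first_idx):
        stop = np.searchsorted(ts, u, side="right")
        d = float(es[start:stop].sum())
        if d > 0:
            ll += float(lps[start:stop][es[start:stop] == 1].sum())
            ll -= d * np.log(suffix[start])
    return ll


def cox_objective(
    lp: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the negative Cox partial log-likelihood.

    For subject j: ``grad_j = exp(lp_j) * A_j - event_j`` and
    ``hess_j = exp(lp_j) * A_j - exp(lp_j)**2 * B_j`` (see
    :func:`_risk_set_sums`); gradients sum to zero (score identity).
    """
    lp = np.asarray(lp, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if lp.shape != times.shape or lp.shape != events.shape:
        raise ValueError("lp, times and events must have equal length")
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    if events.sum() == 0:
        raise ValueError("no events: objective undefined")
    A, B = _risk_set_sums(lp, times, events)
    elp = np.exp(lp)
    grad = elp * A - events
    hess = elp * A - elp**2 * B
    return grad, hess


ObjectiveFn = Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


# ---------------------------------------------------------------------------
# boosted Cox model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperparams:
    """Boosting hyperparameters."""

    max_depth: int = 3
    learning_rate: float = 0.1
    n_rounds: int = 200
    subsample: float = 0.8
    colsample: float = 0.8
    reg_lambda: float = 1.0

    def __post_init__(self) -> None:
        if self.max_depth <= 0 or self.learning_rate <= 0 or self.n_rounds < 0:
            raise ValueError("depth/learning rate must be positive; rounds non-negative")
        if not (0 < self.subsample <= 1) or not (0 < self.colsample <= 1):
            raise ValueError("subsample fractions must be in (0, 1]")
        if self.reg_lambda < 0:
            raise ValueError("L2 leaf penalty must be non-negative")


DEFAULT_GRID: list[Hyperparams] = [
    Hyperparams(max_depth=d, learning_rate=lr, n_rounds=r, subsample=0.8)
    for d in (2, 3, 4)
    for lr in (0.05, 0.1)
    for r in (100, 300)
]


@dataclass
class BoostedCoxModel:
    """Tree ensemble trained with the Cox partial-likelihood objective."""

    booster: xgb.Booster
    variables: list[str]
    hyperparams: Hyperparams
    offset: float  # training-mean raw score; subtracted so scores are centered
    seed: int

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Centered per-subject risk score (log relative hazard scale)."""
        dm = xgb.DMatrix(X[self.variables], missing=np.nan, nthread=1)
        raw = self.booster.predict(dm, output_margin=True)
        return np.asarray(raw, float) - self.offset

    def to_dict(self) -> dict:
        return {
            "booster": json.loads(bytes(self.booster.save_raw(raw_format="json"))),
            "variables": self.variables,
            "hyperparams": self.hyperparams.__dict__,
            "offset": self.offset,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BoostedCoxModel":
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
        return cls(
            booster=booster,
            variables=list(payload["variables"]),
            hyperparams=Hyperparams(**payload["hyperparams"]),
            offset=float(payload["offset"]),
            seed=int(payload["seed"]),
        )


def _xgb_params(hp: Hyperparams, seed: int) -> dict:
    return {
        "max_depth": hp.max_depth,
        "eta": hp.learning_rate,
        "subsample": hp.subsample,
        "colsample_bytree": hp.colsample,
        "lambda": hp.reg_lambda,
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed),
        "base_score": 0.0,
        "disable_default_eval_metric": 1,
    }


def fit_boosted(
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    variables: Sequence[str],
    hp: Hyperparams | None = None,
    seed: int = 0,
    objective_fn: ObjectiveFn = cox_objective,
) -> BoostedCoxModel:
    """Grow a boosted tree ensemble against the Cox objective.

    ``objective_fn`` is the pluggable loss hook; the default is the plain
    Breslow-ties Cox partial-likelihood objective.  With ``n_rounds = 0`` the
    result is a valid constant-score model.
    """
    hp = hp or Hyperparams()
    variables = list(variables)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    dm = xgb.DMatrix(X[variables], missing=np.nan, nthread=1)

    def _obj(predt: np.ndarray, dtrain: xgb.DMatrix):
        return objective_fn(predt, times, events)

    booster = xgb.train(_xgb_params(hp, seed), dm, num_boost_round=hp.n_rounds, obj=_obj)
    raw = booster.predict(dm, output_margin=True)
    return BoostedCoxModel(
        booster=booster,
        variables=variables,
        hyperparams=hp,
        offset=float(np.mean(raw)),
        seed=seed,
    )


def oof_scores(
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    variables: Sequence[str],
    hp: Hyperparams | None = None,
    folds: int = 5,
    seed: int = 0,
    objective_fn: ObjectiveFn = cox_objective,
) -> np.ndarray:
    """Out-of-fold boosted scores (event-stratified folds).

    The default input to the stacking stage: scoring each subject with an
    ensemble that never saw them limits optimism in the stacked coefficient.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = np.zeros(len(X))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(skf.split(X, events)):
        model = fit_boosted(
            X.iloc[tr], times[tr], events[tr], variables, hp,
            seed=seed + k, objective_fn=objective_fn,
        )
        out[te] = model.score(X.iloc[te])
    return out


def tune(
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    variables: Sequence[str],
    grid: Sequence[Hyperparams] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> Hyperparams:
    """Exhaustive grid search maximizing mean out-of-fold Harrell's C.

    Ties break toward fewer rounds, then shallower trees (grid order last).
    """
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    results = []
    for idx, hp in enumerate(grid):
        score = oof_scores(X, times, events, variables, hp, folds=folds, seed=seed)
        c = concordance_index(times, -score, events)
        results.append((-c, hp.n_rounds, hp.max_depth, idx, hp))
    results.sort(key=lambda r: r[:4])
    return results[0][4]


# ---------------------------------------------------------------------------
# stacked ridge Cox model
# ---------------------------------------------------------------------------

SCORE_COLUMN = "boosted_score"


@dataclass
class StackedModel:
    """Ridge Cox over mandatory variables (+ boosted score when ``full``).

    ``baseline_survival`` is the Breslow baseline evaluated at the training
    mean of the model covariates, so absolute risk at horizon ``h`` is
    ``1 - S0(h) ** exp(lp - centering)``.
    """

    coefs: dict[str, float]
    ses: dict[str, float]
    lam: float
    flavor: str  # basic | full
    centering: float
    baseline_times: np.ndarray
    baseline_survival: np.ndarray
    mandatory_vars: list[str]
    imputation_means: dict[str, float] = field(default_factory=dict)
    boosted: BoostedCoxModel | None = None

    def __post_init__(self) -> None:
        if self.flavor not in ("basic", "full"):
            raise ValueError("flavor must be 'basic' or 'full'")
        if self.flavor == "basic" and SCORE_COLUMN in self.coefs:
            raise ValueError("basic flavor cannot carry a boosted-score coefficient")

    # -- prediction ---------------------------------------------------------

    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [v for v in self.mandatory_vars if v not in X.columns]
        if missing:
            raise ValueError(f"missing mandatory feature(s): {missing}")
        for v in self.mandatory_vars:
            if X[v].isna().any():
                raise ValueError(f"mandatory feature {v!r} has missing values; impute first")
        return X

    def predict_lp(self, X: pd.DataFrame) -> np.ndarray:
        """Uncentered linear predictor."""
        X = self._design(X)
        lp = np.zeros(len(X))
        for name, b in self.coefs.items():
            if name == SCORE_COLUMN:
                continue
            lp += b * X[name].to_numpy(float)
        if SCORE_COLUMN in self.coefs:
            if self.boosted is None:
                raise ValueError("full model lacks its boosted component")
            lp += self.coefs[SCORE_COLUMN] * self.boosted.score(X)
        return lp

    def baseline_survival_at(self, t: float) -> float:
        """Right-continuous step lookup; carried forward beyond the grid."""
        if t <= 0:
            return 1.0
        i = int(np.searchsorted(self.baseline_times, t, side="right") - 1)
        if i < 0:
            return 1.0
        return float(self.baseline_survival[min(i, len(self.baseline_survival) - 1)])

    def predict_risk(self, X: pd.DataFrame | Mapping[str, float], horizon: float = 10.0) -> np.ndarray:
        """Absolute event risk by ``horizon`` years, in [0, 1]."""
        if isinstance(X, Mapping):
            X = pd.DataFrame([X])
        lp = self.predict_lp(X)
        s0 = self.baseline_survival_at(horizon)
        risk = 1.0 - np.power(s0, np.exp(lp - self.centering))
        return np.clip(risk, 0.0, 1.0)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "hybridcox.stacked_model/1",
            "flavor": self.flavor,
            "coefs": self.coefs,
            "ses": self.ses,
            "lam": self.lam,
            "centering": self.centering,
            "baseline_times": self.baseline_times.tolist(),
            "baseline_survival": self.baseline_survival.tolist(),
            "mandatory_vars": self.mandatory_vars,
            "imputation_means": self.imputation_means,
            "boosted": self.boosted.to_dict() if self.boosted is not None else None,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict())
        if path is not None:
            from pathlib import Path

            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "StackedModel":
        return cls(
            coefs={k: float(v) for k, v in payload["coefs"].items()},
            ses={k: float(v) for k, v in payload["ses"].items()},
            lam=float(payload["lam"]),
            flavor=payload["flavor"],
            centering=float(payload["centering"]),
            baseline_times=np.asarray(payload["baseline_times"], float),
            baseline_survival=np.asarray(payload["baseline_survival"], float),
            mandatory_vars=list(payload["mandatory_vars"]),
            imputation_means={k: float(v) for k, v in payload["imputation_means"].items()},
            boosted=BoostedCoxModel.from_dict(payload["boosted"]) if payload.get("boosted") else None,
        )

    @classmethod
    def from_json(cls, payload: str) -> "StackedModel":
        return cls.from_dict(json.loads(payload))


def fit_stacked(
    df: pd.DataFrame,
    mandatory_vars: Sequence[str],
    boosted: BoostedCoxModel | None = None,
    lam: float = 0.0001,
    flavor: str = "basic",
    boosted_score: np.ndarray | None = None,
    imputation_means: Mapping[str, float] | None = None,
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> StackedModel:
    """Fit the ridge-penalized Cox stacking model.

    ``flavor='full'`` requires ``boosted``; the score column defaults to
    ``boosted_score`` (e.g. out-of-fold scores) and otherwise to the in-sample
    ensemble score.  A (near-)constant score column is dropped with its
    coefficient fixed at 0, so a zero-round ensemble degenerates exactly to
    the basic model.  ``lam`` is the per-observation L2 penalty handed to the
    partial-likelihood maximizer.
    """
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    mandatory_vars = list(mandatory_vars)
    for v in mandatory_vars:
        if df[v].isna().any():
            raise ValueError(f"mandatory variable {v!r} has missing values; impute first")

    fit_df = df[[duration_col, event_col] + mandatory_vars].copy()
    score_dropped = False
    if flavor == "full":
        if boosted is None:
            raise ValueError("full flavor requires a boosted model")
        score = boosted_score if boosted_score is not None else boosted.score(df)
        if float(np.std(score)) < 1e-10:
            score_dropped = True
        else:
            fit_df[SCORE_COLUMN] = np.asarray(score, float)
    elif flavor != "basic":
        raise ValueError("flavor must be 'basic' or 'full'")

    cph = CoxPHFitter(penalizer=lam, l1_ratio=0.0)
    cph.fit(fit_df, duration_col=duration_col, event_col=event_col)

    coefs = {k: float(v) for k, v in cph.params_.items()}
    ses = {k: float(v) for k, v in cph.standard_errors_.items()}
    if flavor == "full" and score_dropped:
        coefs[SCORE_COLUMN] = 0.0
        ses[SCORE_COLUMN] = float("nan")
    centering = float(np.dot(cph.params_.to_numpy(), cph._norm_mean.to_numpy()))
    bs = cph.baseline_survival_

    return StackedModel(
        coefs=coefs,
        ses=ses,
        lam=lam,
        flavor=flavor,
        centering=centering,
        baseline_times=bs.index.to_numpy(float),
        baseline_survival=bs.iloc[:, 0].to_numpy(float),
        mandatory_vars=mandatory_vars,
        imputation_means=dict(imputation_means or {}),
        boosted=boosted if flavor == "full" else None,
    )


def predict_risk(model: StackedModel, features, horizon: float = 10.0) -> np.ndarray:
    """Functional alias for :meth:`StackedModel.predict_risk`."""
    return model.predict_risk(features, horizon=horizon)


def hazard_ratios(model: StackedModel) -> pd.DataFrame:
    """Wald hazard-ratio table (approximate under ridge penalization)."""
    rows = []
    for name, coef in model.coefs.items():
        se = model.ses.get(name, float("nan"))
        if np.isfinite(se) and se > 0:
            lo, hi = np.exp(coef - 1.959964 * se), np.exp(coef + 1.959964 * se)
            p = 2.0 * norm.sf(abs(coef) / se)
        else:
            lo = hi = p = float("nan")
        rows.append(
            dict(variable=name, coef=coef, hr=float(np.exp(coef)),
                 ci_lower=float(lo), ci_upper=float(hi), p=float(p), flavor=model.flavor)
        )
    return pd.DataFrame(rows)


def attribute(boosted: BoostedCoxModel, X: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-variable additive (tree-Shapley) contributions to the boosted score.

    Returns ``(contributions, base_value)`` with the exact additivity
    identity ``base_value + contributions.sum(axis=1) == score``.
    Cohort-level importance is the mean absolute contribution per variable.
    """
    dm = xgb.DMatrix(X[boosted.variables], missing=np.nan, nthread=1)
    contrib = boosted.booster.predict(dm, pred_contribs=True)
    contrib = np.asarray(contrib, float)
    base = float(contrib[0, -1]) - boosted.offset if len(contrib) else -boosted.offset
    return pd.DataFrame(contrib[:, :-1], columns=boosted.variables, index=X.index), base
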