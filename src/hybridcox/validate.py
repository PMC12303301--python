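"""Model validation: discrimination, calibration, utility, recalibration.

Conventions, stated once:

* Harrell's C counts a pair as usable iff the shorter follow-up ends in an
  event; ties in predicted risk score one half.
* Decile calibration compares mean predicted risk per decile against
  1 − KM(horizon) within the decile; subjects with identical predictions
  stay in the same group even if counts become unequal.
* The calibration slope is the OLS slope of observed on predicted over the
  decile points (ideal 1); calibration-in-the-large is overall observed KM
  risk minus mean predicted risk, on the risk scale (ideal 0).
* The Brier score at the horizon is inverse-probability-of-censoring
  weighted: events before the horizon contribute (1 − risk)² / G(T⁻),
  subjects still at risk contribute risk² / G(horizon), and subjects
  censored early are weighted out (G = censoring Kaplan–Meier).
* Decision-curve net benefit at threshold p is TP/n − FP/n · p/(1−p), with
  TP/FP among flagged subjects estimated censoring-aware via KM within the
  flagged group.
* Bootstrap CIs are percentile CIs over subject-level resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from sklearn.model_selection import StratifiedKFold

from .cohort import km_survival


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def harrells_c(risk: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's concordance of a risk score against censored outcomes."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if not (len(risk) == len(times) == len(events)):
        raise ValueError("risk, times and events must have equal length")
    if events.sum() == 0:
        raise ValueError("no usable pairs: no events observed")
    # higher risk should mean shorter survival, hence the sign flip
    return float(concordance_index(times, -risk, events))


def bootstrap_metric(
    metric: Callable[[pd.DataFrame], float],
    df: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Mean and 95% percentile CI of a cohort metric over B resamples."""
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    n = len(df)
    values = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        values[b] = metric(df.iloc[idx].reset_index(drop=True))
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(values.mean()), (float(lo), float(hi))


def repeated_cv(
    df: pd.DataFrame,
    fit_predict: Callable[[pd.DataFrame, pd.DataFrame], np.ndarray],
    metric: Callable[[np.ndarray, np.ndarray, np.ndarray], float],
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> np.ndarray:
    """Repeated stratified k-fold CV; one pooled out-of-fold metric per repeat.

    Folds are stratified on the event indicator and reshuffled each repeat.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    events = df[event_col].to_numpy(int)
    if events.sum() < k:
        raise ValueError("fewer events than folds; reduce k")
    out = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        risk = np.empty(len(df))
        for tr, te in skf.split(df, events):
            risk[te] = fit_predict(df.iloc[tr].reset_index(drop=True), df.iloc[te].reset_index(drop=True))
        out[r] = metric(risk, df[duration_col].to_numpy(float), events)
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTable:
    """Per-decile mean predicted risk vs KM observed risk at the horizon."""

    table: pd.DataFrame  # group, n, mean_predicted, observed, observed_lo, observed_hi
    horizon: float

    def __len__(self) -> int:
        return len(self.table)


def decile_calibration(
    risk: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon: float = 10.0,
    groups: int = 10,
) -> CalibrationTable:
    """Rank subjects by predicted risk into ``groups`` equal-count bins.

    Tied predictions are kept in one bin (counts may become unequal); if
    fewer distinct values exist than requested bins the grouping coarsens
    with a warning.
    """
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(risk) < groups:
        raise ValueError(f"need at least {groups} subjects for {groups} groups")
    distinct = np.unique(risk)
    if len(distinct) < groups:
        warnings.warn(
            f"only {len(distinct)} distinct predictions; grouping coarsens below {groups} bins"
        )
    try:
        bins = pd.qcut(risk, q=min(groups, len(distinct)), duplicates="drop")
        codes = bins.codes
    except ValueError:
        codes = np.zeros(len(risk), int)
    rows = []
    for g in np.unique(codes):
        sel = codes == g
        km = km_survival(times[sel], events[sel], horizon)
        rows.append(
            dict(
                group=int(g),
                n=int(sel.sum()),
                mean_predicted=float(risk[sel].mean()),
                observed=1.0 - km.survival,
                observed_lo=1.0 - km.upper,
                observed_hi=1.0 - km.lower,
            )
        )
    table = pd.DataFrame(rows).sort_values("mean_predicted").reset_index(drop=True)
    return CalibrationTable(table, horizon)


def calibration_slope(table: CalibrationTable) -> float:
    """OLS slope of observed risk on mean predicted risk over decile points."""
    x = table.table["mean_predicted"].to_numpy()
    y = table.table["observed"].to_numpy()
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate predictor spread: need >= 2 distinct decile means")
    slope, _ = np.polyfit(x, y, deg=1)
    return float(slope)


def calibration_in_the_large(
    risk: np.ndarray, times: np.ndarray, events: np.ndarray, horizon: float = 10.0
) -> float:
    """Overall KM observed risk at the horizon minus mean predicted risk."""
    km = km_survival(times, events, horizon)
    return float((1.0 - km.survival) - np.mean(risk))


# ---------------------------------------------------------------------------
# overall accuracy
# ---------------------------------------------------------------------------

def _step_left(grid: np.ndarray, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Left-limit lookup of a right-continuous step function (value just before t)."""
    idx = np.searchsorted(grid, t, side="left") - 1
    out = np.ones(len(t))
    pos = idx >= 0
    out[pos] = values[idx[pos]]
    return out


def brier(
    risk: np.ndarray, times: np.ndarray, events: np.ndarray, horizon: float = 10.0
) -> float:
    """IPCW (Graf) Brier score of predicted horizon risks."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - events)  # censoring distribution
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)

    event_before = (times <= horizon) & (events == 1)
    at_risk = times > horizon

    g_event = _step_left(grid, surv, times[event_before])
    i = int(np.searchsorted(grid, horizon, side="right") - 1)
    g_horizon = float(surv[i]) if i >= 0 else 1.0
    if (event_before.any() and np.any(g_event <= 0)) or (at_risk.any() and g_horizon <= 0):
        raise ValueError("censoring survival reaches 0 before the horizon; shorten the horizon")

    total = np.zeros(len(risk))
    total[event_before] = (1.0 - risk[event_before]) ** 2 / g_event
    total[at_risk] = risk[at_risk] ** 2 / g_horizon
    return float(total.mean())


# ---------------------------------------------------------------------------
# clinical utility
# ---------------------------------------------------------------------------

@dataclass
class NetBenefitCurve:
    """Net benefit of the model vs treat-all / treat-none over thresholds."""

    table: pd.DataFrame  # threshold, nb_model, nb_all, nb_none


def decision_curve(
    risk: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon: float = 10.0,
    thresholds: Sequence[float] | None = None,
) -> NetBenefitCurve:
    """Censoring-aware decision-curve analysis at the given horizon.

    Among subjects flagged at a threshold, the true-positive fraction is
    estimated with a Kaplan–Meier fit inside the flagged group.
    """
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.51, 0.01)
    thresholds = np.asarray([t for t in np.asarray(thresholds, float) if 0.0 < t < 1.0])
    n = len(risk)
    prevalence = 1.0 - km_survival(times, events, horizon).survival

    rows = []
    for p in thresholds:
        w = p / (1.0 - p)
        flagged = risk >= p
        if flagged.sum() == 0:
            nb = 0.0
        else:
            q = 1.0 - km_survival(times[flagged], events[flagged], horizon).survival
            tp = flagged.sum() * q / n
            fp = flagged.sum() * (1.0 - q) / n
            nb = tp - fp * w
        nb_all = prevalence - (1.0 - prevalence) * w
        rows.append(dict(threshold=float(p), nb_model=float(nb), nb_all=float(nb_all), nb_none=0.0))
    return NetBenefitCurve(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# recalibration
# ---------------------------------------------------------------------------

@dataclass
class RecalibrationResult:
    intercept_shift: float  # on the log cumulative-hazard scale at the horizon
    slope_multiplier: float  # on the linear predictor
    before_slope: float
    after_slope: float
    before_citl: float
    after_citl: float
    accepted: bool


def _breslow_baseline(lp: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Breslow baseline cumulative hazard for a fixed linear predictor."""
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    elp = np.exp(lp[order])
    suffix = np.concatenate([np.cumsum(elp[::-1])[::-1], [0.0]])
    uniq, first_idx = np.unique(ts, return_index=True)
    grid, h0 = [], []
    cum = 0.0
    for u, start in zip(uniq, first_idx):
        stop = np.searchsorted(ts, u, side="right")
        d = float(es[start:stop].sum())
        if d > 0:
            cum += d / suffix[start]
            grid.append(u)
            h0.append(cum)
    return np.asarray(grid), np.asarray(h0)


def recalibrate(model, df: pd.DataFrame, horizon: float = 10.0):
    """Refit baseline intercept and linear-predictor slope on a target cohort.

    The candidate update rescales the centered linear predictor by the Cox
    slope of the original predictor on the target cohort and replaces the
    baseline survival with the target-cohort Breslow estimate.  The update
    is *accepted* only if neither |calibration slope − 1| nor |CITL| worsens.
    Returns ``(RecalibrationResult, model_out)`` where ``model_out`` is the
    updated model when accepted and the original otherwise.
    """
    times = df["followup_years"].to_numpy(float)
    events = df["event"].to_numpy(int)
    if events.sum() == 0:
        raise ValueError("degenerate target cohort: no events")
    lp_c = model.predict_lp(df) - model.centering

    risk_before = model.predict_risk(df, horizon=horizon)
    before_table = decile_calibration(risk_before, times, events, horizon)
    before_slope = calibration_slope(before_table)
    before_citl = calibration_in_the_large(risk_before, times, events, horizon)

    slope_df = pd.DataFrame({"followup_years": times, "event": events, "lp": lp_c})
    cph = CoxPHFitter()
    cph.fit(slope_df, duration_col="followup_years", event_col="event")
    b = float(cph.params_["lp"])

    grid, h0 = _breslow_baseline(b * lp_c, times, events)
    h0_old = -np.log(max(model.baseline_survival_at(horizon), 1e-300))
    i = int(np.searchsorted(grid, horizon, side="right") - 1)
    h0_new = float(h0[i]) if i >= 0 else float("nan")
    intercept_shift = float(np.log(h0_new) - np.log(h0_old))

    from dataclasses import replace as _replace

    updated = _replace(
        model,
        coefs={k: b * v for k, v in model.coefs.items()},
        ses={k: abs(b) * v for k, v in model.ses.items()},
        centering=b * model.centering,
        baseline_times=grid,
        baseline_survival=np.exp(-h0),
    )

    risk_after = updated.predict_risk(df, horizon=horizon)
    after_table = decile_calibration(risk_after, times, events, horizon)
    after_slope = calibration_slope(after_table)
    after_citl = calibration_in_the_large(risk_after, times, events, horizon)

    accepted = (abs(after_slope - 1.0) <= abs(before_slope - 1.0)) and (
        abs(after_citl) <= abs(before_citl)
    )
    result = RecalibrationResult(
        intercept_shift=intercept_shift,
        slope_multiplier=b,
        before_slope=before_slope,
        after_slope=after_slope,
        before_citl=before_citl,
        after_citl=after_citl,
        accepted=accepted,
    )
    return result, (updated if accepted else model)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    c_mean: float
    c_ci: tuple[float, float]
    calibration_slope: float
    citl: float
    brier: float
    calibration: CalibrationTable
    net_benefit: NetBenefitCurve
    recalibration_applied: bool
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "schema": "hybridcox.validation_report/1",
            "c_mean": self.c_mean,
            "c_ci": list(self.c_ci),
            "calibration_slope": self.calibration_slope,
            "calibration_in_the_large": self.citl,
            "brier": self.brier,
            "calibration_table": self.calibration.table.to_dict(orient="records"),
            "net_benefit": self.net_benefit.table.to_dict(orient="records"),
            "recalibration_applied": self.recalibration_applied,
            "metadata": self.metadata,
        }


def validation_report(
    model,
    df: pd.DataFrame,
    horizon: float = 10.0,
    B: int = 1000,
    seed: int = 0,
    recalibrate_first: bool = False,
) -> ValidationReport:
    """Full single-model validation: bootstrap C, calibration, Brier, DCA."""
    applied = False
    if recalibrate_first:
        result, model = recalibrate(model, df, horizon)
        applied = result.accepted
    risk = model.predict_risk(df, horizon=horizon)
    times = df["followup_years"].to_numpy(float)
    events = df["event"].to_numpy(int)

    risk_series = pd.Series(risk, index=df.index)

    def c_metric(resample: pd.DataFrame) -> float:
        r = model.predict_risk(resample, horizon=horizon)
        return harrells_c(r, resample["followup_years"].to_numpy(), resample["event"].to_numpy())

    c_mean, c_ci = bootstrap_metric(c_metric, df, B=B, seed=seed)
    table = decile_calibration(risk, times, events, horizon)
    return ValidationReport(
        c_mean=c_mean,
        c_ci=c_ci,
        calibration_slope=calibration_slope(table),
        citl=calibration_in_the_large(risk, times, events, horizon),
        brier=brier(risk, times, events, horizon),
        calibration=table,
        net_benefit=decision_curve(risk, times, events, horizon),
        recalibration_applied=applied,
        metadata={"B": B, "seed": seed, "horizon": horizon, "n": len(df)},
    )


def compare_models(
    models: Mapping[str, object],
    df: pd.DataFrame,
    horizon: float = 10.0,
    B: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, NetBenefitCurve]]:
    """Aligned comparison table over models (or precomputed risk columns).

    Each value of ``models`` is either an object exposing
    ``predict_risk(df, horizon)`` or a plain per-subject risk vector (e.g. an
    externally computed score).
    """
    times = df["followup_years"].to_numpy(float)
    events = df["event"].to_numpy(int)
    rows = []
    curves: dict[str, NetBenefitCurve] = {}
    for name, m in models.items():
        if hasattr(m, "predict_risk"):
            risk_fn = lambda frame, _m=m: np.asarray(_m.predict_risk(frame, horizon=horizon))
            risk = risk_fn(df)
        else:
            risk = np.asarray(m, float)
            col = f"__risk_{name}"
            df = df.assign(**{col: risk})
            risk_fn = lambda frame, _c=col: frame[_c].to_numpy(float)

        def c_metric(resample: pd.DataFrame, _fn=risk_fn) -> float:
            return harrells_c(
                _fn(resample),
                resample["followup_years"].to_numpy(),
                resample["event"].to_numpy(),
            )

        c_mean, c_ci = bootstrap_metric(c_metric, df, B=B, seed=seed)
        table = decile_calibration(risk, times, events, horizon)
        curves[name] = decision_curve(risk, times, events, horizon)
        rows.append(
            dict(
                model=name,
                c=c_mean,
                c_lo=c_ci[0],
                c_hi=c_ci[1],
                calibration_slope=calibration_slope(table),
                citl=calibration_in_the_large(risk, times, events, horizon),
                brier=brier(risk, times, events, horizon),
            )
        )
    return pd.DataFrame(rows), curves
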