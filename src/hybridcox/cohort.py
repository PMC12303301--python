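"""Cohort assembly from longitudinal records and cohort-level summaries.

Entry/censoring rules follow the usual EHR-derivation pattern for incident
disease cohorts: a subject enters at their first entry-marker record (e.g.,
first lipid test), follow-up runs to the earliest of first outcome, death, or
the administrative study end, and subjects with an outcome or death on or
before entry are excluded.  All exclusions are tallied in an explicit ledger
so that retained + excluded always reconciles with the input.

Time is carried internally in integer days; reported follow-up is
days / 365.25 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .catalog import Codelist, Variable, VariableCatalog, validate_codelists

DAYS_PER_YEAR = 365.25

RECORD_COLUMNS = ["subject_id", "time", "channel", "code", "value"]


class KMEstimate(NamedTuple):
    """Product-limit survival estimate at a time point, with Greenwood CI."""

    survival: float
    lower: float
    upper: float


@dataclass
class CohortTable:
    """One row per subject: follow-up, event indicator and covariates.

    ``df`` columns: ``subject_id``, ``followup_years``, ``event``, one column
    per catalog variable (NaN encodes a missing value), and optionally
    ``component`` (the outcome component attributed to event rows).
    """

    df: pd.DataFrame
    catalog: VariableCatalog

    def __post_init__(self) -> None:
        required = {"subject_id", "followup_years", "event"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.df["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")
        if len(self.df) and (self.df["followup_years"] <= 0).any():
            raise ValueError("followup_years must be positive")
        if len(self.df) and not self.df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        absent = [n for n in self.catalog.names if n not in self.df.columns]
        if absent:
            raise ValueError(f"catalog variables absent from table: {absent}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["followup_years"].to_numpy(float)

    @property
    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(int)

    def features(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        return self.df[list(names) if names is not None else self.catalog.names]

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is observed."""
        return self.df[self.catalog.names].notna()

    def subset(self, index: np.ndarray) -> "CohortTable":
        sub = self.df.iloc[index].reset_index(drop=True).copy()
        if np.unique(np.asarray(index)).size != len(sub):  # bootstrap resample
            sub["subject_id"] = np.arange(len(sub))
        return CohortTable(sub, self.catalog)

    def to_csv(self, path: str | Path, catalog_path: str | Path | None = None) -> None:
        cols = ["subject_id", "followup_years", "event"] + self.catalog.names
        if "component" in self.df.columns:
            cols.append("component")
        self.df[cols].to_csv(path, index=False)
        if catalog_path is not None:
            self.catalog.to_yaml(catalog_path)

    @classmethod
    def from_csv(cls, path: str | Path, catalog: VariableCatalog | str | Path) -> "CohortTable":
        if not isinstance(catalog, VariableCatalog):
            catalog = VariableCatalog.from_yaml(catalog)
        df = pd.read_csv(path)
        required = {"subject_id", "followup_years", "event"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort CSV {path} missing required columns: {sorted(missing)}")
        return cls(df, catalog)


@dataclass
class CohortConfig:
    """Rules governing cohort construction.

    ``entry_marker``, ``outcomes`` and ``exclusions`` name codelists.
    ``outcome_priority`` breaks same-day ties between outcome components;
    default is the order the outcome codelists are listed.
    """

    entry_marker: str
    outcomes: list[str]
    study_end: int  # days since epoch
    exclusions: list[str] = field(default_factory=list)
    outcome_priority: list[str] | None = None
    min_age: float | None = None
    age_variable: str = "age"


@dataclass
class BuiltCohort:
    cohort: CohortTable
    exclusion_ledger: dict[str, int]
    n_input: int


def _first_match_time(group: pd.DataFrame, codelist: Codelist) -> float | None:
    hit = group[
        (group["channel"] == codelist.channel)
        & group["code"].astype(str).str.startswith(tuple(codelist.patterns))
    ]
    return float(hit["time"].min()) if len(hit) else None


def build_cohort(
    records: pd.DataFrame,
    codelists: Sequence[Codelist],
    config: CohortConfig,
    catalog: VariableCatalog | None = None,
) -> BuiltCohort:
    """Assemble an analysis cohort from long-format records.

    Per subject: entry = first entry-marker record; follow-up ends at the
    earliest of first outcome, death, or ``config.study_end``; the event
    indicator is 1 iff an outcome occurs strictly after entry and no later
    than death/study end.  Excluded (and ledgered): subjects with no
    entry-marker record, outcome before or on the entry day, death on or
    before entry, zero follow-up, a matching exclusion codelist, or below the
    configured entry age.

    Covariates extracted against ``catalog``: binary flags from ``exposure``
    codelists (any matching record on or before entry); numeric labs as the
    last lab/vitals value on or before entry for a codelist sharing the
    variable's name (missing if never measured).
    """
    validate_codelists(codelists)
    by_name = {c.name: c for c in codelists}
    if config.entry_marker not in by_name:
        raise ValueError(f"config names unknown entry_marker codelist {config.entry_marker!r}")
    for name in list(config.outcomes) + list(config.exclusions):
        if name not in by_name:
            raise ValueError(f"config names unknown codelist {name!r}")
    entry_cl = by_name[config.entry_marker]
    outcome_cls = [by_name[n] for n in config.outcomes]
    exclusion_cls = [by_name[n] for n in config.exclusions]
    priority = config.outcome_priority or list(config.outcomes)

    missing_cols = set(RECORD_COLUMNS[:4]) - set(records.columns)
    if missing_cols:
        raise ValueError(f"record stream missing columns: {sorted(missing_cols)}")

    ledger: dict[str, int] = {
        "no_entry_marker": 0,
        "outcome_on_or_before_entry": 0,
        "death_on_or_before_entry": 0,
        "zero_followup": 0,
        "below_min_age": 0,
    }
    for cl in exclusion_cls:
        ledger[f"exclusion:{cl.name}"] = 0

    exposure_cls = [c for c in codelists if c.role == "exposure"]
    rows: list[dict] = []
    n_input = records["subject_id"].nunique()

    for sid, grp in records.groupby("subject_id", sort=True):
        entry = _first_match_time(grp, entry_cl)
        if entry is None:
            ledger["no_entry_marker"] += 1
            continue

        death_times = grp.loc[grp["channel"] == "death", "time"]
        death = float(death_times.min()) if len(death_times) else None
        if death is not None and death <= entry:
            ledger["death_on_or_before_entry"] += 1
            continue

        outcome_hits = [(n, _first_match_time(grp, by_name[n])) for n in config.outcomes]
        outcome_hits = [(n, t) for n, t in outcome_hits if t is not None]
        first_outcome = min((t for _, t in outcome_hits), default=None)
        if first_outcome is not None and first_outcome <= entry:
            ledger["outcome_on_or_before_entry"] += 1
            continue

        if any(_first_match_time(grp, cl) is not None for cl in exclusion_cls):
            for cl in exclusion_cls:
                if _first_match_time(grp, cl) is not None:
                    ledger[f"exclusion:{cl.name}"] += 1
                    break
            continue

        candidates = [config.study_end]
        if death is not None:
            candidates.append(death)
        if first_outcome is not None:
            candidates.append(first_outcome)
        end = min(candidates)
        event = int(first_outcome is not None and first_outcome == end)
        if end <= entry:
            ledger["zero_followup"] += 1
            continue

        component = None
        if event:
            tied = [n for n, t in outcome_hits if t == first_outcome]
            component = min(tied, key=priority.index)

        row: dict = {
            "subject_id": sid,
            "followup_years": (end - entry) / DAYS_PER_YEAR,
            "event": event,
            "component": component,
        }
        if catalog is not None:
            lab_cls = {c.name: c for c in codelists if c.channel in ("lab", "vitals")}
            for var in catalog:
                if var.kind == "binary":
                    flag_cl = next((c for c in exposure_cls if c.name == var.name), None)
                    pre = grp[grp["time"] <= entry]
                    row[var.name] = (
                        int(any(flag_cl.matches(ch, co) for ch, co in zip(pre["channel"], pre["code"])))
                        if flag_cl is not None
                        else 0
                    )
                else:
                    cl = lab_cls.get(var.name)
                    val = np.nan
                    if cl is not None:
                        hits = grp[
                            (grp["time"] <= entry)
                            & (grp["channel"] == cl.channel)
                            & grp["code"].astype(str).str.startswith(tuple(cl.patterns))
                        ].sort_values("time")
                        if len(hits):
                            val = float(hits["value"].iloc[-1])
                    row[var.name] = val
        if config.min_age is not None:
            age = row.get(config.age_variable)
            if age is None or not np.isfinite(age) or age < config.min_age:
                ledger["below_min_age"] += 1
                continue
        rows.append(row)

    cat = catalog if catalog is not None else VariableCatalog([])
    df = pd.DataFrame(rows, columns=["subject_id", "followup_years", "event", "component"] + cat.names)
    return BuiltCohort(CohortTable(df, cat), ledger, n_input)


def km_survival(
    times: Sequence[float], events: Sequence[int], t: float
) -> KMEstimate:
    """Kaplan–Meier survival at ``t`` with a Greenwood 95% CI.

    Right-continuous step function; S(0) = 1; beyond the last observed time
    the last estimate is carried forward.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if t < 0:
        raise ValueError("t must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    s = float(kmf.predict(t))
    ci = kmf.confidence_interval_
    grid = ci.index.to_numpy(float)
    if t <= grid[0]:
        lo, hi = 1.0, 1.0
    else:
        i = int(np.searchsorted(grid, t, side="right") - 1)
        lo = float(ci.iloc[i, 0])
        hi = float(ci.iloc[i, 1])
    return KMEstimate(s, lo, hi)


@dataclass
class CohortSummary:
    """Descriptive cohort summary in the style of a baseline table."""

    n: int
    n_events: int
    person_years: float
    event_rate_per_1000py: float
    median_followup_years: float
    followup_p5: float
    followup_p95: float
    km_event_rate_10y: float
    km_event_rate_ci: tuple[float, float]
    composition: dict[str, tuple[int, float]]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "n_events": self.n_events,
            "person_years": self.person_years,
            "event_rate_per_1000py": self.event_rate_per_1000py,
            "median_followup_years": self.median_followup_years,
            "followup_p5": self.followup_p5,
            "followup_p95": self.followup_p95,
            "km_event_rate_10y": self.km_event_rate_10y,
            "km_event_rate_ci": list(self.km_event_rate_ci),
            "composition": {k: list(v) for k, v in self.composition.items()},
        }


def event_rate_per_1000py(n_events: float, person_years: float) -> float:
    """Crude incidence rate per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("invalid cohort: person-years must be positive")
    return 1000.0 * n_events / person_years


def summarize(cohort: CohortTable, horizon: float = 10.0) -> CohortSummary:
    """Event counts, incidence rate, follow-up quantiles and KM event rate."""
    if len(cohort) == 0:
        raise ValueError("invalid cohort: empty")
    t = cohort.times
    e = cohort.events
    py = float(t.sum())
    km = km_survival(t, e, horizon)
    composition: dict[str, tuple[int, float]] = {}
    if "component" in cohort.df.columns:
        comp = cohort.df.loc[cohort.df["event"] == 1, "component"].dropna()
        n_ev = int(e.sum())
        for name, cnt in comp.value_counts().items():
            composition[str(name)] = (int(cnt), float(cnt) / n_ev if n_ev else 0.0)
    return CohortSummary(
        n=len(cohort),
        n_events=int(e.sum()),
        person_years=py,
        event_rate_per_1000py=event_rate_per_1000py(int(e.sum()), py),
        median_followup_years=float(np.median(t)),
        followup_p5=float(np.percentile(t, 5)),
        followup_p95=float(np.percentile(t, 95)),
        km_event_rate_10y=1.0 - km.survival,
        km_event_rate_ci=(1.0 - km.upper, 1.0 - km.lower),
        composition=composition,
    )
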