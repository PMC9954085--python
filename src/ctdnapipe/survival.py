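"""Survival stratification by ctDNA detection status.

Kaplan–Meier product-limit curves, the 1-df log-rank test and univariable Cox
regression (Efron tie handling) over overall or progression-free survival,
with ctDNA-detectable vs non-detectable as the single binary covariate.
Estimation is delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .core import ValidationError

DETECTABLE = "detectable"
NONDETECTABLE = "nondetectable"


@dataclass(frozen=True)
class SurvivalRecord:
    participant_id: str
    time_years: float
    event: bool
    group: str  # "detectable" | "nondetectable"

    def __post_init__(self) -> None:
        if self.time_years <= 0:
            raise ValidationError("time_years must be > 0")
        if self.group not in (DETECTABLE, NONDETECTABLE):
            raise ValidationError(f"unknown group {self.group!r}")


def _to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time_years for r in records],
            "event": [int(r.event) for r in records],
            "group": [int(r.group == DETECTABLE) for r in records],
        }
    )


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event/censoring time with columns
    ``time``, ``at_risk``, ``events``, ``censored``, ``survival``; deaths are
    processed before censorings at tied times (the standard convention).
    """
    if not records:
        raise ValidationError("km_estimate requires at least one record")
    df = _to_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    table = kmf.event_table
    # keep only times where something happened (drops the synthetic t=0 row)
    table = table[(table["observed"] + table["censored"]) > 0]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": kmf.survival_function_["KM_estimate"]
            .reindex(table.index)
            .to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(
    group1: Sequence[SurvivalRecord], group2: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Standard (Mantel–Haenszel) 1-df log-rank comparison of two groups;
    two-sided p from the chi-square distribution.  Symmetric under group
    label swap; identical groups give statistic 0, p = 1."""
    if not group1 or not group2:
        raise ValidationError("both groups must be non-empty")
    t1 = [r.time_years for r in group1]
    t2 = [r.time_years for r in group2]
    e1 = [int(r.event) for r in group1]
    e2 = [int(r.event) for r in group2]
    if t1 == t2 and e1 == e2:
        return LogrankResult(0.0, 1.0)
    res = _lifelines_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    unbounded: bool = False  # monotone likelihood: no events in one group

    def summary(self) -> str:
        if self.unbounded:
            return f"HR unbounded (no events in one group; {self.n_events} events total)"
        return (
            f"HR {self.hazard_ratio:.2f} "
            f"(95% CI {self.ci_low:.2f}-{self.ci_high:.2f}), p = {self.p_value:.3g}"
        )


def cox_univariable(records: Sequence[SurvivalRecord]) -> CoxResult:
    """Univariable Cox regression of survival on detection group.

    Efron handling of tied event times; Wald CI and p-value.  With no events
    in one group the partial likelihood is monotone and the HR is flagged
    unbounded rather than reported as a number.
    """
    df = _to_frame(records)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValidationError("no events observed; Cox model undefined")
    events_by_group = df.groupby("group")["event"].sum()
    if len(events_by_group) < 2 or (events_by_group == 0).any():
        hr = np.inf if events_by_group.get(1, 0) > 0 else 0.0
        return CoxResult(hr, np.nan, np.nan, np.nan, n_events, unbounded=True)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event", formula="group")
    row = cph.summary.loc["group"]
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p_value=float(row["p"]),
        n_events=n_events,
    )


def records_from_table(
    survival_df: pd.DataFrame,
    detected: dict[str, Optional[bool]],
    time_col: str = "os_years",
    event_col: str = "os_event",
) -> list[SurvivalRecord]:
    """Join clinical survival rows with per-participant detection calls.

    Participants whose detection status is NA (missing prerequisites) are
    excluded from the stratified comparison.
    """
    records = []
    for _, row in survival_df.iterrows():
        pid = row["participant_id"]
        status = detected.get(pid)
        if status is None:
            continue
        records.append(
            SurvivalRecord(
                pid,
                float(row[time_col]),
                bool(row[event_col]),
                DETECTABLE if status else NONDETECTABLE,
            )
        )
    return records
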