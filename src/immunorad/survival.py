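"""Kaplan–Meier estimation and log-rank comparisons between
immunophenotype groups.

Thin, typed surface over lifelines. The median convention is stated
explicitly because it matters for reporting: the median is the smallest
observed time at which the survival curve S(t) falls to 0.5 or below,
and is undefined (NaN) when the curve never reaches 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

log = logging.getLogger(__name__)


@dataclass
class SurvivalRecord:
    sample_id: str
    time_days: float
    event: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("time_days must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass
class KmCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when S never reaches 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk})


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([r.time_days for r in records], float)
    events = np.asarray([r.event for r in records], int)
    if len(times) == 0:
        raise ValueError("no records")
    if (times <= 0).any():
        raise ValueError("non-positive survival times")
    return times, events


def km_estimate(records) -> KmCurve:
    """Product-limit estimator over a list of records."""
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
        else kmf.event_table
    grid = tbl.index.to_numpy(float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = tbl["at_risk"].to_numpy()
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return KmCurve(grid, surv, at_risk, median)


def logrank(records, group_a: str, group_b: str) -> tuple[float, float]:
    """Two-group log-rank test (O-E with hypergeometric variance, 1 df)."""
    a = [r for r in records if r.group == group_a]
    b = [r for r in records if r.group == group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _to_arrays(a)
    tb, eb = _to_arrays(b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def logrank_global(records) -> tuple[float, float]:
    """k-group log-rank test across all groups present."""
    times, events = _to_arrays(records)
    groups = np.asarray([r.group for r in records])
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    if events.sum() == 0:
        raise ValueError("no events")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def idh_filter(clinical: pd.DataFrame) -> pd.DataFrame:
    """Keep IDH wild-type rows only (the study's prognosis population)."""
    if "idh_status" not in clinical.columns:
        raise ValueError("clinical table lacks an idh_status column")
    is_wt = clinical["idh_status"].astype(str).str.lower().isin(
        ("wild-type", "wildtype", "wt"))
    out = clinical[is_wt]
    log.info("IDH filter: %d of %d retained", len(out), len(clinical))
    if out.empty:
        log.warning("IDH filter removed every sample")
    return out


def records_from_tables(clinical: pd.DataFrame,
                        groups: pd.Series) -> list[SurvivalRecord]:
    shared = [s for s in clinical.index if s in groups.index]
    return [
        SurvivalRecord(str(s), float(clinical.loc[s, "survival_days"]),
                       int(clinical.loc[s, "event"]), str(groups.loc[s]))
        for s in shared
    ]


def group_survival_report(records) -> tuple[pd.DataFrame, dict]:
    """KM curves per group (long CSV form) and pairwise/global tests."""
    groups = sorted({r.group for r in records})
    frames = []
    medians = {}
    for g in groups:
        curve = km_estimate([r for r in records if r.group == g])
        df = curve.to_frame()
        df.insert(0, "group", g)
        frames.append(df)
        medians[g] = curve.median
    tests: dict = {"pairwise": {}, "median_by_group": medians}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            try:
                stat, p = logrank(records, ga, gb)
            except ValueError:
                continue
            tests["pairwise"][f"{ga}_vs_{gb}"] = {"statistic": stat, "p": p}
    if len(groups) >= 2:
        try:
            stat, p = logrank_global(records)
            tests["global"] = {"statistic": stat, "p": p}
        except ValueError:
            pass
    return pd.concat(frames, ignore_index=True), tests
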