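"""Kaplan-Meier estimation and two-group log-rank comparison.

Used to validate predicted MVI groups: patients called MVI+ should show worse
recurrence-free/overall survival than predicted MVI- patients. Tied event and
censoring times follow the standard censored-after-events convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import EmptyCohortError, SchemaError, UndefinedTestError


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival estimate for one group.

    Returns one row per distinct observed time with the at-risk count, event
    and censoring counts, and the right-continuous survival estimate
    S(t) = prod_{t_i <= t} (1 - d_i / n_i).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise EmptyCohortError("empty group")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise SchemaError("survival times must be finite and non-negative")
    kmf = KaplanMeierFitter().fit(t, e)
    table = kmf.event_table
    table = table[(table["observed"] + table["censored"]) > 0]  # drop the t=0 anchor
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.loc[table.index].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class LogrankResult:
    statistic: float   # chi-square with 1 df
    p_value: float


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> LogrankResult:
    """Standard two-group log-rank test (observed minus expected events over
    pooled risk sets, hypergeometric variance, chi-square with 1 df)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g))
    if len(labels) != 2:
        raise SchemaError(f"log-rank needs exactly two groups, got {labels}")
    a = g == labels[0]
    if a.all() or not a.any():
        raise EmptyCohortError("one log-rank group is empty")
    if not e.any():
        raise UndefinedTestError("log-rank needs at least one event")
    res = _ll_logrank(t[a], t[~a], e[a], e[~a])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def survival_by_group(
    metadata: pd.DataFrame, calls: pd.Series
) -> tuple[pd.DataFrame, LogrankResult]:
    """KM tables and log-rank comparison for predicted MVI groups.

    ``calls`` maps tumour sample ids to 'positive'/'negative'. Samples without
    usable survival data (unknown event status) are dropped.
    """
    meta = metadata.loc[calls.index]
    usable = meta["surv_event"].isin(["event", "censored"]) & meta["surv_time"].notna()
    meta = meta[usable]
    if meta.empty:
        raise EmptyCohortError("no samples with survival data")
    t = meta["surv_time"].to_numpy(dtype=float)
    e = (meta["surv_event"] == "event").to_numpy()
    grp = calls.loc[meta.index]
    tables = []
    for label in sorted(grp.unique()):
        sel = (grp == label).to_numpy()
        km = kaplan_meier(t[sel], e[sel])
        km.insert(0, "group", label)
        tables.append(km)
    result = logrank_test(t, e, grp.to_numpy())
    return pd.concat(tables, ignore_index=True), result
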