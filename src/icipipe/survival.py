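"""Survival analysis: Kaplan-Meier curves, log-rank tests and the
maximally-selected-rank-statistic cutpoint.

Kaplan-Meier estimation and the multi-group log-rank test are delegated to
lifelines; the optimal-cutpoint search (the ``surv_cutpoint``-style
maximally selected log-rank statistic) is implemented here because the
per-candidate standardized statistic is needed directly.

A cohort-level convention used throughout: survival analyses exclude
patients followed for less than 30 days (``filter_min_followup``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "filter_min_followup",
    "km_estimate",
    "logrank_test",
    "maxstat_cutpoint",
    "LogRankResult",
    "CutpointResult",
    "restricted_mean_survival",
]


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    max_statistic: float  # standardized |Z| at the chosen split
    n_candidates: int


def _check_survival(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("os_time", "os_event"):
        if col not in data.columns:
            raise ValueError(f"survival data needs an {col!r} column")
    if (data["os_time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not data["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be 0/1")
    return data


def filter_min_followup(data: pd.DataFrame, min_days: float = 30) -> pd.DataFrame:
    """Drop records with follow-up shorter than ``min_days`` (default 30)."""
    _check_survival(data)
    kept = data[data["os_time"] >= min_days]
    if kept.empty:
        raise ValueError(f"no records with follow-up >= {min_days} days")
    return kept.copy()


def km_estimate(data: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve with Greenwood standard errors.

    Returns a DataFrame over observed event times: ``time``, ``survival``,
    ``se`` (Greenwood), ``n_at_risk``. With zero events the curve is
    constant 1 (a warning is emitted).
    """
    _check_survival(data)
    if data["os_event"].sum() == 0:
        import warnings

        warnings.warn("no events observed; survival curve is constant 1", stacklevel=2)
    kmf = KaplanMeierFitter()
    kmf.fit(data["os_time"], event_observed=data["os_event"])
    event_times = np.sort(data.loc[data["os_event"] == 1, "os_time"].unique())
    if len(event_times) == 0:
        event_times = np.array([float(data["os_time"].max())])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    # Greenwood variance: S(t)^2 * sum d_i / (n_i (n_i - d_i))
    times = data["os_time"].to_numpy()
    events = data["os_event"].to_numpy()
    se = np.empty_like(surv)
    n_at_risk = np.empty(len(event_times), dtype=int)
    for i, t in enumerate(event_times):
        acc = 0.0
        for u in event_times[event_times <= t]:
            n_u = int((times >= u).sum())
            d_u = int(((times == u) & (events == 1)).sum())
            if n_u > d_u:
                acc += d_u / (n_u * (n_u - d_u))
        se[i] = surv[i] * np.sqrt(acc)
        n_at_risk[i] = int((times >= t).sum())
    return pd.DataFrame({"time": event_times, "survival": surv, "se": se, "n_at_risk": n_at_risk})


def logrank_test(data: pd.DataFrame, labels: pd.Series | np.ndarray) -> LogRankResult:
    """Multi-group log-rank test (chi-square with #groups - 1 df)."""
    _check_survival(data)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if data["os_event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(data["os_time"], labels, data["os_event"])
    return LogRankResult(statistic=float(res.test_statistic), df=len(groups) - 1, p=float(res.p_value))


def _two_group_z(times: np.ndarray, events: np.ndarray, in_high: np.ndarray) -> float:
    """Standardized two-sample log-rank statistic (O - E)/sqrt(V) for the
    ``in_high`` group, with the hypergeometric variance and the convention
    that censored observations at t stay at risk for events at t."""
    event_times = np.unique(times[events == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_high).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_high).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        return 0.0
    return float((O - E) / np.sqrt(V))


def maxstat_cutpoint(
    scores: pd.Series | np.ndarray,
    data: pd.DataFrame,
    minprop: float = 0.1,
) -> CutpointResult:
    """Optimal survival cutpoint by the maximally selected log-rank statistic.

    Candidate cutpoints are midpoints between consecutive distinct score
    values whose induced groups both hold at least ``minprop`` of the
    cohort; the cutpoint maximizing the absolute standardized two-sample
    log-rank statistic is returned.
    """
    _check_survival(data)
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n != len(data):
        raise ValueError("scores and survival data must be aligned")
    if n < 20:
        raise ValueError("cutpoint search needs at least 20 samples")
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise ValueError("all scores identical; no cutpoint exists")
    times = data["os_time"].to_numpy(dtype=float)
    events = data["os_event"].to_numpy(dtype=int)

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_group = minprop * n
    best: tuple[float, float] | None = None
    n_admissible = 0
    for c in candidates:
        high = scores > c
        n_high = high.sum()
        if n_high < min_group or (n - n_high) < min_group:
            continue
        n_admissible += 1
        z = abs(_two_group_z(times, events, high))
        if best is None or z > best[1]:
            best = (float(c), z)
    if best is None:
        raise ValueError(f"no candidate cutpoint satisfies minprop={minprop}")
    return CutpointResult(cutpoint=best[0], max_statistic=best[1], n_candidates=n_admissible)


def restricted_mean_survival(data: pd.DataFrame, horizon: float | None = None) -> float:
    """Area under the KM curve up to ``horizon`` (default: last observed time).

    Used to rank groups by prognosis when the KM median is undefined.
    """
    _check_survival(data)
    if horizon is None:
        horizon = float(data["os_time"].max())
    kmf = KaplanMeierFitter()
    kmf.fit(data["os_time"], event_observed=data["os_event"])
    sf = kmf.survival_function_
    times = np.concatenate([[0.0], sf.index.to_numpy(), [horizon]])
    probs = np.concatenate([[1.0], sf.iloc[:, 0].to_numpy(), [float(sf.iloc[-1, 0])]])
    keep = times <= horizon
    times, probs = times[keep], probs[keep]
    if times[-1] < horizon:
        times = np.append(times, horizon)
        probs = np.append(probs, probs[-1])
    # step function: survival is right-continuous
    return float(np.sum(probs[:-1] * np.diff(times)))
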