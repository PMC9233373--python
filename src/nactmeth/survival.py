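"""Product-limit survival curves, median survival, and the log-rank test.

Thin, validated wrappers around lifelines exposing exactly what the risk
evaluation needs: the Kaplan–Meier step function with at-risk and event
counts, the median survival time (smallest t with S(t) ≤ 0.5), right-
continuous evaluation at arbitrary times, and the 1-df chi-square log-rank
comparison of two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["SurvivalFit", "LogRankResult", "km_fit", "logrank_test", "survival_at"]


@dataclass(frozen=True)
class SurvivalFit:
    """Kaplan–Meier estimate at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S is 1 before
    the first event.  ``median`` is the smallest event time with
    S(t) ≤ 0.5, or None if the curve never reaches 0.5.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    max_observed_time: float

    @property
    def median(self) -> float | None:
        reached = self.survival <= 0.5
        if not reached.any():
            return None
        return float(self.event_times[np.argmax(reached)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p: float


def _check_inputs(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


def km_fit(times, events) -> SurvivalFit:
    """Product-limit estimate; simultaneous tied events handled jointly,
    censored-only times reduce the risk set without a step."""
    times, events = _check_inputs(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    at_event = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    event_times = at_event.index.to_numpy(float)
    return SurvivalFit(
        event_times=event_times,
        n_at_risk=at_event["at_risk"].to_numpy(int),
        n_events=at_event["observed"].to_numpy(int),
        survival=surv.loc[event_times].to_numpy(float),
        max_observed_time=float(times.max()),
    )


def survival_at(fit: SurvivalFit, t: float) -> tuple[float, bool]:
    """Right-continuous S(t); second element flags extrapolation beyond the
    last observed time."""
    if t < 0:
        raise ValueError("t must be ≥ 0")
    extrapolated = t > fit.max_observed_time
    idx = np.searchsorted(fit.event_times, t, side="right") - 1
    s = 1.0 if idx < 0 else float(fit.survival[idx])
    return s, extrapolated


def logrank_test(group_a: tuple, group_b: tuple) -> LogRankResult:
    """Two-group log-rank test (observed − expected over pooled event times,
    hypergeometric variance, chi-square with 1 df).

    With no events in either group the statistic is 0 and p = 1.
    """
    t_a, e_a = _check_inputs(*group_a)
    t_b, e_b = _check_inputs(*group_b)
    if e_a.sum() == 0 and e_b.sum() == 0:
        return LogRankResult(0.0, 1.0)
    res = _ll_logrank(t_a, t_b, event_observed_A=e_a, event_observed_B=e_b)
    return LogRankResult(float(res.test_statistic), float(res.p_value))
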