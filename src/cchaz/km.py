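"""Survival-curve estimation for case-cohort data.

Cases are oversampled in a case-cohort sample, so the ordinary
Nelson-Aalen / Kaplan-Meier estimators computed on the case-cohort rows
are biased.  The fix is a weighted Breslow increment,

    dLambda(t) = (#events at t) * (m/n) / (#at risk in the case-cohort rows at t),

i.e. the at-risk count is scaled up by n/m to stand in for the full
cohort.  The survival estimate is S(t) = exp(-Lambda(t)).  An alternative
form, a product-limit KM of the case-cohort rows raised to the power
m/n, agrees to O(d/r^2) and is available via ``method="product-limit"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import records_to_arrays

__all__ = ["SurvivalCurve", "casecohort_cumhaz", "casecohort_km", "km_at_events"]


@dataclass(frozen=True)
class SurvivalCurve:
    """Step-function survival estimate on the distinct event times."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    n_events: np.ndarray   # events at each time
    cumhaz: np.ndarray     # Lambda(t)


def _event_counts_and_risk(records):
    _, start, stop, event, _ = records_to_arrays(records)
    ev_times = stop[event == 1]
    if ev_times.size == 0:
        raise ValueError("no events: survival curve is identically 1")
    times, counts = np.unique(ev_times, return_counts=True)
    at_risk = ((start[None, :] < times[:, None]) & (times[:, None] <= stop[None, :])).sum(axis=1)
    return times, counts, at_risk


def casecohort_cumhaz(records, m: int, n: int) -> SurvivalCurve:
    """Weighted Breslow cumulative hazard for a case-cohort sample.

    ``m`` and ``n`` are the subcohort and full-cohort sizes; with m == n
    this is the ordinary Breslow / Nelson-Aalen estimator.
    """
    if m > n:
        raise ValueError(f"m={m} exceeds n={n}")
    times, counts, at_risk = _event_counts_and_risk(records)
    if np.any(at_risk == 0):
        raise ValueError("zero at-risk count at an event time: invalid counting process")
    increments = counts * (m / n) / at_risk
    cumhaz = np.cumsum(increments)
    return SurvivalCurve(
        times=times,
        survival=np.exp(-cumhaz),
        n_events=counts,
        cumhaz=cumhaz,
    )


def casecohort_km(records, m: int, n: int, method: str = "breslow") -> SurvivalCurve:
    """Case-cohort survival curve S(t).

    ``method="breslow"`` (default) exponentiates the weighted Breslow
    cumulative hazard; ``method="product-limit"`` raises the ordinary
    product-limit estimate of the case-cohort rows to the power m/n.
    """
    if method == "breslow":
        return casecohort_cumhaz(records, m, n)
    if method == "product-limit":
        if m > n:
            raise ValueError(f"m={m} exceeds n={n}")
        times, counts, at_risk = _event_counts_and_risk(records)
        if np.any(at_risk == 0):
            raise ValueError("zero at-risk count at an event time: invalid counting process")
        surv = np.cumprod(1.0 - counts / at_risk) ** (m / n)
        with np.errstate(divide="ignore"):
            cumhaz = -np.log(surv)
        return SurvivalCurve(times=times, survival=surv, n_events=counts, cumhaz=cumhaz)
    raise ValueError(f"unknown method {method!r}")


def km_at_events(curve: SurvivalCurve, event_times) -> np.ndarray:
    """Curve value at each event's own time; tied events share one value.

    ``event_times`` must be sorted ascending and every time must be a
    jump point of ``curve``.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        return np.empty(0)
    if np.any(np.diff(event_times) < 0):
        raise ValueError("event_times must be sorted ascending")
    idx = np.searchsorted(curve.times, event_times)
    bad = (idx >= curve.times.size) | (curve.times[np.minimum(idx, curve.times.size - 1)] != event_times)
    if np.any(bad):
        raise ValueError(f"event time(s) not on the curve: {event_times[bad][:5]}")
    return curve.survival[idx]
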