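"""Case-cohort Schoenfeld residuals and the smoothed departure curve.

For an event at time t with covariate vector x, the Schoenfeld residual
is x minus the exp(beta'x)-weighted mean of the covariate over the
case-cohort risk set at t.  Under proportional hazards the residuals have
mean zero given the event history, which is what the correlation tests
in :mod:`cchaz.phtest` exploit.

Scaled residuals follow the standard convention s_i = beta + d * V * r_i
(d the event count, V the fitted covariance); their lowess smooth G(t)
estimates the time-dependent departure, with beta + G(t) approximating a
time-varying coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import PseudoLikelihoodFit, _event_order, _risk_matrix
from .records import records_to_arrays

__all__ = [
    "ResidualTable",
    "SmoothedDeparture",
    "schoenfeld_residuals",
    "scaled_residuals",
    "smooth_departure",
]


@dataclass(frozen=True)
class ResidualTable:
    """Schoenfeld residuals, one row per event, ordered by (time, id)."""

    event_times: np.ndarray   # (d,) nondecreasing
    residuals: np.ndarray     # (d, p)
    event_ids: np.ndarray     # (d,) labels
    beta_used: np.ndarray     # (p,)

    @property
    def n_events(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class SmoothedDeparture:
    """Lowess smooth of the scaled residuals with a pointwise +-2 SE band.

    ``g_values`` estimates the time-varying coefficient beta + G(t); the
    departure G(t) itself is ``g_values - beta_ref``, flat at zero under
    proportional hazards.
    """

    grid_times: np.ndarray
    g_values: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    beta_ref: float

    @property
    def departure(self) -> np.ndarray:
        """G(t): the smoothed curve relative to the fitted coefficient."""
        return self.g_values - self.beta_ref


def schoenfeld_residuals(fit: PseudoLikelihoodFit, records, beta=None) -> ResidualTable:
    """Residuals r_ij = x_ij - E[x_j | risk set at t_i] at the fitted beta.

    ``beta`` overrides ``fit.beta`` (useful for the beta = 0 diagnostic,
    where the weighted mean collapses to the arithmetic risk-set mean).
    At beta-hat the residual columns sum to zero — the score equations.
    """
    ids, start, stop, event, X = records_to_arrays(records)
    beta = np.asarray(fit.beta if beta is None else beta, dtype=float)
    ev_idx = _event_order(stop, event, ids)
    if ev_idx.size == 0:
        raise ValueError("no events: nothing to compute residuals for")
    R = _risk_matrix(start, stop, stop[ev_idx])
    if np.any(R.sum(axis=1) == 0):
        raise RuntimeError("event with empty risk set: corrupt counting process")
    eta = X @ beta
    w = np.exp(eta - eta.max())
    W = R * w[None, :]
    mean = (W @ X) / W.sum(axis=1)[:, None]
    resid = X[ev_idx] - mean
    return ResidualTable(
        event_times=stop[ev_idx],
        residuals=resid,
        event_ids=ids[ev_idx],
        beta_used=beta,
    )


def scaled_residuals(fit: PseudoLikelihoodFit, resid_table: ResidualTable) -> np.ndarray:
    """Scaled residuals s_i = beta + d * V * r_i, shape (d, p).

    The row mean approximately recovers beta (exactly, when the residual
    columns sum to zero at the fitted optimum).
    """
    V = fit.covariance
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("singular covariance: cannot scale residuals")
    d = resid_table.n_events
    return fit.beta[None, :] + d * (resid_table.residuals @ V.T)


def smooth_departure(
    resid_table: ResidualTable,
    fit: PseudoLikelihoodFit,
    component: int = 0,
    span: float = 0.6,
    n_grid: int = 60,
) -> SmoothedDeparture:
    """Lowess smooth of the scaled residuals for one covariate vs event time.

    Parameters
    ----------
    component : int
        Covariate column to smooth.
    span : float
        Lowess span (fraction of points in each local fit); 3 robustness
        iterations are used.
    n_grid : int
        Number of grid points spanning [min, max] event time.

    Notes
    -----
    The band is a pointwise kernel-variance band: +-2 sigma_local where
    sigma is estimated from the residuals about the smooth and the local
    factor is sqrt(sum w^2)/sum w with tricube weights over the span
    window.  It is not a simultaneous band.
    """
    d = resid_table.n_events
    if d < 10:
        raise ValueError(f"too few events to smooth ({d} < 10)")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    t = resid_table.event_times
    s = scaled_residuals(fit, resid_table)[:, component]
    sm = lowess(s, t, frac=span, it=3, return_sorted=True)
    ts, fitted = sm[:, 0], sm[:, 1]
    grid = np.linspace(t.min(), t.max(), min(n_grid, d))
    g = np.interp(grid, ts, fitted)

    resid = s - np.interp(t, ts, fitted)
    dof = max(d - 2, 1)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    k = max(int(np.ceil(span * d)), 2)
    se = np.empty_like(grid)
    for i, t0 in enumerate(grid):
        dist = np.abs(t - t0)
        h = np.partition(dist, k - 1)[k - 1]
        if h == 0:
            h = np.max(dist) or 1.0
        w = np.clip(1 - (dist / h) ** 3, 0, None) ** 3
        se[i] = sigma * np.sqrt(np.sum(w**2)) / np.sum(w)
    beta_ref = float(fit.beta[component])
    return SmoothedDeparture(
        grid_times=grid,
        g_values=g,
        band_low=g - 2 * se,
        band_high=g + 2 * se,
        beta_ref=beta_ref,
    )
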