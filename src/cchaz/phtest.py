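"""Correlation tests of the proportional-hazards assumption.

Each covariate's Schoenfeld residuals are Pearson-correlated against
three functions of the event times:

* the event time itself,
* the rank order of the event times (average ranks for ties),
* the case-cohort weighted Kaplan-Meier estimate at each event time.

A significant correlation is evidence against proportional hazards.  The
three tests probe the same departure on different time scales; as a
conservative summary the minimum of the three p-values per covariate is
exposed as ``min_p`` (no multiplicity adjustment is applied — report it
as a minimum, not a corrected p-value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import PseudoLikelihoodFit
from .km import SurvivalCurve, casecohort_km, km_at_events
from .residuals import ResidualTable, schoenfeld_residuals

__all__ = ["PHTestReport", "time_functions", "pearson_test", "run_ph_tests"]

TIME_FUNCTIONS = ("time", "rank", "km")


@dataclass(frozen=True)
class PHTestReport:
    """Per-covariate Pearson correlations and p-values for the three tests.

    ``correlations`` and ``p_values`` are (p, 3) arrays with columns in
    the order (time, rank, km); ``min_p`` is the rowwise minimum p-value.
    """

    covariates: tuple[str, ...]
    correlations: np.ndarray
    p_values: np.ndarray
    d: int

    @property
    def min_p(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmin(self.p_values, axis=1)

    def to_frame(self):
        """Tabular view: one row per covariate with all six statistics."""
        import pandas as pd

        cols = {}
        for k, name in enumerate(TIME_FUNCTIONS):
            cols[f"corr_{name}"] = self.correlations[:, k]
            cols[f"p_{name}"] = self.p_values[:, k]
        cols["min_p"] = self.min_p
        return pd.DataFrame(cols, index=list(self.covariates))


def time_functions(resid_table: ResidualTable, curve: SurvivalCurve):
    """The three event-time transforms paired with the residual rows.

    Returns ``(times, ranks, km)``, each of length d.  Ranks use the
    average-rank convention for ties; tied events share one KM value.
    """
    t = resid_table.event_times
    ranks = stats.rankdata(t, method="average")
    km = km_at_events(curve, t)
    if km.size != t.size:
        raise ValueError("KM vector length does not match the residual table")
    return t, ranks, km


def pearson_test(x, y) -> tuple[float, float]:
    """Two-sided Pearson correlation test.

    p is computed from t = r sqrt((d-2)/(1-r^2)) on d-2 degrees of
    freedom.  A constant input vector has no defined correlation and
    yields (nan, nan) with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def run_ph_tests(
    fit: PseudoLikelihoodFit,
    records,
    m: int,
    n: int,
    covariate_names=None,
) -> PHTestReport:
    """Run all three correlation tests for every covariate.

    Residuals are computed at the fitted beta; the KM transform uses the
    case-cohort weighted survival curve on the same records.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to test proportionality")
    table = schoenfeld_residuals(fit, records)
    curve = casecohort_km(records, m, n)
    funcs = time_functions(table, curve)
    p = table.residuals.shape[1]
    if covariate_names is None:
        covariate_names = tuple(f"x{j + 1}" for j in range(p))
    corr = np.full((p, 3), np.nan)
    pval = np.full((p, 3), np.nan)
    for j in range(p):
        for k, f in enumerate(funcs):
            corr[j, k], pval[j, k] = pearson_test(f, table.residuals[:, j])
    return PHTestReport(
        covariates=tuple(covariate_names),
        correlations=corr,
        p_values=pval,
        d=table.n_events,
    )
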