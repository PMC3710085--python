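"""Prentice pseudolikelihood fitting for case-cohort Cox models.

The pseudolikelihood replaces each event's full-cohort risk set with the
case-cohort risk set R~(t) = (at-risk subcohort members) U (the case
itself).  With the data in counting-process form that risk set is exactly
the set of records whose interval contains the event time, so the
log-pseudolikelihood has the familiar partial-likelihood shape

    l(beta) = sum_events [ beta'x_i - log sum_{k in R~_i} exp(beta'x_k) ]

with Breslow handling of ties (tied events each contribute their own
numerator against the shared denominator).  Maximisation is plain
Newton-Raphson with step-halving; the model-based covariance is the
inverse observed information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import records_to_arrays

__all__ = [
    "PseudoLikelihoodFit",
    "pseudo_loglik_score_info",
    "fit",
    "SeparationError",
    "DegenerateCovariateError",
]


class SeparationError(RuntimeError):
    """Monotone pseudolikelihood: beta diverges (perfect separation)."""


class DegenerateCovariateError(ValueError):
    """A covariate column is constant, so its information is zero."""


@dataclass(frozen=True)
class PseudoLikelihoodFit:
    """Result of maximizing the Prentice pseudolikelihood.

    ``beta`` holds log hazard ratios (exp(beta) is the HR per unit
    increase); ``covariance`` is the model-based inverse observed
    information; ``robust_covariance`` the optional dfbeta sandwich.
    """

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_events: int
    robust_covariance: np.ndarray | None = None

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def confidence_intervals(self, level: float = 0.95) -> np.ndarray:
        """Wald CI for the hazard ratios, shape (p, 2)."""
        from scipy.stats import norm

        se = np.sqrt(np.diag(self.covariance))
        z = norm.ppf(0.5 + level / 2.0)
        lo = np.exp(self.beta - z * se)
        hi = np.exp(self.beta + z * se)
        return np.column_stack([lo, hi])


def _event_order(stop, event, ids):
    """Indices of event records ordered by (time, id) — the row order used everywhere."""
    ev = np.flatnonzero(event == 1)
    order = sorted(ev, key=lambda i: (stop[i], str(ids[i])))
    return np.asarray(order, dtype=int)


def _risk_matrix(start, stop, event_times):
    """Boolean (d, N) matrix: R[i, k] iff record k is at risk at event time i."""
    t = event_times[:, None]
    return (start[None, :] < t) & (t <= stop[None, :])


def _prepare(records):
    ids, start, stop, event, X = records_to_arrays(records)
    if not np.any(event == 1):
        raise ValueError("nothing to fit: no events in the data")
    ev_idx = _event_order(stop, event, ids)
    R = _risk_matrix(start, stop, stop[ev_idx])
    return ids, start, stop, event, X, ev_idx, R


def _loglik_score_info_arrays(beta, X, ev_idx, R):
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    # stabilise exp against large linear predictors
    eta = eta - eta.max()
    w = np.exp(eta)
    W = R * w[None, :]                      # (d, N)
    denom = W.sum(axis=1)                   # (d,)
    Xe = X[ev_idx]                          # (d, p)
    loglik = float(np.sum(eta[ev_idx] - np.log(denom)))
    S1 = W @ X                              # (d, p)
    mean = S1 / denom[:, None]
    score = (Xe - mean).sum(axis=0)
    p = X.shape[1]
    XX = (X[:, :, None] * X[:, None, :]).reshape(X.shape[0], p * p)
    S2 = (W @ XX).reshape(-1, p, p)
    info = (S2 / denom[:, None, None] - mean[:, :, None] * mean[:, None, :]).sum(axis=0)
    return loglik, score, info


def pseudo_loglik_score_info(beta, records):
    """Log-pseudolikelihood, score vector and observed information at ``beta``.

    Returns ``(loglik, score, info)`` where ``info`` is minus the Hessian.
    Ties are handled by the Breslow approximation: each tied event keeps
    its own numerator term against the common risk-set denominator.
    """
    _, _, _, _, X, ev_idx, R = _prepare(records)
    return _loglik_score_info_arrays(beta, X, ev_idx, R)


def fit(
    records,
    init_beta=None,
    tol: float = 1e-9,
    max_iter: int = 25,
    robust: bool = False,
) -> PseudoLikelihoodFit:
    """Maximize the Prentice pseudolikelihood by Newton-Raphson.

    Parameters
    ----------
    records : list of IntervalRecord
        Counting-process rows (see :func:`cchaz.records.to_counting_process`).
    init_beta : array-like, optional
        Starting value, default 0 (safe: each term is concave in beta).
    tol : float
        Converged when ``max|score| <= tol * (1 + |loglik|)``.
    max_iter : int
        Newton iterations before returning a flagged non-converged result.
    robust : bool
        Also compute the grouped-jackknife (dfbeta) sandwich covariance.

    Raises
    ------
    DegenerateCovariateError
        If a covariate column is constant across records.
    SeparationError
        If ``||beta||`` exceeds 50 (monotone likelihood).
    """
    ids, start, stop, event, X, ev_idx, R = _prepare(records)
    p = X.shape[1]
    if np.any(np.ptp(X, axis=0) == 0.0):
        j = int(np.flatnonzero(np.ptp(X, axis=0) == 0.0)[0])
        raise DegenerateCovariateError(
            f"degenerate covariate: column {j} is constant across all records"
        )
    beta = np.zeros(p) if init_beta is None else np.atleast_1d(np.asarray(init_beta, float)).copy()

    loglik, score, info = _loglik_score_info_arrays(beta, X, ev_idx, R)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(score)) <= tol * (1.0 + abs(loglik)):
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise DegenerateCovariateError("singular information matrix") from exc
        # step-halving keeps the Newton path monotone in loglik
        for _ in range(40):
            cand = beta + step
            cand_ll, cand_score, cand_info = _loglik_score_info_arrays(cand, X, ev_idx, R)
            if cand_ll >= loglik or np.max(np.abs(step)) < 1e-14:
                break
            step = step / 2.0
        beta, loglik, score, info = cand, cand_ll, cand_score, cand_info
        if np.linalg.norm(beta) > 50.0:
            raise SeparationError(
                "separation: |beta| diverging, the pseudolikelihood appears monotone"
            )
    else:
        converged = np.max(np.abs(score)) <= tol * (1.0 + abs(loglik))

    covariance = np.linalg.inv(info)
    robust_cov = None
    if robust:
        robust_cov = _dfbeta_sandwich(beta, covariance, X, ev_idx, R, ids)
    return PseudoLikelihoodFit(
        beta=beta,
        covariance=covariance,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        n_events=len(ev_idx),
        robust_covariance=robust_cov,
    )


def _dfbeta_sandwich(beta, covariance, X, ev_idx, R, ids):
    """Grouped-jackknife sandwich: sum of dfbeta outer products.

    dfbeta_k ~= V * U_k with U_k the score residual of record k,

        U_k = delta_k (x_k - xbar_i(k)) - sum_{i: k in R_i} w_k (x_k - xbar_i) / denom_i.
    """
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    W = R * w[None, :]
    denom = W.sum(axis=1)
    mean = (W @ X) / denom[:, None]
    N, p = X.shape
    U = np.zeros((N, p))
    U[ev_idx] += X[ev_idx] - mean
    # subtraction term, vectorised over events
    frac = R / denom[:, None]                       # (d, N)
    U -= w[:, None] * (frac.sum(axis=0)[:, None] * X - frac.T @ mean)
    D = U @ covariance
    return D.T @ D
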