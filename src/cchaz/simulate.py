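"""Synthetic cohorts for the proportional-hazards test study.

Event times come from piecewise-exponential or Weibull hazards, with
covariate effects that are either constant over time (proportional
hazards hold) or change across time intervals / with Weibull shape
(proportional hazards violated).  Censoring is Uniform(0, c) with c
calibrated by bisection so that the cohort event rate lands on a target
(default 7.5%, the midpoint of the 5-10% band typical of rare-disease
cohorts that motivate the case-cohort design).  A case-cohort sample is
then drawn: a simple random subcohort of size m plus every case outside
it.

Twelve named scenarios are registered in :data:`SCENARIOS`:

===== ====================================================================
1.1   binary covariate, non-monotonic piecewise hazard, constant HR 0.5
1.2   binary, piecewise hazards with interval HRs 2, 4/3, 1, 2/3 (non-PH)
1.3   binary, increasing Weibull hazards, shapes 1.5 vs 2.0 (non-PH)
1.4   binary, decreasing Weibull hazards, shapes 0.3 vs 0.6 (non-PH)
1.5   binary, constant vs increasing Weibull hazards, 1.0 vs 1.5 (non-PH)
2.1   standard-normal covariate, piecewise baseline, constant HR 0.5
2.2   normal covariate, Weibull(shape 1.5, scale 4) baseline, HR 1.5
2.3   normal covariate, piecewise baseline, interval HRs .5,.5,1,1 (non-PH)
3.1   binary + normal, both constant HR 0.5
3.2   binary HRs .5,.5,1,1 (non-PH); normal constant 0.5
3.3   binary constant 0.5; normal HRs .5,.5,1,1 (non-PH)
3.4   both covariates with interval HRs .5,.5,1,1 (non-PH)
===== ====================================================================

All use a cohort of n = 2000 with a subcohort of m = 500.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .records import CaseCohortDataset, CohortSubject, make_casecohort_dataset

__all__ = [
    "PiecewiseHazardSpec",
    "WeibullHazardSpec",
    "GroupedWeibullSpec",
    "CovariateSpec",
    "ScenarioSpec",
    "SCENARIOS",
    "sample_piecewise_exponential",
    "sample_weibull",
    "calibrate_censoring",
    "simulate_cohort",
    "sample_casecohort",
    "simulate_casecohort",
]

# fixed pilot seed: the censoring bound is a per-scenario design constant,
# not a per-run source of randomness
_PILOT_SEED = 971
_PILOT_N = 40_000


@dataclass(frozen=True)
class PiecewiseHazardSpec:
    """Piecewise-constant baseline hazard with (possibly interval-varying) log HRs.

    ``cutpoints`` are the interior interval boundaries; ``rates`` has one
    entry per interval (len(cutpoints) + 1).  ``log_hr`` holds one row per
    covariate: a scalar for a time-constant effect or a per-interval tuple.
    """

    cutpoints: tuple[float, ...]
    rates: tuple[float, ...]
    log_hr: tuple = ()

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.cutpoints) + 1:
            raise ValueError("need len(rates) == len(cutpoints) + 1")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be > 0")
        if list(self.cutpoints) != sorted(self.cutpoints) or (
            self.cutpoints and self.cutpoints[0] <= 0
        ):
            raise ValueError("cutpoints must be positive and ascending")
        object.__setattr__(self, "log_hr", tuple(self.log_hr))

    @property
    def n_intervals(self) -> int:
        return len(self.rates)

    def log_hr_matrix(self, p: int) -> np.ndarray:
        """(p, n_intervals) matrix of log hazard ratios."""
        J = self.n_intervals
        if len(self.log_hr) != p:
            raise ValueError(f"log_hr has {len(self.log_hr)} rows for {p} covariates")
        out = np.empty((p, J))
        for j, row in enumerate(self.log_hr):
            row = np.atleast_1d(np.asarray(row, float))
            if row.size == 1:
                out[j] = row[0]
            elif row.size == J:
                out[j] = row
            else:
                raise ValueError(f"log_hr row {j} has length {row.size}, expected 1 or {J}")
        return out

    def cumulative_hazard(self, t, x=None) -> np.ndarray:
        """Lambda(t | x) evaluated exactly (piecewise-linear in t)."""
        t = np.atleast_1d(np.asarray(t, float))
        bounds = np.concatenate([[0.0], self.cutpoints])
        rates = np.asarray(self.rates)
        if x is not None:
            x = np.atleast_1d(np.asarray(x, float))
            B = self.log_hr_matrix(x.size)
            rates = rates * np.exp(x @ B)
        out = np.zeros_like(t)
        for j in range(self.n_intervals):
            lo = bounds[j]
            hi = bounds[j + 1] if j + 1 < len(bounds) else np.inf
            out += rates[j] * np.clip(t - lo, 0.0, hi - lo)
        return out


@dataclass(frozen=True)
class WeibullHazardSpec:
    """Weibull hazard, S(t) = exp(-(t/scale)^shape), with constant log HRs."""

    shape: float
    scale: float
    log_hr: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be > 0")
        object.__setattr__(self, "log_hr", tuple(float(b) for b in self.log_hr))


@dataclass(frozen=True)
class GroupedWeibullSpec:
    """Separate Weibull hazards for the two levels of a binary covariate.

    Used for the crossing / non-proportional Weibull scenarios, where the
    two exposure groups have different shape parameters and the hazard
    ratio varies as a power of t.
    """

    unexposed: WeibullHazardSpec
    exposed: WeibullHazardSpec


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate distribution: kind 'binary' (P(1) = prob) or 'normal' (N(0,1))."""

    name: str
    kind: str
    prob: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "normal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "binary":
            return (rng.random(n) < self.prob).astype(float)
        return rng.standard_normal(n)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: covariates, hazard model, design sizes."""

    label: str
    covariates: tuple[CovariateSpec, ...]
    hazard: object
    n_cohort: int = 2000
    m_subcohort: int = 500
    event_rate_band: tuple[float, float] = (0.05, 0.10)

    def __post_init__(self) -> None:
        if not 0 < self.m_subcohort < self.n_cohort:
            raise ValueError("need 0 < m_subcohort < n_cohort")
        lo, hi = self.event_rate_band
        if not 0 < lo < hi < 1:
            raise ValueError("event_rate_band must be inside (0, 1)")

    @property
    def target_event_rate(self) -> float:
        return 0.5 * (self.event_rate_band[0] + self.event_rate_band[1])

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)


# ---------------------------------------------------------------------------
# samplers

def sample_piecewise_exponential(spec: PiecewiseHazardSpec, x, u) -> np.ndarray:
    """Invert the piecewise-linear cumulative hazard: t = Lambda^{-1}(-log u | x).

    ``x`` is an (n, p) covariate matrix (or (p,) for one subject) and
    ``u`` uniform(0,1) draws.  The last interval extends to infinity so a
    time always exists.
    """
    x = np.atleast_2d(np.asarray(x, float))
    u = np.atleast_1d(np.asarray(u, float))
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in (0, 1)")
    n, p = x.shape
    J = spec.n_intervals
    B = spec.log_hr_matrix(p)                       # (p, J)
    haz = np.asarray(spec.rates) * np.exp(x @ B)    # (n, J) per-subject interval hazards
    bounds = np.concatenate([[0.0], spec.cutpoints])
    lengths = np.diff(np.concatenate([bounds, [np.inf]]))
    H = np.zeros((n, J + 1))
    for j in range(J - 1):
        H[:, j + 1] = H[:, j] + lengths[j] * haz[:, j]
    H[:, J] = np.inf
    E = -np.log(u)
    t = np.empty(n)
    done = np.zeros(n, dtype=bool)
    for j in range(J):
        sel = ~done & (E < H[:, j + 1])
        t[sel] = bounds[j] + (E[sel] - H[sel, j]) / haz[sel, j]
        done |= sel
    return t


def sample_weibull(spec: WeibullHazardSpec, u, x=None) -> np.ndarray:
    """Weibull inversion: t = scale * ((-log u) * exp(-beta'x))^(1/shape)."""
    u = np.atleast_1d(np.asarray(u, float))
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in (0, 1)")
    E = -np.log(u)
    if x is not None and len(spec.log_hr):
        x = np.atleast_2d(np.asarray(x, float))
        E = E * np.exp(-(x @ np.asarray(spec.log_hr)))
    return spec.scale * E ** (1.0 / spec.shape)


def _latent_times(spec: ScenarioSpec, X: np.ndarray, u: np.ndarray) -> np.ndarray:
    hz = spec.hazard
    if isinstance(hz, PiecewiseHazardSpec):
        return sample_piecewise_exponential(hz, X, u)
    if isinstance(hz, WeibullHazardSpec):
        return sample_weibull(hz, u, X)
    if isinstance(hz, GroupedWeibullSpec):
        g = X[:, 0]  # first covariate is the binary group indicator
        t = np.empty(X.shape[0])
        for val, sub in ((0.0, hz.unexposed), (1.0, hz.exposed)):
            sel = g == val
            if np.any(sel):
                t[sel] = sample_weibull(sub, u[sel])
        return t
    raise TypeError(f"unknown hazard spec {type(hz).__name__}")


# ---------------------------------------------------------------------------
# censoring calibration

def calibrate_censoring(
    scenario: ScenarioSpec,
    target_rate: float | None = None,
    n_pilot: int = _PILOT_N,
    seed: int = _PILOT_SEED,
    tol: float = 0.01,
) -> float:
    """Uniform(0, c) censoring bound hitting the target cohort event rate.

    A single pilot sample of latent times and censoring uniforms is drawn,
    making the event rate a monotone deterministic function of c; c is
    then found by bisection to within ``tol`` (1 percentage point) of the
    target.  Raises if the target is unattainable, reporting the
    achievable range.
    """
    if target_rate is None:
        target_rate = scenario.target_event_rate
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    X = np.column_stack([c.draw(n_pilot, rng) for c in scenario.covariates])
    u = rng.random(n_pilot)
    u = np.clip(u, 1e-300, 1 - 1e-16)
    T = _latent_times(scenario, X, u)
    U = rng.random(n_pilot)

    def rate(c: float) -> float:
        return float(np.mean(T <= c * U))

    # cap the censoring horizon: a bound orders of magnitude beyond the
    # hazard's timescale means the target rate is effectively unattainable
    c_max = 1e7
    lo, hi = 0.0, 1.0
    while rate(hi) < target_rate:
        hi *= 2.0
        if hi > c_max:
            raise ValueError(
                f"unattainable event rate {target_rate}: achievable range is "
                f"[0, {rate(c_max):.4g}] with censoring bounds up to {c_max:.3g}"
            )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * max(hi, 1.0):
            break
    c = 0.5 * (lo + hi)
    if abs(rate(c) - target_rate) > tol:
        raise ValueError(
            f"calibration failed: closest achievable rate {rate(c):.4f} vs target {target_rate}"
        )
    return c


@lru_cache(maxsize=64)
def _cached_censoring_bound(scenario: ScenarioSpec) -> float:
    return calibrate_censoring(scenario)


# ---------------------------------------------------------------------------
# cohort and case-cohort generation

def simulate_cohort(scenario: ScenarioSpec, seed, censor_bound: float | None = None):
    """Draw the full cohort of ``scenario.n_cohort`` subjects.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  It is
    split into independent covariate / latent-time / censoring streams so
    that each ingredient is reproducible on its own.  The censoring bound
    is calibrated once per scenario (and cached) unless given.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cov, s_lat, s_cen = ss.spawn(3)
    if censor_bound is None:
        censor_bound = _cached_censoring_bound(scenario)
    if censor_bound <= 0:
        raise ValueError("censoring bound must be > 0")
    n = scenario.n_cohort
    rng_cov = np.random.default_rng(s_cov)
    X = np.column_stack([c.draw(n, rng_cov) for c in scenario.covariates])
    u = np.clip(np.random.default_rng(s_lat).random(n), 1e-300, 1 - 1e-16)
    T = _latent_times(scenario, X, u)
    C = np.random.default_rng(s_cen).random(n) * censor_bound
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    # guard against zero follow-up from a censoring draw at exactly 0
    time = np.maximum(time, 1e-300)
    width = len(str(n))
    return [
        CohortSubject(
            id=f"s{i:0{width}d}",
            time=float(time[i]),
            event=int(event[i]),
            in_subcohort=1,
            covariates=tuple(X[i]),
        )
        for i in range(n)
    ]


def sample_casecohort(cohort, m: int, seed, allow_full: bool = False) -> CaseCohortDataset:
    """Case-cohort sample: random subcohort of size m plus all outside cases.

    Subjects that are neither subcohort members nor cases are dropped —
    they are never observed in a real case-cohort study.  ``allow_full``
    permits m == n (useful for oracle comparisons against full-cohort
    estimators).
    """
    cohort = list(cohort)
    n = len(cohort)
    if m > n or (m == n and not allow_full):
        raise ValueError(f"need m < n (got m={m}, n={n})")
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    chosen = set(rng.choice(n, size=m, replace=False).tolist())
    kept = []
    for i, s in enumerate(cohort):
        if i in chosen:
            kept.append(
                CohortSubject(s.id, s.time, s.event, in_subcohort=1, covariates=s.covariates)
            )
        elif s.event == 1:
            kept.append(
                CohortSubject(s.id, s.time, s.event, in_subcohort=0, covariates=s.covariates)
            )
    return make_casecohort_dataset(kept, n_cohort=n)


def simulate_casecohort(scenario: ScenarioSpec, seed) -> CaseCohortDataset:
    """One replicate: simulate the cohort, then draw the case-cohort sample."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cohort, s_sub = ss.spawn(2)
    cohort = simulate_cohort(scenario, s_cohort)
    return sample_casecohort(cohort, scenario.m_subcohort, s_sub)


# ---------------------------------------------------------------------------
# scenario registry

def _make_scenarios() -> dict[str, ScenarioSpec]:
    ln = math.log
    cuts = (0.3, 0.5, 0.8)
    exposed_rates = (0.1, 0.2, 0.05, 0.1)
    binary = CovariateSpec("exposure", "binary", 0.5)
    normal = CovariateSpec("z", "normal")
    reg: dict[str, ScenarioSpec] = {}

    # Scenario 1: one binary covariate, varying hazard shapes
    # 1.1 proportional: unexposed hazard is 0.5 x exposed, so baseline
    # (unexposed) rates are half the exposed ones and HR(exposed) = 2.
    reg["1.1"] = ScenarioSpec(
        "1.1",
        (binary,),
        PiecewiseHazardSpec(cuts, tuple(0.5 * r for r in exposed_rates), (ln(2.0),)),
    )
    # 1.2 non-proportional: interval HRs 2, 4/3, 1, 2/3
    reg["1.2"] = ScenarioSpec(
        "1.2",
        (binary,),
        PiecewiseHazardSpec(
            cuts,
            (0.05, 0.15, 0.05, 0.15),
            ((ln(2.0), ln(0.2 / 0.15), 0.0, ln(0.1 / 0.15)),),
        ),
    )
    # 1.3-1.5: Weibull pairs (shape, scale): exposed first in each printed pair
    reg["1.3"] = ScenarioSpec(
        "1.3",
        (binary,),
        GroupedWeibullSpec(
            unexposed=WeibullHazardSpec(shape=2.0, scale=4.0),
            exposed=WeibullHazardSpec(shape=1.5, scale=4.0),
        ),
    )
    reg["1.4"] = ScenarioSpec(
        "1.4",
        (binary,),
        GroupedWeibullSpec(
            unexposed=WeibullHazardSpec(shape=0.6, scale=80.0),
            exposed=WeibullHazardSpec(shape=0.3, scale=80.0),
        ),
    )
    reg["1.5"] = ScenarioSpec(
        "1.5",
        (binary,),
        GroupedWeibullSpec(
            unexposed=WeibullHazardSpec(shape=1.5, scale=4.0),
            exposed=WeibullHazardSpec(shape=1.0, scale=4.0),
        ),
    )

    # Scenario 2: one standard-normal covariate
    reg["2.1"] = ScenarioSpec(
        "2.1", (normal,), PiecewiseHazardSpec(cuts, exposed_rates, (ln(0.5),))
    )
    reg["2.2"] = ScenarioSpec(
        "2.2", (normal,), WeibullHazardSpec(shape=1.5, scale=4.0, log_hr=(ln(1.5),))
    )
    reg["2.3"] = ScenarioSpec(
        "2.3",
        (normal,),
        PiecewiseHazardSpec(cuts, exposed_rates, ((ln(0.5), ln(0.5), 0.0, 0.0),)),
    )

    # Scenario 3: binary + independent normal on the 1.1-shaped baseline
    const = ln(0.5)
    vary = (ln(0.5), ln(0.5), 0.0, 0.0)
    for label, b_hr, z_hr in (
        ("3.1", const, const),
        ("3.2", vary, const),
        ("3.3", const, vary),
        ("3.4", vary, vary),
    ):
        reg[label] = ScenarioSpec(
            label,
            (binary, normal),
            PiecewiseHazardSpec(cuts, exposed_rates, (b_hr, z_hr)),
        )
    return reg


SCENARIOS: dict[str, ScenarioSpec] = _make_scenarios()
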