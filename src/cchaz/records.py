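"""Data model for case-cohort survival data.

A case-cohort study observes covariates on a simple random subcohort of
size ``m`` drawn at baseline from a cohort of size ``n``, plus every
incident case that falls outside the subcohort.  The types here carry that
design explicitly (``n`` and ``m`` are needed downstream even though
non-case non-subcohort subjects never appear in the data) and convert it
to the counting-process (start, stop] form that the pseudolikelihood
fitter and the residual machinery operate on.

The key construction is the late-entry device for outside cases: a case
that is not a subcohort member is given a start time immediately before
its own event, so it enters its own risk set and no other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSubject",
    "CaseCohortDataset",
    "IntervalRecord",
    "make_casecohort_dataset",
    "to_counting_process",
    "risk_set_at",
    "records_to_arrays",
]


@dataclass(frozen=True)
class CohortSubject:
    """One subject: follow-up time, event status, design membership, covariates.

    Covariates are time-fixed; ``in_subcohort == 0`` implies ``event == 1``
    (subjects outside the subcohort are only observed when they become cases).
    """

    id: str
    time: float
    event: int
    in_subcohort: int
    covariates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"subject {self.id!r}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.id!r}: event must be 0 or 1")
        if self.in_subcohort not in (0, 1):
            raise ValueError(f"subject {self.id!r}: in_subcohort must be 0 or 1")
        if self.in_subcohort == 0 and self.event != 1:
            raise ValueError(
                f"subject {self.id!r}: non-subcohort non-case — a subject outside "
                "the subcohort can only appear as a case"
            )
        object.__setattr__(self, "covariates", tuple(float(c) for c in self.covariates))


@dataclass(frozen=True)
class CaseCohortDataset:
    """Validated case-cohort sample with its design sizes ``n`` and ``m``."""

    subjects: tuple[CohortSubject, ...]
    n_cohort: int
    m_subcohort: int

    @property
    def n_covariates(self) -> int:
        return len(self.subjects[0].covariates)

    @property
    def n_events(self) -> int:
        return sum(s.event for s in self.subjects)

    @property
    def sampling_fraction(self) -> float:
        """m/n, the subcohort sampling fraction used by the weighted KM."""
        return self.m_subcohort / self.n_cohort


@dataclass(frozen=True)
class IntervalRecord:
    """One (start, stop] at-risk interval; time-fixed covariates mean one per subject."""

    id: str
    start: float
    stop: float
    event: int
    covariates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"record {self.id!r}: need start < stop")
        object.__setattr__(self, "covariates", tuple(float(c) for c in self.covariates))


def make_casecohort_dataset(subjects, n_cohort: int) -> CaseCohortDataset:
    """Validate subjects and assemble a :class:`CaseCohortDataset`.

    ``m_subcohort`` is computed as the number of subjects flagged
    ``in_subcohort=1``; ``n_cohort`` must be supplied because the cohort
    members who are neither cases nor subcohort members are absent.
    """
    subjects = tuple(subjects)
    if not subjects:
        raise ValueError("no subjects")
    p = len(subjects[0].covariates)
    ids = [s.id for s in subjects]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValueError(f"duplicate subject id(s): {sorted(dups)}")
    for s in subjects:
        if len(s.covariates) != p:
            raise ValueError(f"subject {s.id!r}: covariate length {len(s.covariates)} != {p}")
    if n_cohort < len(subjects):
        raise ValueError(
            f"n_cohort={n_cohort} smaller than the number of observed subjects "
            f"({len(subjects)})"
        )
    m = sum(s.in_subcohort for s in subjects)
    if m == 0:
        raise ValueError("empty subcohort")
    return CaseCohortDataset(subjects=subjects, n_cohort=n_cohort, m_subcohort=m)


def _default_entry_epsilon(time: float, min_gap: float) -> float:
    # keeps the outside case's entry interval free of every foreign stop time
    # while staying representable next to `time`
    return min(min_gap / 2.0, time * 1e-6)


def to_counting_process(
    dataset: CaseCohortDataset,
    entry_epsilon_policy=None,
) -> list[IntervalRecord]:
    """Convert a case-cohort dataset to (start, stop] counting-process rows.

    Subcohort members contribute ``(0, time]`` with their event status.
    Cases outside the subcohort enter an instant before their own event,
    ``(time - eps, time]``, so they contribute to no other risk set.

    Parameters
    ----------
    entry_epsilon_policy
        Callable ``(time, min_gap) -> eps`` choosing the late-entry offset;
        default is ``min(min_gap/2, time * 1e-6)`` where ``min_gap`` is the
        smallest positive gap between distinct observed times.
    """
    if entry_epsilon_policy is None:
        entry_epsilon_policy = _default_entry_epsilon
    times = np.unique([s.time for s in dataset.subjects])
    min_gap = float(np.min(np.diff(times))) if times.size > 1 else float(times[0])

    out: list[IntervalRecord] = []
    for s in dataset.subjects:
        if s.in_subcohort:
            out.append(IntervalRecord(s.id, 0.0, s.time, s.event, s.covariates))
        else:
            eps = float(entry_epsilon_policy(s.time, min_gap))
            if not 0.0 < eps < s.time or s.time - eps == s.time:
                warnings.warn(
                    f"entry epsilon {eps} unusable for outside case {s.id!r} at "
                    f"t={s.time}; falling back to relative eps = time * 1e-9",
                    stacklevel=2,
                )
                eps = s.time * 1e-9
            out.append(IntervalRecord(s.id, s.time - eps, s.time, 1, s.covariates))
    return out


def risk_set_at(records, t: float) -> set[str]:
    """Ids at risk at time ``t`` under the (start, stop] convention.

    A subject is at risk at its own stop time; a start exactly at ``t``
    excludes it.  At an event time this yields the Prentice risk set: the
    at-risk subcohort members plus the (possibly outside) case itself.
    """
    if not t > 0:
        raise ValueError("t must be > 0")
    return {r.id for r in records if r.start < t <= r.stop}


def records_to_arrays(records):
    """Stack interval records into numpy arrays (ids, start, stop, event, X)."""
    records = list(records)
    ids = np.array([r.id for r in records], dtype=object)
    start = np.array([r.start for r in records], dtype=float)
    stop = np.array([r.stop for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    X = np.array([r.covariates for r in records], dtype=float)
    if X.ndim == 1:
        X = X.reshape(len(records), -1)
    return ids, start, stop, event, X
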