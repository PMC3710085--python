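"""Reading and writing case-cohort datasets, plus packaged toy fixtures.

Datasets travel as delimited text with a header row
``id,time,event,subcohort,<covariate...>`` and an optional metadata line
``# n_cohort=<n>`` (a case-cohort file cannot represent the unobserved
cohort members, so the cohort size must come from somewhere external).
Counting-process output uses ``id,start,stop,event,<covariate...>``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import CaseCohortDataset, CohortSubject, make_casecohort_dataset
from .simulate import SCENARIOS, simulate_casecohort

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_counting_process",
    "make_fixture",
    "toy6_dataset",
]

REQUIRED_COLUMNS = ("id", "time", "event", "subcohort")


def _read_metadata(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_dataset(path, n_cohort: int | None = None, covariates=None) -> CaseCohortDataset:
    """Read a case-cohort CSV/TSV into a validated dataset.

    ``n_cohort`` may be given explicitly or via a ``# n_cohort=...``
    metadata line in the file; ``covariates`` selects (and orders) the
    covariate columns, defaulting to every non-required column.
    """
    path = Path(path)
    meta = _read_metadata(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    else:
        unknown = [c for c in covariates if c not in df.columns]
        if unknown:
            raise ValueError(f"unknown covariate column(s): {', '.join(unknown)}")
    if not covariates:
        raise ValueError("no covariate columns found")
    if n_cohort is None:
        if "n_cohort" not in meta:
            raise ValueError("n_cohort not given and no '# n_cohort=' metadata line found")
        n_cohort = int(meta["n_cohort"])
    times = pd.to_numeric(df["time"], errors="coerce")
    if times.isna().any():
        bad = df.loc[times.isna(), "id"].tolist()[:5]
        raise ValueError(f"non-numeric time for subject(s) {bad}")
    subjects = [
        CohortSubject(
            id=str(row["id"]),
            time=float(row["time"]),
            event=int(row["event"]),
            in_subcohort=int(row["subcohort"]),
            covariates=tuple(float(row[c]) for c in covariates),
        )
        for _, row in df.iterrows()
    ]
    return make_casecohort_dataset(subjects, n_cohort=n_cohort)


def write_dataset(dataset: CaseCohortDataset, path, covariate_names=None) -> None:
    """Write a dataset back to CSV with its ``# n_cohort=`` metadata line."""
    p = dataset.n_covariates
    if covariate_names is None:
        covariate_names = [f"x{j + 1}" for j in range(p)]
    rows = [
        {
            "id": s.id,
            "time": s.time,
            "event": s.event,
            "subcohort": s.in_subcohort,
            **{name: s.covariates[j] for j, name in enumerate(covariate_names)},
        }
        for s in dataset.subjects
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# n_cohort={dataset.n_cohort}\n")
        df.to_csv(fh, index=False)


def write_counting_process(records, path, covariate_names=None) -> None:
    """Write counting-process rows ``id,start,stop,event,<covariate...>``."""
    records = list(records)
    p = len(records[0].covariates)
    if covariate_names is None:
        covariate_names = [f"x{j + 1}" for j in range(p)]
    rows = [
        {
            "id": r.id,
            "start": np.format_float_positional(r.start, trim="0"),
            "stop": r.stop,
            "event": r.event,
            **{name: r.covariates[j] for j, name in enumerate(covariate_names)},
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def toy6_dataset() -> CaseCohortDataset:
    """A 6-subject worked example: 4 subcohort members + 2 outside cases.

    Small enough for every quantity (risk sets, pseudolikelihood terms,
    residuals, KM steps) to be checked by hand.
    """
    subjects = [
        CohortSubject("A", 2.0, 1, 1, (1.0,)),
        CohortSubject("B", 3.0, 0, 1, (0.0,)),
        CohortSubject("C", 4.0, 1, 1, (1.0,)),
        CohortSubject("D", 5.0, 0, 1, (0.0,)),
        CohortSubject("E", 2.5, 1, 0, (0.0,)),
        CohortSubject("F", 3.5, 1, 0, (1.0,)),
    ]
    return make_casecohort_dataset(subjects, n_cohort=10)


def oracle_mn_dataset(seed: int = 7, n: int = 40) -> CaseCohortDataset:
    """An m = n dataset (everyone in the 'subcohort'): the full-cohort limit.

    With m = n the Prentice risk sets coincide with standard Cox risk
    sets, so fits and curves can be compared against full-cohort tools.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t = rng.exponential(scale=np.exp(-0.5 * x))
    c = rng.exponential(scale=1.5, size=n)
    time = np.maximum(np.minimum(t, c), 1e-12)
    event = (t <= c).astype(int)
    subjects = [
        CohortSubject(f"s{i:03d}", float(time[i]), int(event[i]), 1, (float(x[i]),))
        for i in range(n)
    ]
    return make_casecohort_dataset(subjects, n_cohort=n)


FIXTURE_KINDS = ("toy6", "oracle-mn") + tuple(f"scenario-{k}" for k in sorted(SCENARIOS))


def make_fixture(kind: str, seed: int = 0, outdir=".") -> Path:
    """Write a named fixture CSV and return its path.

    Kinds: ``toy6`` (hand-checkable 6-subject example), ``oracle-mn``
    (m = n full-cohort limit), ``scenario-<label>`` (one case-cohort
    replicate of a registered simulation scenario).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "toy6":
        data = toy6_dataset()
        names = ["x1"]
    elif kind == "oracle-mn":
        data = oracle_mn_dataset(seed=seed)
        names = ["x1"]
    elif kind.startswith("scenario-"):
        label = kind.removeprefix("scenario-")
        if label not in SCENARIOS:
            raise ValueError(f"unknown scenario {label!r}; known: {sorted(SCENARIOS)}")
        spec = SCENARIOS[label]
        data = simulate_casecohort(spec, seed)
        names = list(spec.covariate_names)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; known kinds: {FIXTURE_KINDS}")
    path = outdir / f"{kind}.csv"
    write_dataset(data, path, covariate_names=names)
    return path
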