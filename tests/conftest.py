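import numpy as np
import pytest

from cchaz import (
    CohortSubject,
    make_casecohort_dataset,
    to_counting_process,
    toy6_dataset,
)


@pytest.fixture(scope="session")
def toy6():
    """Hand-checkable 6-subject case-cohort dataset (4 subcohort + 2 outside cases)."""
    return toy6_dataset()


@pytest.fixture(scope="session")
def toy6_records(toy6):
    return to_counting_process(toy6)


def random_full_cohort(seed: int, n: int = 30, p: int = 1):
    """Random m = n dataset with continuous (tie-free) times.

    In the full-cohort limit the Prentice risk sets coincide with standard
    Cox risk sets, so these datasets support oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.uniform(-1, 1, size=p)
    t = rng.exponential(scale=np.exp(-(X @ beta)))
    c = rng.exponential(scale=np.quantile(t, 0.8), size=n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    if event.sum() < 3:  # ensure enough events to fit
        event[:3] = 1
    subjects = [
        CohortSubject(f"s{i:03d}", float(max(time[i], 1e-9)), int(event[i]), 1, tuple(X[i]))
        for i in range(n)
    ]
    return make_casecohort_dataset(subjects, n_cohort=n)
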