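import numpy as np
import pandas as pd
import pytest

from seqtrials import simulate_cohort, to_person_period
from seqtrials.cohort import LongitudinalCohort


@pytest.fixture(scope="session")
def cohort_s1():
    """A moderate scenario-1 cohort shared across read-only tests."""
    return simulate_cohort("scenario1", n=2000, seed=7)


@pytest.fixture(scope="session")
def pp_s1(cohort_s1):
    return to_person_period(cohort_s1)


@pytest.fixture(scope="session")
def two_period_binary():
    """Two-visit binary world: tree records plus the equivalent cohort.

    Survival is discrete (event times 0.5 / 1.5), treatment is absorbing,
    and the confounder is binary, so saturated models are available and
    the nonparametric tree estimators apply exactly.
    """
    rng = np.random.default_rng(5)
    n = 400
    L0 = rng.integers(0, 2, n)
    A0 = (rng.random(n) < 0.3 + 0.3 * L0).astype(int)
    Y1 = (rng.random(n) < 0.2 + 0.1 * L0 - 0.05 * A0).astype(int)
    L1 = np.where(Y1 == 0,
                  (rng.random(n) < 0.3 + 0.2 * L0 - 0.1 * A0).astype(int), -1)
    A1 = np.where(Y1 == 0,
                  np.maximum(A0, (rng.random(n)
                                  < 0.25 + 0.3 * np.maximum(L1, 0)).astype(int)),
                  -1)
    Y2 = np.where(Y1 == 0,
                  (rng.random(n) < 0.25 + 0.1 * np.maximum(L1, 0)
                   - 0.05 * A1).astype(int), -1)
    records = pd.DataFrame({
        "L0": L0, "A0": A0, "Y1": Y1,
        "L1": np.where(Y1 == 0, L1, np.nan),
        "A1": np.where(Y1 == 0, A1, np.nan),
        "Y2": np.where(Y1 == 0, Y2, np.nan),
    })
    T = np.where(Y1 == 1, 0.5, np.where(Y2 == 1, 1.5, 2.0))
    event = (Y1 == 1) | (Y2 == 1)
    cohort = LongitudinalCohort(
        ids=np.arange(n),
        A=np.column_stack([A0, np.where(Y1 == 0, A1, 0)]),
        L=np.column_stack([L0, np.where(Y1 == 0, L1, 0)]).astype(float),
        T=T, event=event)
    return records, cohort
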