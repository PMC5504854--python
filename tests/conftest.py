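import numpy as np
import pandas as pd
import pytest

import wcr


@pytest.fixture
def fixture_cohort():
    cohort, _ = wcr.make_fixture_example()
    return cohort


@pytest.fixture
def tiny_cohort():
    """3 subjects, all cause-1 events, distinct times."""
    df = pd.DataFrame(
        {
            "subject_id": [0, 1, 2],
            "time": [1.0, 2.0, 3.0],
            "event": [1, 1, 1],
            "arm": ["a", "a", "a"],
        }
    )
    return wcr.CohortTable(df, reference_arm="a")


@pytest.fixture(scope="session")
def sim_cohort():
    """Mid-sized confounded simulated cohort shared across tests."""
    cohort, truth = wcr.generate_cohort(wcr.SimulationConfig(n=4000, seed=42))
    return cohort, truth


def make_cohort(times, events, arms=None, weights=None, covs=None, reference=None):
    n = len(times)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "arm": np.asarray(arms if arms is not None else ["a"] * n, dtype=object),
        }
    )
    if weights is not None:
        df["weight"] = np.asarray(weights, dtype=float)
    if covs:
        for k, v in covs.items():
            df[k] = v
    ref = reference if reference is not None else str(df["arm"].iloc[0])
    return wcr.CohortTable(df, reference_arm=ref)
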