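import numpy as np
import pandas as pd
import pytest

from gaitbalance import prep, simdata


@pytest.fixture(scope="session")
def cohort():
    """Cohort-calibrated feature table, 30 minority / 100 majority rows."""
    return simdata.simulate_cohort(seed=0)


@pytest.fixture(scope="session")
def prepped(cohort):
    """Power-transformed and standardised cohort table."""
    transformed, _ = prep.power_transform(cohort)
    standardized, _ = prep.standardize(transformed)
    return standardized


@pytest.fixture(scope="session")
def small_minority_frame():
    """Tiny single-class frame for generator-contract tests."""
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal([2.0, -1.0], [0.5, 0.8], (100, 2)),
                      columns=["a", "b"])
    df["class"] = simdata.MINORITY_LABEL
    df["subject_id"] = [f"m{i}" for i in range(len(df))]
    return df
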