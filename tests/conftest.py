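import numpy as np
import pandas as pd
import pytest

from msmcpm import (
    generate_development,
    obs_20pct_treated,
    obs_50pct_treated,
    rct_10pct_dropout,
)
from msmcpm.experiment_runner import calibrated


@pytest.fixture(scope="session")
def rct_cal():
    return calibrated(rct_10pct_dropout(), 0.0)


@pytest.fixture(scope="session")
def obs50_cal():
    return calibrated(obs_50pct_treated(), 0.0)


@pytest.fixture(scope="session")
def obs20_cal():
    return calibrated(obs_20pct_treated(), 0.0)


@pytest.fixture(scope="session")
def obs50_dev(obs50_cal):
    """A mid-sized observational development cohort shared across tests."""
    return generate_development(obs50_cal, 20_000, seed=1)


@pytest.fixture(scope="session")
def rct_dev(rct_cal):
    return generate_development(rct_cal, 20_000, seed=2)


@pytest.fixture()
def toy_cohort():
    """Six-subject cohort with a known treatment pattern."""
    return pd.DataFrame(
        {
            "x0": [0.1, -0.3, 1.2, 0.0, -1.1, 0.5],
            "a0": [0, 1, 0, 1, 1, 0],
            "x1": [0.2, -0.5, 1.0, 0.3, -1.4, 0.6],
            "a1": [0, 1, 0, 0, 1, 1],
            "y": [0, 0, 1, 0, 1, 1],
        }
    )
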