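import numpy as np
import pandas as pd
import pytest

from amhcut import (
    AgeStepGenParams,
    CohortGenParams,
    StepGenParams,
    generate_age_step_outcome,
    generate_cohort,
    generate_step_data,
)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The calibrated synthetic cohort at 5000 per group, seed 1."""
    return generate_cohort(CohortGenParams(n_case=5000, n_control=5000, seed=1))


@pytest.fixture(scope="session")
def step_data_2000() -> pd.DataFrame:
    """Step-model data at the standard recovery truth (c=4.5, PPV=.95, NPV=.85)."""
    return generate_step_data(StepGenParams(n=2000, seed=7))


@pytest.fixture(scope="session")
def age_step_6000() -> pd.DataFrame:
    """Age-band prevalence fixture: cut-points (27, 35), prevalences (.8, .5, .1)."""
    return generate_age_step_outcome(
        AgeStepGenParams(cutpoints=(27.0, 35.0), prevalences=(0.8, 0.5, 0.1), n=6000, seed=3)
    )


@pytest.fixture
def six_point_step():
    """x = 1..6 with the three largest diseased: a perfectly separating marker."""
    return np.arange(1.0, 7.0), np.array([0, 0, 0, 1, 1, 1])
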