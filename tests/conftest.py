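import numpy as np
import pytest

from lgascreen import SimulationConfig, simulate_cohort_df
from lgascreen.simulate import (
    synthetic_birthweight_reference,
    synthetic_chart_suite,
    truth_efw_chart,
)


@pytest.fixture(scope="session")
def truth_chart():
    return truth_efw_chart()


@pytest.fixture(scope="session")
def bw_ref():
    return synthetic_birthweight_reference()


@pytest.fixture(scope="session")
def chart_suite():
    return synthetic_chart_suite()


@pytest.fixture(scope="session")
def cohort_358():
    """Default-condition cohort at the study's size."""
    return simulate_cohort_df(SimulationConfig(n_subjects=358, seed=1))


@pytest.fixture(scope="session")
def cohort_10k():
    """Large cohort for marginal-recovery and dose-response checks."""
    return simulate_cohort_df(SimulationConfig(n_subjects=10_000, seed=2))


@pytest.fixture()
def rng():
    """Fresh, fixed-seed generator per test: deterministic and order-independent."""
    return np.random.default_rng(2024)
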