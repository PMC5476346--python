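import numpy as np
import pytest

from neurochron.kinetics import standard_schedule
from neurochron.synthetic import (SimulationConfig, generate_cohort,
                                  simulate_reference_tac)


@pytest.fixture(scope="session")
def schedule():
    return standard_schedule()


@pytest.fixture(scope="session")
def reference_curve(schedule):
    """(tac, fine_times, fine_values) of the noiseless reference region."""
    return simulate_reference_tac(schedule, peak_time_s=300.0, scale=1.0)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort for fast end-to-end tests."""
    return SimulationConfig(n_train=40, n_ds=12, n_control=8, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, include_tacs=False)


@pytest.fixture(scope="session")
def default_cohort_tables():
    """Default-size cohort without the expensive imaging/TAC payloads."""
    return generate_cohort(SimulationConfig(seed=21), include_maps=False,
                           include_tacs=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
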