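import numpy as np
import pytest
from hypothesis import settings

from chlymph.synthetic_cohort import SimulationConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient simulated cohort with ground truth."""
    return simulate_cohort(SimulationConfig(n_patients=40, seed=123))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
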