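import numpy as np
import pytest

from facesym import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    params = SimulationParams(n_individuals=120, n_loci=15, seed=11)
    return simulate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
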