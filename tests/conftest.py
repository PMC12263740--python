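import numpy as np
import pytest

from nlmrsim import ScenarioConfig, generate_cohort, simulation_a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A 500-person scenario-A cohort with interaction and confounding."""
    return generate_cohort(simulation_a(n=500, seed=42))


@pytest.fixture
def null_config():
    """No interaction, no confounding: x = 0.3 g + e_x, y = e_y."""
    return ScenarioConfig(n=2000, n_replicates=3, seed=7, mu=2.0)
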