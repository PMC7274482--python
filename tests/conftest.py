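import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lvdilution import SimulationConfig
from lvdilution.synth import example_community

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def trio_params():
    """Three-species community with a bistable pair and two coexisting pairs."""
    return example_community()


@pytest.fixture(scope="session")
def bistable_pair(trio_params):
    """Fast/slow pair bistable between DF 10^1.5 and 10^3.5."""
    return trio_params.pair(0, 1)


@pytest.fixture(scope="session")
def coexist_pair(trio_params):
    """Pair coexisting between DF 10^1.5 and 10^4."""
    return trio_params.pair(2, 1)


@pytest.fixture
def ideal_config():
    """Infinite-population model: no extinction cutoff."""
    return SimulationConfig(extinction_threshold=0.0, max_cycles=400)
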