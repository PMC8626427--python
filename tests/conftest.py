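import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from firetrends.grids import GridSpec
from firetrends.synthetic import FireProcessParams, simulate_fire_history

settings.register_profile(
    "ci", derandomize=True, max_examples=60, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_history():
    """A 30x30, 90-year stationary Bernoulli(0.05) wildfire history."""
    return simulate_fire_history(
        FireProcessParams(shape=(30, 30), start_year=1930, end_year=2019, p=0.05, seed=11)
    )


@pytest.fixture
def equator_grid():
    """A 10x10 grid of 0.01-degree cells straddling the equator."""
    return GridSpec(nrows=10, ncols=10, lat_origin=0.05, lon_origin=0.0, cell_size=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
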