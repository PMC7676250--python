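import numpy as np
import pytest
from hypothesis import settings

from fooddemand import (
    WorldSpec, default_parameters, make_drivers, make_observations,
    run_scenario,
)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_world():
    """A 12-country world with noiseless observations (fast shared fixture)."""
    spec = WorldSpec(n_countries=12, seed=11)
    drivers = make_drivers(spec)
    obs = make_observations(drivers, spec.truth, noise=0)
    return spec, drivers, obs


@pytest.fixture(scope="session")
def base_result(small_world):
    spec, drivers, _ = small_world
    return run_scenario(drivers, spec.truth)


@pytest.fixture(scope="session")
def truth():
    return default_parameters()
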