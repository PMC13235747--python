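import numpy as np
import pytest

from u5m.b3 import B3Config, fit_b3
from u5m.synthetic import SimConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """Six synthetic countries with the default study conditions."""
    return generate_world(SimConfig(n_countries=6, seed=7))


@pytest.fixture(scope="session")
def fitted_country(small_world):
    """One synthetic country with a moderate-budget U5MR fit."""
    country = small_world[0]
    traj = fit_b3(country.observations,
                  B3Config(n_warmup=250, n_draws=250, seed=7),
                  indicator="U5MR")
    return country, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
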