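import numpy as np
import pytest

from trimda import RunConfig, generate_scenario
from trimda.core import ApgSettings


@pytest.fixture(scope="session")
def small_scenario():
    """A small, quickly fittable scenario for unit tests."""
    return generate_scenario(n_m=40, n_d=30, r_true=4, seed=11)


@pytest.fixture(scope="session")
def default_scenario():
    """The standard benchmark scenario used by the protocol tests."""
    return generate_scenario()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def fast_config():
    return RunConfig(seed=3, solver=ApgSettings(max_inner=30, max_outer=20))
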