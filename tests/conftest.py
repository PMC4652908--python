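import numpy as np
import pytest

from gridstreams import (
    CONFIG_A,
    MovementParams,
    build_environment,
    derive_configuration_b,
    synthesize_trajectory,
)


@pytest.fixture(scope="session")
def env_a():
    return build_environment(CONFIG_A, seed=7)


@pytest.fixture(scope="session")
def env_b(env_a):
    return derive_configuration_b(env_a)


@pytest.fixture(scope="session")
def short_params():
    return MovementParams(n_sample=3000)


@pytest.fixture(scope="session")
def traj_short(env_a, short_params):
    return synthesize_trajectory(env_a, short_params, seed=11)


@pytest.fixture(scope="session")
def traj_short_b(env_b, short_params):
    return synthesize_trajectory(env_b, short_params, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
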