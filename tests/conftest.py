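import numpy as np
import pytest

from adscreensim import RunConfig, Simulator
from adscreensim.fixtures import Fixtures, make_toy_fixtures


@pytest.fixture(scope="session")
def toy_fixtures() -> Fixtures:
    life, sexes, incidence = make_toy_fixtures(seed=7)
    return Fixtures(life_table=life, sex_proportions=sexes, incidence=incidence, source="toy")


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(population_size=20_000, n_trials=50, trial_size=500, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config, toy_fixtures) -> Simulator:
    """Shared simulator on toy fixtures; callers must not mutate its state."""
    return Simulator(small_config, toy_fixtures)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
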