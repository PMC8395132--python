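import numpy as np
import pytest

from smtrack import modeclass
from smtrack.trajsim import SimulationConfig


@pytest.fixture(scope="session")
def mode_classifier():
    """One trained classifier shared by all tests (deterministic seed)."""
    table = modeclass.build_training_set(n_per_class=4000, seed=1)
    return modeclass.train_mode_classifier(table, seed=1)


@pytest.fixture(scope="session")
def training_table():
    """Small deterministic training table for training-contract tests."""
    return modeclass.build_training_set(n_per_class=600, seed=7)


@pytest.fixture()
def base_config():
    return SimulationConfig(dt=0.1, n_steps=100, D=0.1, loc_sigma=0.05,
                            L=0.3, v=0.5, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
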