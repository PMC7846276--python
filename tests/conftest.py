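import numpy as np
import pytest

from lapsekit import synthetic
from lapsekit.models import TaskConfig


@pytest.fixture(scope="session")
def task() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def generative_params() -> dict:
    return synthetic.default_generative_params()


@pytest.fixture(scope="session")
def exploration_dataset(generative_params):
    """One synthetic subject's worth of exploration-model choices."""
    trials = synthetic.generate_trials(n_trials=30000, seed=101)
    return synthetic.simulate_choices(trials, "exploration", generative_params,
                                      seed=102)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
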