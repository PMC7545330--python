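import numpy as np
import pytest

from iladyn.data_model import apply_inclusion_filter
from iladyn.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_persons=12, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small generated study shared across tests (12 persons, 7 days)."""
    dataset, truth, episodes = generate_study(small_config)
    dataset, _ = apply_inclusion_filter(dataset)
    return dataset, truth, episodes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
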