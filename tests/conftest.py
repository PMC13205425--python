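import numpy as np
import pytest

from evogmd.fitness import CVConfig
from evogmd.synthetic import SyntheticConfig, generate_dataset, to_labeled


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_splits():
    """Default two-orientation benchmark: 32 train / 8 test labeled crops."""
    train, test = generate_dataset(SyntheticConfig(seed=0))
    return to_labeled(train), to_labeled(test)


@pytest.fixture(scope="session")
def cv_config():
    return CVConfig()
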