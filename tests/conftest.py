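import numpy as np
import pytest

from hatl import SimConfig, TrainConfig, simulate_multimodal_features, train_hatl


@pytest.fixture(scope="session")
def mini_ds():
    """Small coupled multimodal dataset on the mini profile (3 subjects)."""
    return simulate_multimodal_features(
        SimConfig(seed=0, rows_per_subject=80))


@pytest.fixture(scope="session")
def scaled_mini(mini_ds):
    return mini_ds.scale()


@pytest.fixture(scope="session")
def quick_model(scaled_mini):
    """A briefly trained CWGAN-GP model for synthesis/checkpoint tests."""
    return train_hatl(scaled_mini, "cwgan-gp",
                      TrainConfig(epochs=10, batch_size=32, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
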