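import numpy as np
import pytest

from scfactor import TrainConfig, simulate_dataset, svi_fit


@pytest.fixture(scope="session")
def small_sim():
    """Small 3-type, 2-batch benchmark used across unit tests."""
    cm, truth, labels = simulate_dataset(n_cells=80, G=40, seed=1)
    return cm, truth, labels


@pytest.fixture(scope="session")
def small_model(small_sim):
    """A briefly trained model on the small benchmark (unit-test scale)."""
    cm, truth, labels = small_sim
    cfg = TrainConfig(epochs=15, kl_warmup_epochs=10, seed=0)
    return svi_fit(cm, labels, cfg=cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
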