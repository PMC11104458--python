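import numpy as np
import pytest

from cardiolens.model import ModelConfig, TrainConfig, build_model, train
from cardiolens.synthgen import make_planted_benchmark


@pytest.fixture(scope="session")
def toy_config():
    """Tiny 2-lead configuration for exact/oracle tests."""
    return ModelConfig(n_leads=2, input_length=16, enc_channels=2, enc_kernel=5,
                       trunk_channels=3, trunk_kernel=3, trunk_strides=(2,),
                       n_labels=2, seed=7)


@pytest.fixture(scope="session")
def planted_small():
    """Small planted-in-V1 benchmark: train/test data at T=1024."""
    xtr, ytr, plant = make_planted_benchmark(160, t_samples=1024, seed=11)
    xte, yte, _ = make_planted_benchmark(100, t_samples=1024, seed=12)
    return xtr, ytr, xte, yte, plant


@pytest.fixture(scope="session")
def planted_model(planted_small):
    """Model trained on the small planted benchmark (shared across tests)."""
    xtr, ytr, _, _, _ = planted_small
    cfg = ModelConfig(n_leads=12, input_length=1024, enc_channels=4,
                      enc_kernel=17, trunk_channels=8, trunk_kernel=9,
                      trunk_strides=(4, 4), n_labels=1, seed=0)
    model = build_model(cfg)
    train(model, xtr, ytr, TrainConfig(lr=3e-3, batch_size=32, max_epochs=12,
                                       patience=3, seed=0))
    return model
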