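import numpy as np
import pytest

from protomae.backbone import ModelConfig, PRESETS
from protomae.mae import MaskedAutoencoder

# A deliberately small architecture so gradient checks and training-dynamics
# tests run in milliseconds; the tiny preset is exercised by the
# end-to-end/acceptance tests.
MICRO = ModelConfig(
    image_size=16, patch_size=4, channels=3,
    encoder_dim=16, encoder_layers=2, encoder_heads=2,
    decoder_dim=8, decoder_layers=1, decoder_heads=2,
    mlp_ratio=2,
)


@pytest.fixture
def micro_config():
    return MICRO


@pytest.fixture
def micro_model():
    return MaskedAutoencoder(MICRO, seed=7)


@pytest.fixture
def tiny_config():
    return PRESETS["vit-tiny-test"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def float64_model(config: ModelConfig, seed: int = 0) -> MaskedAutoencoder:
    """A model with float64 parameters, for finite-difference gradient checks."""
    model = MaskedAutoencoder(config, seed=seed)
    for t in model.params.values():
        t.data = t.data.astype(np.float64)
    model._dec_pos = model._dec_pos.astype(np.float64)
    if model.encoder._fixed_pos is not None:
        model.encoder._fixed_pos = model.encoder._fixed_pos.astype(np.float64)
    return model
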