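import numpy as np
import pytest

from thinslice import DLSModel, ModelConfig, PhantomConfig, make_paired_dataset


@pytest.fixture(scope="session")
def micro_config() -> ModelConfig:
    """Smallest legal architecture; fast enough for per-op tests."""
    return ModelConfig(
        r=5,
        L=2,
        embed_dim=8,
        enc_depth=1,
        dec_depth=1,
        n_heads=2,
        window_3d=(2, 2, 2),
        window_2d=(2, 2),
        mlp_ratio=2.0,
    )


@pytest.fixture(scope="session")
def micro_model(micro_config) -> DLSModel:
    return DLSModel(micro_config, seed=0)


@pytest.fixture(scope="session")
def small_pairs():
    """Four small paired phantoms (thin 21x32x32, thick 5x32x32)."""
    cfg = PhantomConfig(shape_thin=(21, 32, 32), seed=0)
    return make_paired_dataset(4, cfg, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
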