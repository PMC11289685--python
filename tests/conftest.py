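import numpy as np
import pytest

from mtlgrn import synthetic_data as sd
from mtlgrn import training


@pytest.fixture(scope="session")
def tiny_world():
    """Small, fast world for unit tests (30 genes, short promoters)."""
    return sd.make_world(n_genes=30, n_samples=20, d_latent=4,
                         edge_density=0.1, noise_sd=0.1, motif_len=6,
                         n_knockouts=6, seed=7, promoter_len=200)


@pytest.fixture(scope="session")
def tiny_config():
    """Config sized for the tiny world; a few dozen epochs."""
    return training.RunConfig(seed=7, epochs=40, early_stop_patience=40,
                              n_heads=2, d_head=8, d_z=8, d_t=6,
                              d_promoter=8, d_attr=4)


@pytest.fixture(scope="session")
def tiny_checkpoint(tiny_world, tiny_config):
    ckpt, history = training.train(tiny_world, tiny_config)
    return ckpt, history


@pytest.fixture
def rng():
    return np.random.default_rng(0)
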