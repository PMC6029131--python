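import numpy as np
import pytest

from rnabind import BindingSiteModel, ModelConfig, SimConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_sim(seed=5, **kw):
    """A small, quickly trainable world: 40-nt reads, strong planted motif."""
    defaults = dict(
        n_pos=150, n_neg=150, length=40, seed=seed,
        seq_motif="UGUGUGU", seq_motif_freq=1.0,
        struct_motif="HHHHH", struct_motif_freq=1.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def small_model_config(seed=5, **kw):
    defaults = dict(
        input_length=40, batch_size=50, max_epochs=10, patience=3, seed=seed,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def trained_small():
    """One trained model on a small separable dataset, shared across tests."""
    ds = generate(small_sim())
    results = BindingSiteModel(ds, small_model_config()).fit()
    return ds, results
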