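import numpy as np
import pytest

import groupecg as g


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_model_config(lead_names=g.STANDARD_LEADS, seed=0, **overrides):
    """A desk-scale model: short window, narrow channels, small hidden size."""
    defaults = dict(
        lead_names=tuple(lead_names),
        l_win=128,
        window_policy="decimate",
        encoder=g.ResGCNNConfig(base_channels=4, stem_kernel=5),
        recurrent=g.RecurrentConfig(hidden_size=8),
        batch_size=16,
        epochs=2,
        seed=seed,
    )
    defaults.update(overrides)
    return g.ModelConfig(**defaults)


@pytest.fixture
def tiny_config():
    return tiny_model_config()


@pytest.fixture(scope="session")
def small_dataset():
    """30 mixed-class records at the clinical sampling rate."""
    records, manifest = g.generate_dataset(30, seed=11)
    return records, manifest
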