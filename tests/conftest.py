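import numpy as np
import pytest

import pssmrnn as pr


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_profile(rng, length=None, sequence_id="p"):
    """A random but structurally valid PSSM profile."""
    n = int(rng.integers(1, 40)) if length is None else length
    residues = "".join(rng.choice(list(pr.AMINO_ACIDS), size=n))
    scores = rng.integers(-10, 11, size=(n, 20))
    return pr.PSSMProfile(sequence_id, residues, scores)


@pytest.fixture
def small_order_dataset():
    """Order-mode dataset small enough for fast unit tests."""
    cfg = pr.SyntheticConfig(
        n_positive=30, n_negative=60, length_range=(45, 90),
        signal_mode="order", motif_length=10, effect_size=4.0, seed=11,
    )
    return pr.generate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_order_model():
    """One small CNN-GRU trained on order-mode data, shared by tests that
    need a model whose predictions actually depend on row order."""
    cfg = pr.SyntheticConfig(
        n_positive=40, n_negative=80, length_range=(90, 180),
        signal_mode="order", effect_size=4.0, seed=5,
    )
    dataset = pr.generate_dataset(cfg)
    model, history = pr.train(
        dataset, pr.desk_model_config(), pr.desk_train_config(epochs=5, seed=5)
    )
    return model, dataset, history
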