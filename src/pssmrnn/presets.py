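"""Ready-made configurations.

``paper_model_config`` / ``paper_train_config`` carry the tuned
full-scale settings (256 GRU units, 512-node FC layer, lr 1e-4, 30
epochs).  ``desk_model_config`` / ``desk_train_config`` are a reduced
profile for single-CPU experiments on synthetic data: a narrower network
trains in minutes and, on the synthetic signals this package generates,
separates the classes just as cleanly.  The methods note discusses the
choice.
"""

from __future__ import annotations

from .model import ModelConfig
from .training import TrainConfig

__all__ = [
    "paper_model_config", "paper_train_config",
    "desk_model_config", "desk_train_config",
]


def paper_model_config(**overrides) -> ModelConfig:
    return ModelConfig(**overrides)


def paper_train_config(**overrides) -> TrainConfig:
    return TrainConfig(**overrides)


def desk_model_config(**overrides) -> ModelConfig:
    defaults = dict(
        conv_filters=(16, 32),
        conv_kernel=7,
        gru_hidden=32,
        fc_size=64,
        dropout_rate=0.2,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def desk_train_config(**overrides) -> TrainConfig:
    defaults = dict(
        learning_rate=1e-3,
        epochs=10,
        batch_size=16,
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)
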