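"""The order-preserving CNN-GRU classifier.

A PSSM profile (N positions x 20 amino-acid channels) is passed through
two stages of 1-D convolution + ReLU + pooling along the position axis,
each pooling with kernel = stride = 3, so a length-N profile becomes a
feature sequence of length floor(floor(N/3)/3) — the 9-fold reduction
the architecture is designed around.  A gated recurrent unit then reads
the feature sequence; its final hidden state goes through a fully
connected layer and a single sigmoid output giving the probability that
the profile belongs to the positive (adaptor) class.

Unlike the 400-dimensional summed-PSSM representation, every stage here
respects the ordering of the profile rows, which is the point of the
architecture: the signal distinguishing the classes may live purely in
*where* conserved positions sit along the sequence.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np

from . import nn
from .pssm_io import PSSMProfile

__all__ = [
    "ModelConfig", "GRUParams", "CNNGRUClassifier",
    "gru_cell_step", "cnn_front_end", "model_forward",
    "front_end_length", "save_checkpoint", "load_checkpoint",
]

MIN_LENGTH = 9  # shortest profile producing one front-end step


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults follow the tuned architecture: 256 GRU hidden units and a
    512-node fully connected layer; the convolutional front-end (filter
    counts, kernel width) and dropout rate are this package's choices,
    documented in the methods note.
    """

    conv_filters: tuple[int, int] = (64, 128)
    conv_kernel: int = 7
    pool: str = "max"          # "max" or "avg" — both pooling readings exist
    pool_kernel: int = 3
    pool_stride: int = 3
    gru_hidden: int = 256
    gru_layers: int = 1
    fc_size: int = 512
    dropout_rate: float = 0.5
    input_channels: int = 20
    squash_input: bool = False  # optional elementwise 1/(1+e^-x) on raw scores
    pad_short: bool = False     # zero-pad profiles shorter than 9 instead of rejecting

    def __post_init__(self) -> None:
        if self.pool_kernel != self.pool_stride:
            raise ValueError("pooling is non-overlapping: kernel must equal stride")
        if self.pool_stride ** 2 != 9:
            raise ValueError("two equal pooling stages must realise the 9-fold reduction")
        if self.gru_hidden < 1 or self.fc_size < 1 or self.gru_layers < 1:
            raise ValueError("gru_hidden, gru_layers and fc_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.conv_filters) != 2:
            raise ValueError("exactly two convolution stages are expected")


@dataclasses.dataclass
class GRUParams:
    """The twelve weight/bias arrays of one GRU layer."""

    W_iz: np.ndarray
    W_ir: np.ndarray
    W_in: np.ndarray
    W_hz: np.ndarray
    W_hr: np.ndarray
    W_hn: np.ndarray
    b_iz: np.ndarray
    b_ir: np.ndarray
    b_in: np.ndarray
    b_hz: np.ndarray
    b_hr: np.ndarray
    b_hn: np.ndarray
    hidden_size: int

    def __post_init__(self) -> None:
        h = self.hidden_size
        for name in ("W_hz", "W_hr", "W_hn"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must be ({h}, {h})")
        for name in ("b_iz", "b_ir", "b_in", "b_hz", "b_hr", "b_hn"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have length {h}")


def gru_cell_step(x_t: np.ndarray, h_prev: np.ndarray, params: GRUParams) -> np.ndarray:
    """One GRU time step.

    Computes the update gate z_t, reset gate r_t, candidate memory n_t
    and new hidden state h_t = (1 - z_t) * n_t + z_t * h_{t-1}, with
    sigmoid gates and a tanh candidate whose recurrent term is gated
    elementwise by r_t.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if h_prev.shape != (params.hidden_size,):
        raise ValueError(f"h_prev must have length {params.hidden_size}")
    if x_t.shape[0] != params.W_iz.shape[1]:
        raise ValueError(
            f"x_t has length {x_t.shape[0]}, expected {params.W_iz.shape[1]}"
        )
    z = nn.sigmoid(params.W_iz @ x_t + params.b_iz + params.W_hz @ h_prev + params.b_hz)
    r = nn.sigmoid(params.W_ir @ x_t + params.b_ir + params.W_hr @ h_prev + params.b_hr)
    n = np.tanh(params.W_in @ x_t + params.b_in + r * (params.W_hn @ h_prev + params.b_hn))
    return (1.0 - z) * n + z * h_prev


def front_end_length(n: int, pool_stride: int = 3) -> int:
    """Output length of the two-stage front-end for an N-position input."""
    return (n // pool_stride) // pool_stride


class CNNGRUClassifier:
    """The full architecture with trainable parameters.

    Parameters are initialised from a seeded generator (Glorot for the
    convolution and dense layers, uniform +/- 1/sqrt(H) for the GRU), so
    two models built with the same config and seed are identical.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c1, c2 = config.conv_filters
        self.conv1 = nn.Conv1d(config.input_channels, c1, config.conv_kernel, rng, prefix="conv1")
        self.pool1 = nn.Pool1d(config.pool_kernel, config.pool)
        self.conv2 = nn.Conv1d(c1, c2, config.conv_kernel, rng, prefix="conv2")
        self.pool2 = nn.Pool1d(config.pool_kernel, config.pool)
        self.grus = [
            nn.GRULayer(c2 if i == 0 else config.gru_hidden, config.gru_hidden,
                        rng, prefix=f"gru{i}")
            for i in range(config.gru_layers)
        ]
        self.fc = nn.Dense(config.gru_hidden, config.fc_size, rng, relu=True, prefix="fc")
        self.dropout = nn.Dropout(config.dropout_rate)
        self.out = nn.Dense(config.fc_size, 1, rng, relu=False, prefix="out")

    # -- parameters ---------------------------------------------------------

    @property
    def params(self) -> list[nn.Param]:
        layers = [self.conv1, self.conv2, *self.grus, self.fc, self.out]
        return [p for layer in layers for p in layer.params]

    def gru_params(self, layer: int = 0) -> GRUParams:
        """Expose one GRU layer's weights as a :class:`GRUParams` view."""
        g = self.grus[layer]
        return GRUParams(
            W_iz=g.Wi["z"].v, W_ir=g.Wi["r"].v, W_in=g.Wi["n"].v,
            W_hz=g.Wh["z"].v, W_hr=g.Wh["r"].v, W_hn=g.Wh["n"].v,
            b_iz=g.bi["z"].v, b_ir=g.bi["r"].v, b_in=g.bi["n"].v,
            b_hz=g.bh["z"].v, b_hr=g.bh["r"].v, b_hn=g.bh["n"].v,
            hidden_size=g.hidden_size,
        )

    # -- forward / backward -------------------------------------------------

    def _prepare(self, scores: np.ndarray) -> np.ndarray:
        x = np.asarray(scores, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.input_channels:
            raise ValueError(f"input must be (N, {self.config.input_channels})")
        if x.shape[0] < MIN_LENGTH:
            if not self.config.pad_short:
                raise ValueError(
                    f"profile length {x.shape[0]} < {MIN_LENGTH}; the front-end "
                    "would emit no steps (set pad_short=True to zero-pad)"
                )
            pad = np.zeros((MIN_LENGTH - x.shape[0], x.shape[1]))
            x = np.vstack([x, pad])
        if self.config.squash_input:
            x = nn.sigmoid(x)
        return x

    def front_end(self, scores: np.ndarray) -> np.ndarray:
        """Convolutional feature extraction: (N, 20) -> (floor(floor(N/3)/3), C)."""
        x = self._prepare(scores)
        x = self.pool1.forward(self.conv1.forward(x))
        return self.pool2.forward(self.conv2.forward(x))

    def forward_logit(self, scores: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None) -> float:
        xs = self.front_end(scores)
        for gru in self.grus:
            xs = gru.forward(xs)
        h_last = xs[-1]
        f = self.fc.forward(h_last)
        f = self.dropout.forward(f, train, rng)
        return float(self.out.forward(f)[0])

    def backward(self, dlogit: float) -> None:
        """Accumulate parameter gradients for the last forward pass."""
        g = self.out.backward(np.array([dlogit]))
        g = self.dropout.backward(g)
        g = self.fc.backward(g)
        t_steps = len(self.grus[-1]._cache)
        ghs = np.zeros((t_steps, self.config.gru_hidden))
        ghs[-1] = g
        for gru in reversed(self.grus):
            ghs = gru.backward(ghs)
        g = self.pool2.backward(ghs)
        g = self.conv2.backward(g)
        g = self.pool1.backward(g)
        self.conv1.backward(g)

    def predict_proba(self, scores: np.ndarray) -> float:
        """Probability that the profile is positive; deterministic
        (dropout disabled)."""
        return float(nn.sigmoid(np.array([self.forward_logit(scores, train=False)]))[0])

    def predict_dataset(self, profiles) -> np.ndarray:
        return np.array([self.predict_proba(p.scores) for p in profiles])


def cnn_front_end(profile: PSSMProfile | np.ndarray, model: CNNGRUClassifier) -> np.ndarray:
    """Feature sequence emitted by the model's convolutional front-end."""
    scores = profile.scores if isinstance(profile, PSSMProfile) else profile
    return model.front_end(scores)


def model_forward(profile: PSSMProfile | np.ndarray, model: CNNGRUClassifier) -> float:
    """Predicted probability for one profile (inference mode)."""
    scores = profile.scores if isinstance(profile, PSSMProfile) else profile
    return model.predict_proba(scores)


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz holding every parameter plus the JSON config.
# ---------------------------------------------------------------------------

def save_checkpoint(model: CNNGRUClassifier, path: str | os.PathLike) -> None:
    arrays = {p.name: p.v for p in model.params}
    arrays["__config__"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_checkpoint(path: str | os.PathLike) -> CNNGRUClassifier:
    with np.load(Path(path)) as data:
        raw = json.loads(bytes(data["__config__"].tobytes()).decode())
        raw["conv_filters"] = tuple(raw["conv_filters"])
        model = CNNGRUClassifier(ModelConfig(**raw), seed=0)
        for p in model.params:
            p.v[...] = data[p.name]
    return model
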