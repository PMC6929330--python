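"""Minimal numpy neural-network layers with hand-written gradients.

Layers operate on one variable-length sample at a time (position-major
arrays); minibatch gradients are formed by accumulation, which is
mathematically identical to padded batch processing of the mean loss.
Every layer caches what its backward pass needs during ``forward`` and
releases gradients into :class:`Param` objects consumed by :class:`Adam`.

All randomness flows through explicitly passed ``numpy.random.Generator``
instances, so training is bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Conv1d", "Pool1d", "GRULayer", "Dense", "Dropout",
    "Adam", "sigmoid", "glorot",
]


def sigmoid(x):
    # numerically stable logistic
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("name", "v", "g")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g.fill(0.0)


class Conv1d:
    """1-D convolution along the position axis, zero-padded to preserve
    length (odd kernel), followed optionally by ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True, prefix: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd to preserve length")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.relu = relu
        fan_in = in_channels * kernel
        self.W = Param(f"{prefix}.W", glorot(rng, (out_channels, fan_in), fan_in, out_channels))
        self.b = Param(f"{prefix}.b", np.zeros(out_channels))
        self._cols = None
        self._mask = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C_in) -> (N, C_out)
        n = x.shape[0]
        pad = self.kernel // 2
        xp = np.zeros((n + 2 * pad, self.in_channels))
        xp[pad:pad + n] = x
        windows = sliding_window_view(xp, self.kernel, axis=0)  # (N, C_in, K)
        self._cols = windows.reshape(n, -1)
        y = self._cols @ self.W.v.T + self.b.v
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.relu:
            gy = np.where(self._mask, gy, 0.0)
        n = gy.shape[0]
        pad = self.kernel // 2
        self.W.g += gy.T @ self._cols
        self.b.g += gy.sum(axis=0)
        gcols = (gy @ self.W.v).reshape(n, self.in_channels, self.kernel)
        gxp = np.zeros((n + 2 * pad, self.in_channels))
        for k in range(self.kernel):
            gxp[k:k + n] += gcols[:, :, k]
        return gxp[pad:pad + n]


class Pool1d:
    """Non-overlapping pooling (kernel == stride); trailing positions
    that do not fill a window are dropped (floor semantics)."""

    def __init__(self, kernel: int, mode: str = "max"):
        if mode not in ("max", "avg"):
            raise ValueError("pool mode must be 'max' or 'avg'")
        self.kernel = kernel
        self.mode = mode
        self._n = 0
        self._argmax = None
        self._channels = 0

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape
        t = n // self.kernel
        if t == 0:
            raise ValueError(f"sequence of length {n} too short for pooling kernel {self.kernel}")
        self._n, self._channels = n, c
        xt = x[: t * self.kernel].reshape(t, self.kernel, c)
        if self.mode == "max":
            self._argmax = xt.argmax(axis=1)
            return xt.max(axis=1)
        return xt.mean(axis=1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        t = gy.shape[0]
        gxt = np.zeros((t, self.kernel, self._channels))
        if self.mode == "max":
            np.put_along_axis(gxt, self._argmax[:, None, :], gy[:, None, :], axis=1)
        else:
            gxt += gy[:, None, :] / self.kernel
        gx = np.zeros((self._n, self._channels))
        gx[: t * self.kernel] = gxt.reshape(t * self.kernel, self._channels)
        return gx


class GRULayer:
    """A gated recurrent unit layer unrolled over the sequence.

    Per step, with input x_t and previous hidden state h_{t-1}:

        z_t = sigmoid(W_iz x_t + b_iz + W_hz h_{t-1} + b_hz)   (update gate)
        r_t = sigmoid(W_ir x_t + b_ir + W_hr h_{t-1} + b_hr)   (reset gate)
        n_t = tanh(W_in x_t + b_in + r_t * (W_hn h_{t-1} + b_hn))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}

    The update gate decides how much of the previous state to carry, the
    reset gate how much of it enters the candidate memory n_t.
    """

    GATES = ("z", "r", "n")

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, prefix: str = "gru"):
        self.input_size = input_size
        self.hidden_size = hidden_size
        k = 1.0 / np.sqrt(hidden_size)
        def u(shape):
            return rng.uniform(-k, k, size=shape)
        self.Wi = {g: Param(f"{prefix}.W_i{g}", u((hidden_size, input_size))) for g in self.GATES}
        self.Wh = {g: Param(f"{prefix}.W_h{g}", u((hidden_size, hidden_size))) for g in self.GATES}
        self.bi = {g: Param(f"{prefix}.b_i{g}", u(hidden_size)) for g in self.GATES}
        self.bh = {g: Param(f"{prefix}.b_h{g}", u(hidden_size)) for g in self.GATES}
        self._cache = None

    @property
    def params(self) -> list[Param]:
        out = []
        for g in self.GATES:
            out += [self.Wi[g], self.Wh[g], self.bi[g], self.bh[g]]
        return out

    def step(self, x_t: np.ndarray, h_prev: np.ndarray):
        """One GRU step; returns (h_t, stash) with intermediates for BPTT."""
        z = sigmoid(self.Wi["z"].v @ x_t + self.bi["z"].v + self.Wh["z"].v @ h_prev + self.bh["z"].v)
        r = sigmoid(self.Wi["r"].v @ x_t + self.bi["r"].v + self.Wh["r"].v @ h_prev + self.bh["r"].v)
        c = self.Wh["n"].v @ h_prev + self.bh["n"].v
        n = np.tanh(self.Wi["n"].v @ x_t + self.bi["n"].v + r * c)
        h = (1.0 - z) * n + z * h_prev
        return h, (x_t, h_prev, z, r, c, n)

    def forward(self, xs: np.ndarray, h0: np.ndarray | None = None) -> np.ndarray:
        # xs: (T, input_size) -> hidden states (T, hidden_size)
        t_steps = xs.shape[0]
        h = np.zeros(self.hidden_size) if h0 is None else h0
        hs = np.empty((t_steps, self.hidden_size))
        stashes = []
        for t in range(t_steps):
            h, stash = self.step(xs[t], h)
            hs[t] = h
            stashes.append(stash)
        self._cache = stashes
        return hs

    def backward(self, ghs: np.ndarray) -> np.ndarray:
        """Backpropagate through time.

        ``ghs``: (T, hidden_size) gradients w.r.t. each hidden state
        (zeros everywhere but the last row when only h_T is consumed).
        Returns gradients w.r.t. the input sequence.
        """
        stashes = self._cache
        t_steps = ghs.shape[0]
        gxs = np.empty((t_steps, self.input_size))
        carry = np.zeros(self.hidden_size)
        for t in range(t_steps - 1, -1, -1):
            x_t, h_prev, z, r, c, n = stashes[t]
            dh = ghs[t] + carry
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z

            da_n = dn * (1.0 - n * n)
            dr = da_n * c
            dc = da_n * r
            self.Wi["n"].g += np.outer(da_n, x_t)
            self.bi["n"].g += da_n
            self.Wh["n"].g += np.outer(dc, h_prev)
            self.bh["n"].g += dc
            dx = self.Wi["n"].v.T @ da_n
            dh_prev += self.Wh["n"].v.T @ dc

            for gate, dgate in (("z", dz), ("r", dr)):
                da = dgate * (z if gate == "z" else r) * (1.0 - (z if gate == "z" else r))
                self.Wi[gate].g += np.outer(da, x_t)
                self.bi[gate].g += da
                self.Wh[gate].g += np.outer(da, h_prev)
                self.bh[gate].g += da
                dx += self.Wi[gate].v.T @ da
                dh_prev += self.Wh[gate].v.T @ da

            gxs[t] = dx
            carry = dh_prev
        return gxs


class Dense:
    """Affine map on a vector, with optional ReLU."""

    def __init__(self, in_size: int, out_size: int, rng: np.random.Generator,
                 relu: bool = False, prefix: str = "fc"):
        self.W = Param(f"{prefix}.W", glorot(rng, (out_size, in_size), in_size, out_size))
        self.b = Param(f"{prefix}.b", np.zeros(out_size))
        self.relu = relu
        self._x = None
        self._mask = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = self.W.v @ x + self.b.v
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.relu:
            gy = np.where(self._mask, gy, 0.0)
        self.W.g += np.outer(gy, self._x)
        self.b.g += gy
        return self.W.v.T @ gy


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        return gy * self._mask


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.vv = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.vv):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.g
            v *= self.beta2
            v += (1.0 - self.beta2) * p.g * p.g
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
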