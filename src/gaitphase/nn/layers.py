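"""Neural-network layers built on the autodiff tape."""

from __future__ import annotations

import numpy as np

from gaitphase.nn.autodiff import Tensor
from gaitphase.nn.functional import positional_encoding


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class; children are discovered from instance attributes."""

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        params: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.trainable:
                params.append((full, value))
            elif isinstance(value, Module):
                params.extend(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.extend(item.named_parameters(f"{full}.{i}."))
        return params

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def _param(data: np.ndarray) -> Tensor:
    return Tensor(data, trainable=True)


_ACT = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
    None: lambda t: t,
    "linear": lambda t: t,
}


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.weight = _param(glorot(rng, d_in, d_out, (d_in, d_out)))
        self.bias = _param(np.zeros(d_out))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        return _ACT[self.activation](x @ self.weight + self.bias)


class Conv1D(Module):
    """Valid 1-D convolution over (batch, time, channels)."""

    def __init__(self, c_in: int, n_filters: int, kernel_size: int,
                 rng: np.random.Generator, activation: str | None = "relu"):
        fan_in = kernel_size * c_in
        self.weight = _param(glorot(rng, fan_in, n_filters,
                                    (kernel_size, c_in, n_filters)))
        self.bias = _param(np.zeros(n_filters))
        self.kernel_size = kernel_size
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel_size
        t_out = x.shape[1] - k + 1
        if t_out < 1:
            raise ValueError(f"sequence length {x.shape[1]} < kernel size {k}")
        out = None
        for i in range(k):
            term = x[:, i : i + t_out, :] @ self.weight[i]
            out = term if out is None else out + term
        return _ACT[self.activation](out + self.bias)


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not train or self.rate == 0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = _param(np.ones(d))
        self.bias = _param(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gain + self.bias


class LSTM(Module):
    """Single LSTM layer over (batch, time, features); returns the full
    hidden sequence as a list of (batch, units) tensors."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.wx = _param(glorot(rng, d_in, units, (d_in, 4 * units)))
        self.wh = _param(glorot(rng, units, units, (units, 4 * units)))
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 1.0  # forget-gate bias
        self.bias = _param(bias)
        self.units = units

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        u = self.units
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, u)))
        c = Tensor(np.zeros((batch, u)))
        outs = []
        for x_t in xs:
            gates = x_t @ self.wx + h @ self.wh + self.bias
            i = gates[:, 0:u].sigmoid()
            f = gates[:, u : 2 * u].sigmoid()
            g = gates[:, 2 * u : 3 * u].tanh()
            o = gates[:, 3 * u : 4 * u].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs


class GRU(Module):
    """Single GRU layer; returns the final hidden state."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.wx = _param(glorot(rng, d_in, units, (d_in, 3 * units)))
        self.wh = _param(glorot(rng, units, units, (units, 3 * units)))
        self.bx = _param(np.zeros(3 * units))
        self.bh = _param(np.zeros(3 * units))
        self.units = units

    def __call__(self, xs: list[Tensor]) -> Tensor:
        u = self.units
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, u)))
        for x_t in xs:
            gx = x_t @ self.wx + self.bx
            gh = h @ self.wh + self.bh
            r = (gx[:, 0:u] + gh[:, 0:u]).sigmoid()
            z = (gx[:, u : 2 * u] + gh[:, u : 2 * u]).sigmoid()
            n = (gx[:, 2 * u : 3 * u] + r * gh[:, 2 * u : 3 * u]).tanh()
            h = (1.0 - z) * n + z * h
        return h


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)
        self.n_heads = n_heads
        self.d_k = d_model // n_heads

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        q = self._split(self.wq(x))
        k = self._split(self.wk(x))
        v = self._split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        attended = scores.softmax(axis=-1) @ v
        merged = attended.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(merged)


class EncoderBlock(Module):
    """Post-norm Transformer encoder block: MHA and position-wise FFN,
    each wrapped in residual + layer normalization."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 dropout: float, rng: np.random.Generator):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Dense(d_model, d_ff, rng, activation="relu")
        self.ff2 = Dense(d_ff, d_model, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x), train, rng))
        return self.norm2(x + self.drop(self.ff2(self.ff1(x)), train, rng))


class PositionalEncoding(Module):
    def __init__(self, max_len: int, d_model: int):
        self.pe = positional_encoding(max_len, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        t = x.shape[1]
        return x + Tensor(self.pe[:t])
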