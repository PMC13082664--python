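"""The three gait-phase classifier architectures.

Defaults follow the tuned hyperparameters adopted for the comparison:
CNN (32 filters, kernel 1, two conv layers), hybrid LSTM(100)->LSTM(100)
->GRU(256)->Dense(128), Transformer encoder (d_model 256, 1 head, 2
layers, d_ff 512).  All models map a batch of (w, 12) windows to 4-class
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitphase.nn.autodiff import Tensor, cross_entropy_logits
from gaitphase.nn.layers import (
    GRU,
    LSTM,
    Conv1D,
    Dense,
    Dropout,
    EncoderBlock,
    Module,
    PositionalEncoding,
)

N_CLASSES = 4


class ConfigError(ValueError):
    """A model config violates one of its invariants."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


@dataclass(frozen=True)
class CnnConfig:
    n_filters: int = 32
    kernel_size: int = 1
    n_conv_layers: int = 2
    pool_size: int = 2
    dense_units: int = 64
    dropout: float = 0.3
    n_classes: int = N_CLASSES

    def validate(self) -> None:
        _check(self.kernel_size >= 1, "kernel_size must be >= 1")
        _check(0 <= self.dropout < 1, "dropout must be in [0, 1)")
        _check(self.n_filters >= 1, "n_filters must be >= 1")
        _check(self.n_conv_layers >= 1, "n_conv_layers must be >= 1")
        _check(self.pool_size >= 1, "pool_size must be >= 1")


@dataclass(frozen=True)
class HybridConfig:
    lstm_units_1: int = 100
    lstm_units_2: int = 100
    gru_units: int = 256
    dense_units: int = 128
    dropout: float = 0.3
    n_classes: int = N_CLASSES

    def validate(self) -> None:
        for name in ("lstm_units_1", "lstm_units_2", "gru_units", "dense_units"):
            _check(getattr(self, name) >= 1, f"{name} must be >= 1")
        _check(0 <= self.dropout < 1, "dropout must be in [0, 1)")


@dataclass(frozen=True)
class TransformerConfig:
    d_model: int = 256
    n_heads: int = 1
    n_layers: int = 2
    d_ff: int = 512
    dropout: float = 0.4
    pooling: str = "mean"
    n_classes: int = N_CLASSES

    def validate(self) -> None:
        _check(self.d_model % self.n_heads == 0,
               "d_model must be divisible by n_heads")
        _check(self.d_model % 2 == 0, "d_model must be even")
        _check(self.pooling in ("mean", "last"), "pooling must be mean or last")
        _check(0 <= self.dropout < 1, "dropout must be in [0, 1)")


class SequenceClassifier(Module):
    """Common interface: logits, probabilities and the training loss."""

    n_channels = 12

    def forward(self, x: Tensor, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def loss(self, x: np.ndarray, y: np.ndarray, train: bool = True,
             rng: np.random.Generator | None = None) -> Tensor:
        return cross_entropy_logits(self.forward(Tensor(x), train, rng), y)

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Deterministic inference (dropout off); rows sum to 1."""
        chunks = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(Tensor(x[start : start + batch_size]))
            chunks.append(logits.softmax(axis=1).data)
        return np.concatenate(chunks)

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)


class CnnClassifier(SequenceClassifier):
    def __init__(self, cfg: CnnConfig, w: int = 20, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.convs = []
        c_in, t = self.n_channels, w
        for _ in range(cfg.n_conv_layers):
            self.convs.append(Conv1D(c_in, cfg.n_filters, cfg.kernel_size, rng))
            t = t - cfg.kernel_size + 1
            if t >= cfg.pool_size:
                t //= cfg.pool_size
            c_in = cfg.n_filters
        _check(t >= 1, f"window of {w} steps is too short for this config")
        self.flat_dim = t * cfg.n_filters
        self.dense = Dense(self.flat_dim, cfg.dense_units, rng, activation="relu")
        self.drop = Dropout(cfg.dropout)
        self.head = Dense(cfg.dense_units, cfg.n_classes, rng)

    def forward(self, x, train=False, rng=None):
        for conv in self.convs:
            x = conv(x)
            if x.shape[1] >= self.cfg.pool_size:
                x = x.maxpool1d(self.cfg.pool_size, axis=1)
        x = x.reshape(x.shape[0], self.flat_dim)
        x = self.drop(self.dense(x), train, rng)
        return self.head(x)


class HybridClassifier(SequenceClassifier):
    """LSTM (sequence) -> LSTM (sequence) -> GRU (last state) -> dense."""

    def __init__(self, cfg: HybridConfig, w: int = 20, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.lstm1 = LSTM(self.n_channels, cfg.lstm_units_1, rng)
        self.lstm2 = LSTM(cfg.lstm_units_1, cfg.lstm_units_2, rng)
        self.gru = GRU(cfg.lstm_units_2, cfg.gru_units, rng)
        self.dense = Dense(cfg.gru_units, cfg.dense_units, rng, activation="relu")
        self.drop = Dropout(cfg.dropout)
        self.head = Dense(cfg.dense_units, cfg.n_classes, rng)

    def forward(self, x, train=False, rng=None):
        steps = [x[:, t, :] for t in range(x.shape[1])]
        h = self.gru(self.lstm2(self.lstm1(steps)))
        h = self.drop(self.dense(h), train, rng)
        return self.head(h)


class TransformerClassifier(SequenceClassifier):
    """Encoder-only Transformer: input projection to d_model, sinusoidal
    positional encoding, stacked encoder blocks, temporal pooling, dense
    classification head."""

    def __init__(self, cfg: TransformerConfig, w: int = 20, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.proj = Dense(self.n_channels, cfg.d_model, rng)
        self.pos = PositionalEncoding(max(w, 512), cfg.d_model)
        self.blocks = [
            EncoderBlock(cfg.d_model, cfg.n_heads, cfg.d_ff, cfg.dropout, rng)
            for _ in range(cfg.n_layers)
        ]
        self.drop = Dropout(cfg.dropout)
        self.head = Dense(cfg.d_model, cfg.n_classes, rng)

    def forward(self, x, train=False, rng=None):
        x = self.drop(self.pos(self.proj(x)), train, rng)
        for block in self.blocks:
            x = block(x, train, rng)
        pooled = x.mean(axis=1) if self.cfg.pooling == "mean" else x[:, -1, :]
        return self.head(pooled)


def build_cnn(cfg: CnnConfig | None = None, w: int = 20, seed: int = 0) -> CnnClassifier:
    return CnnClassifier(cfg or CnnConfig(), w=w, seed=seed)


def build_hybrid(cfg: HybridConfig | None = None, w: int = 20, seed: int = 0) -> HybridClassifier:
    return HybridClassifier(cfg or HybridConfig(), w=w, seed=seed)


def build_transformer(cfg: TransformerConfig | None = None, w: int = 20,
                      seed: int = 0) -> TransformerClassifier:
    return TransformerClassifier(cfg or TransformerConfig(), w=w, seed=seed)


_BUILDERS = {"cnn": (build_cnn, CnnConfig),
             "hybrid": (build_hybrid, HybridConfig),
             "transformer": (build_transformer, TransformerConfig)}


def build_model(name: str, config_kwargs: dict | None = None, w: int = 20,
                seed: int = 0) -> SequenceClassifier:
    """Build a model by name ('cnn', 'hybrid', 'transformer')."""
    if name not in _BUILDERS:
        raise ConfigError(f"unknown model {name!r}; choose from {sorted(_BUILDERS)}")
    builder, cfg_cls = _BUILDERS[name]
    return builder(cfg_cls(**(config_kwargs or {})), w=w, seed=seed)
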