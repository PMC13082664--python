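"""Model training and prediction.

Fixed-epoch training (no early stopping) with cross-entropy loss;
per-epoch train and validation losses are recorded.  With a fixed seed
and single-threaded BLAS the loss trajectory is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitphase.datasets import WindowSet
from gaitphase.nn.architectures import SequenceClassifier
from gaitphase.nn.autodiff import cross_entropy_logits, Tensor
from gaitphase.nn.optim import Adam, AdamW


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 80
    batch_size: int = 1024
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer not in ("adam", "adamw"):
            raise ValueError("optimizer must be 'adam' or 'adamw'")


#: Per-model training defaults matching the adopted best hyperparameters.
DEFAULT_TRAIN_CONFIGS = {
    "cnn": TrainConfig(epochs=80, batch_size=1024, optimizer="adam",
                       learning_rate=0.0001),
    "hybrid": TrainConfig(epochs=80, batch_size=1024, optimizer="adam",
                          learning_rate=0.0022),
    "transformer": TrainConfig(epochs=80, batch_size=128, optimizer="adamw",
                               learning_rate=0.0000292),
}


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def _dataset_loss(model: SequenceClassifier, ws: WindowSet,
                  batch_size: int = 4096) -> float:
    total, n = 0.0, len(ws)
    for start in range(0, n, batch_size):
        x = ws.inputs[start : start + batch_size]
        y = ws.targets[start : start + batch_size]
        loss = cross_entropy_logits(model.forward(Tensor(x)), y)
        total += float(loss.data) * len(y)
    return total / n


def train_model(
    model: SequenceClassifier,
    train_ws: WindowSet,
    val_ws: WindowSet | None,
    cfg: TrainConfig,
) -> TrainHistory:
    """Train in place; returns per-epoch train/val loss history."""
    if len(train_ws) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt_cls = Adam if cfg.optimizer == "adam" else AdamW
    opt = opt_cls(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    n = len(train_ws)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss = model.loss(train_ws.inputs[idx], train_ws.targets[idx],
                              train=True, rng=rng)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.train_loss.append(epoch_loss / n)
        if val_ws is not None and len(val_ws):
            history.val_loss.append(_dataset_loss(model, val_ws))
    return history


def predict(model: SequenceClassifier, ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """(predicted labels, class probabilities); deterministic (dropout off)."""
    proba = model.predict_proba(ws.inputs)
    return proba.argmax(axis=1), proba
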