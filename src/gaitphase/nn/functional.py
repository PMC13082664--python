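"""Plain-NumPy reference kernels for the model building blocks.

These are the mathematical primitives of the classifiers, written
directly from their defining formulas.  The autodiff layers are tested
against them.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def conv1d_forward(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Valid (no-padding) 1-D convolution over a ``(w, C)`` sequence.

    ``z[t, f] = act( sum_i <weights[i, :, f], x[t+i, :]> + bias[f] )``
    with ``weights`` of shape ``(k, C, F)``; output is ``(w-k+1, F)``.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if x.ndim != 2 or weights.ndim != 3:
        raise ValueError("x must be (w, C) and weights (k, C, F)")
    w, c = x.shape
    k, c_w, f = weights.shape
    if c != c_w:
        raise ValueError(f"channel mismatch: x has {c}, weights expect {c_w}")
    if k > w:
        raise ValueError(f"kernel size {k} exceeds sequence length {w}")
    if bias.shape != (f,):
        raise ValueError(f"bias must have shape ({f},)")
    out = np.zeros((w - k + 1, f))
    for i in range(k):
        out += x[i : i + w - k + 1, :] @ weights[i]
    out += bias
    return activation(out) if activation is not None else out


def positional_encoding(n_positions: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/d_model))`` and
    ``PE[pos, 2i+1] = cos(pos / 10000^(2i/d_model))``.
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.zeros((n_positions, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def scaled_dot_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, d_k: int | None = None
) -> np.ndarray:
    """``softmax(Q K^T / sqrt(d_k)) V`` with row-wise softmax."""
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("Q and K feature dimensions differ")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V sequence lengths differ")
    if d_k is None:
        d_k = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=-1, keepdims=True)
    return weights @ v
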