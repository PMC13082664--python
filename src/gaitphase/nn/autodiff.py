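"""Tape-based reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the sequence classifiers in this package:
broadcast-aware elementwise ops, (batched) matmul, slicing/reshape,
softmax, max-pooling and a fused softmax cross-entropy loss.  Everything
is float64 and single-threaded-deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cross_entropy_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "trainable")

    def __init__(self, data, parents=(), backward=None, trainable=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward
        self.trainable = trainable

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- elementwise -----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, (self,), bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, (self,), bw)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, (self,), bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            self._accum(g * mask)

        return Tensor(out_data, (self,), bw)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor(out_data, (self,), bw)

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        inverse = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inverse))

        return Tensor(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key) -> "Tensor":
        keys = key if isinstance(key, tuple) else (key,)
        plain = all(isinstance(k, (int, np.integer, slice)) for k in keys)

        def bw(g):
            full = np.zeros_like(self.data)
            if plain:  # slices/ints never alias; fast path
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accum(full)

        return Tensor(self.data[key], (self,), bw)

    # -- linear algebra --------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            if b.ndim >= 2:
                ga = g @ np.swapaxes(b, -1, -2)
            else:  # vector rhs
                ga = np.expand_dims(g, -1) * b
            if a.ndim >= 2:
                gb = np.swapaxes(a, -1, -2) @ g
            else:
                gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor(out_data, (self, other), bw)

    __matmul__ = matmul

    # -- neural-net specifics -------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor(out_data, (self,), bw)

    def maxpool1d(self, size: int, axis: int = 1) -> "Tensor":
        """Non-overlapping max pooling along ``axis`` (truncates remainder)."""
        x = np.moveaxis(self.data, axis, -1)
        length = x.shape[-1] - x.shape[-1] % size
        blocks = x[..., :length].reshape(*x.shape[:-1], length // size, size)
        arg = blocks.argmax(axis=-1)
        out = np.moveaxis(blocks.max(axis=-1), -1, axis)

        def bw(g):
            gmoved = np.moveaxis(g, axis, -1)
            gblocks = np.zeros_like(blocks)
            np.put_along_axis(
                gblocks, np.expand_dims(arg, -1), np.expand_dims(gmoved, -1), axis=-1
            )
            gx = np.zeros_like(x)
            gx[..., :length] = gblocks.reshape(*x.shape[:-1], length)
            self._accum(np.moveaxis(gx, -1, axis))

        return Tensor(out, (self,), bw)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy with integer targets (fused op)."""
    targets = np.asarray(targets)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = len(targets)
    loss = -logp[np.arange(n), targets].mean()

    def bw(g):
        probs = np.exp(logp)
        grad = probs.copy()
        grad[np.arange(n), targets] -= 1.0
        logits._accum(g * grad / n)

    return Tensor(loss, (logits,), bw)
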