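"""Adam and AdamW optimizers."""

from __future__ import annotations

import numpy as np

from gaitphase.nn.autodiff import Tensor


class Adam:
    """Adam with optional (coupled) L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _grad(self, p: Tensor) -> np.ndarray:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        return g

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = self._grad(p)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        super().__init__(params, lr, betas, eps, weight_decay=0.0)
        self.decoupled_decay = weight_decay

    def step(self) -> None:
        if self.decoupled_decay:
            for p in self.params:
                p.data -= self.lr * self.decoupled_decay * p.data
        super().step()
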