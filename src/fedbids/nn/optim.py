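"""Adaptive-moment (Adam) optimiser for the NumPy layers."""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter


class Adam:
    """Standard Adam with bias correction; steps only trainable parameters."""

    def __init__(self, model: Module, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._params: list[Parameter] = [
            p for _, p in model.named_parameters() if p.trainable]
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self._params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self._params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self._params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(np.float32)


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    pred = pred.reshape(-1)
    target = np.asarray(target, dtype=np.float32).reshape(-1)
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(np.float32)
    return loss, grad
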