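"""AdamW and a plateau learning-rate scheduler for the NumPy layers."""

from __future__ import annotations

import numpy as np

from .layers import Param


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied only to parameters flagged for decay (conv and
    linear weights), never to biases or batch-norm affine parameters.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored value stops improving."""

    def __init__(
        self,
        optimizer: AdamW,
        mode: str = "min",
        factor: float = 0.5,
        patience: int = 3,
        min_lr: float = 1e-6,
    ):
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.optimizer = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best: float | None = None
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        better = (
            self.best is None
            or (self.mode == "min" and metric < self.best - 1e-8)
            or (self.mode == "max" and metric > self.best + 1e-8)
        )
        if better:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
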