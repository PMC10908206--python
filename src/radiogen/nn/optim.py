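"""Optimizers and the plateau learning-rate schedule used by the classifiers."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, parameters, lr: float):
        # parameters: iterable of (key, layer, name) as produced by
        # Sequential.parameters(); grads are looked up live at step time.
        self.parameters = list(parameters)
        self.lr = float(lr)

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, parameters, lr: float, momentum: float = 0.0):
        super().__init__(parameters, lr)
        self.momentum = momentum
        self._vel = {key: None for key, _, _ in self.parameters}

    def step(self) -> None:
        for key, layer, name in self.parameters:
            g = layer.grads.get(name)
            if g is None:
                continue
            if self.momentum:
                v = self._vel[key]
                v = g.copy() if v is None else self.momentum * v + g
                self._vel[key] = v
                g = v
            layer.params[name] -= self.lr * g


class Adam(Optimizer):
    def __init__(self, parameters, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(parameters, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = {}
        self._v = {}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.b1 ** self._t
        b2t = 1.0 - self.b2 ** self._t
        for key, layer, name in self.parameters:
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g.astype(np.float64)
            m = self._m.get(key)
            v = self._v.get(key)
            m = (1 - self.b1) * g if m is None else self.b1 * m + (1 - self.b1) * g
            v = (1 - self.b2) * g * g if v is None else self.b2 * v + (1 - self.b2) * g * g
            self._m[key], self._v[key] = m, v
            upd = (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps))
            layer.params[name] -= upd.astype(layer.params[name].dtype)


class ReduceLROnPlateau:
    """Halve the learning rate when the tracked loss stops improving."""

    def __init__(self, optimizer: Optimizer, factor: float = 0.5,
                 patience: int = 10, min_lr: float = 1e-6, threshold: float = 1e-4):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self._best = np.inf
        self._bad = 0

    def step(self, loss: float) -> None:
        if loss < self._best * (1.0 - self.threshold):
            self._best = loss
            self._bad = 0
        else:
            self._bad += 1
            if self._bad > self.patience:
                self.optimizer.lr = max(self.min_lr, self.optimizer.lr * self.factor)
                self._bad = 0
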