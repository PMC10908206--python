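"""Loss functions returning (scalar loss, gradient w.r.t. prediction)."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def mse_loss(pred: np.ndarray, target) -> tuple[float, np.ndarray]:
    diff = pred - np.asarray(target, dtype=pred.dtype)
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 / diff.size) * diff


def l1_loss(pred: np.ndarray, target) -> tuple[float, np.ndarray]:
    diff = pred - np.asarray(target, dtype=pred.dtype)
    loss = float(np.mean(np.abs(diff)))
    return loss, np.sign(diff) / diff.size


def bce_loss(prob: np.ndarray, target) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on probabilities (post-sigmoid)."""
    t = np.asarray(target, dtype=np.float64)
    p = np.clip(prob.astype(np.float64), _EPS, 1.0 - _EPS)
    loss = float(-np.mean(t * np.log(p) + (1 - t) * np.log1p(-p)))
    grad = ((p - t) / (p * (1 - p))) / p.size
    return loss, grad.astype(prob.dtype)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Multiclass cross-entropy on raw scores; labels are integer classes."""
    z = logits.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    idx = np.arange(n)
    loss = float(-np.mean(np.log(np.clip(p[idx, labels], _EPS, None))))
    grad = p
    grad[idx, labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype)
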