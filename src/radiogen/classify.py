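"""Volume classifiers: the 3D CNN for mutation status and subtype, and
the L1-logistic multi-omic baseline.

The CNN trunk is three conv(3x3x3, stride 1, pad 1) + 2x max-pool blocks
with 32, 16 and 8 output channels, a 128-unit fully-connected layer with
dropout 0.5, and either a single sigmoid output (binary mutation status)
or 5 raw class scores (subtype, argmax prediction).  Rectified-linear
activations everywhere else.  Named epoch presets follow the per-task
budgets used for the reference experiments; short presets for phantom
scale are separate and explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import train_test_split

from . import nn
from .nn.losses import bce_loss, softmax_cross_entropy
from .volio import Volume3D

#: per-task training epoch budgets of the reference pipeline
EPOCH_PRESETS = {
    "CDH1": 1300,
    "PIK3CA": 1500,
    "TP53": 2000,
    "subtype": 2500,
    "real": 300,          # real-MRI mutation models, all three genes
}


@dataclass
class CnnConfig:
    volume_shape: tuple[int, int, int] = (32, 128, 128)
    conv_channels: tuple[int, ...] = (32, 16, 8)
    fc_hidden: int = 128
    dropout_p: float = 0.5
    n_outputs: int = 1                 # 1 = binary/sigmoid, 5 = multiclass/raw
    batch_size: int = 1
    optimizer: str = "Adam"            # Adam | SGD
    learning_rate: float = 1e-3
    lr_schedule: str = "reduce_on_plateau"
    plateau_patience: int = 10
    epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        if not self.conv_channels:
            raise ValueError("conv_channels must be nonempty")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0,1)")
        if self.n_outputs not in (1, 5):
            raise ValueError("n_outputs must be 1 (binary) or 5 (subtype)")
        if self.optimizer not in ("Adam", "SGD"):
            raise ValueError(f"unknown optimizer {self.optimizer}")
        k = len(self.conv_channels)
        bad = [s for s in self.volume_shape if s % (2 ** k) != 0]
        if bad:
            raise ValueError(
                f"volume shape {self.volume_shape} too small/odd for {k} "
                f"max-poolings; each axis must be a multiple of {2 ** k}")


def _build_cnn(config: CnnConfig) -> nn.Sequential:
    rng = np.random.default_rng(config.seed)
    layers: list = []
    in_ch = 1
    for i, ch in enumerate(config.conv_channels):
        layers += [nn.Conv3d(in_ch, ch, 3, 1, 1, rng, is_first=(i == 0)),
                   nn.ReLU(), nn.MaxPool3d()]
        in_ch = ch
    k = len(config.conv_channels)
    flat = in_ch * int(np.prod([s // 2 ** k for s in config.volume_shape]))
    layers += [nn.Flatten(), nn.Dense(flat, config.fc_hidden, rng), nn.ReLU(),
               nn.Dropout(config.dropout_p),
               nn.Dense(config.fc_hidden, config.n_outputs, rng)]
    if config.n_outputs == 1:
        layers.append(nn.Sigmoid())
    return nn.Sequential(*layers)


def build_mutation_cnn(config: CnnConfig) -> nn.Sequential:
    """Binary mutation-status classifier (sigmoid probability output)."""
    if config.n_outputs != 1:
        raise ValueError("mutation CNN requires n_outputs=1")
    return _build_cnn(config)


def build_subtype_cnn(config: CnnConfig) -> nn.Sequential:
    """5-class subtype classifier (raw scores; predict with argmax)."""
    if config.n_outputs != 5:
        raise ValueError("subtype CNN requires n_outputs=5")
    return _build_cnn(config)


def _as_batch(volumes: list[Volume3D], shape) -> np.ndarray:
    for v in volumes:
        if v.shape != tuple(shape):
            raise ValueError(f"volume shape {v.shape} != configured {tuple(shape)}")
    return np.stack([v.rescaled((0.0, 1.0)).data
                     for v in volumes])[:, None].astype(np.float32)


def train_classifier(model: nn.Sequential, volumes: list[Volume3D],
                     labels: np.ndarray, config: CnnConfig,
                     progress: bool = False) -> list[float]:
    """Mini-batch training; returns the per-epoch loss history."""
    labels = np.asarray(labels)
    if len(volumes) != len(labels):
        raise ValueError("volumes and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    if config.n_outputs == 1 and not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("binary labels must be 0/1")
    x = _as_batch(volumes, config.volume_shape)
    n = x.shape[0]

    rng = np.random.default_rng(config.seed + 100)
    model.set_rng(np.random.default_rng(config.seed + 101))
    if config.optimizer == "Adam":
        opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    else:
        opt = nn.SGD(model.parameters(), lr=config.learning_rate, momentum=0.9)
    sched = nn.ReduceLROnPlateau(opt, patience=config.plateau_patience) \
        if config.lr_schedule == "reduce_on_plateau" else None

    history = []
    bs = max(1, config.batch_size)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep, nb = 0.0, 0
        for i0 in range(0, n, bs):
            idx = order[i0:i0 + bs]
            out = model.forward(x[idx], training=True)
            if config.n_outputs == 1:
                loss, grad = bce_loss(out[:, 0], labels[idx].astype(float))
                grad = grad[:, None]
            else:
                loss, grad = softmax_cross_entropy(out, labels[idx].astype(int))
            model.backward(grad.astype(np.float32))
            opt.step()
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            ep += loss
            nb += 1
        history.append(ep / nb)
        if sched is not None:
            sched.step(history[-1])
        if progress and (epoch + 1) % max(1, config.epochs // 10) == 0:
            print(f"epoch {epoch + 1}/{config.epochs}: loss {history[-1]:.4f}",
                  flush=True)
    return history


def predict_proba(model: nn.Sequential, volumes: list[Volume3D],
                  volume_shape=None) -> np.ndarray:
    """Deterministic eval-mode scores: (n,) probabilities for the binary
    model, (n, 5) raw scores for the subtype model."""
    if not volumes:
        return np.zeros((0,))
    shape = volume_shape or volumes[0].shape
    x = _as_batch(volumes, shape)
    outs = []
    for i0 in range(0, len(x), 32):
        outs.append(model.forward(x[i0:i0 + 32], training=False))
    out = np.concatenate(outs, axis=0)
    return out[:, 0] if out.shape[1] == 1 else out


def logistic_l1_baseline(latents: np.ndarray, labels: np.ndarray,
                         test_fraction: float = 0.2, seed: int = 0):
    """L1-penalized logistic regression on the multi-omic latent features.

    Penalty strength is chosen by internal cross-validation.  Returns
    (coefficients, test_probabilities, test_labels).
    """
    latents = np.asarray(latents, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    x_tr, x_te, y_tr, y_te = train_test_split(
        latents, labels, test_size=test_fraction, stratify=labels,
        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegressionCV(
            Cs=10, cv=5, penalty="l1", solver="liblinear", random_state=seed,
            max_iter=2000).fit(x_tr, y_tr)
    return clf.coef_[0], clf.predict_proba(x_te)[:, 1], y_te
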