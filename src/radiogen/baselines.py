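"""Conditional reconstruction baselines for the generative comparison.

Two autoencoder variants mirror the classical alternatives to the cGAN:

* ``trainable`` — a plain autoencoder.  An encoder compresses the volume
  to a bottleneck and the decoder reconstructs it under mean-squared
  loss.  A vanilla autoencoder has no conditional sampling path, so after
  training the bottleneck codes are ridge-regressed onto the patients'
  multi-omic latent vectors; generating "from genomics alone" decodes
  the bridge-predicted code.  The decoder only ever saw real encoder
  codes during training, so decoding predicted (conditional-mean) codes
  is exactly the distribution shift that makes autoencoders weak
  conditional generators.
* ``pretrained_frozen`` — the same, but the volumetric encoder is frozen
  at its fixed-seed initialization and never updated, standing in for a
  generic pretrained feature backbone.

Both share the generator/decoder family of the cGAN so FID comparisons
are at matched capacity and budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cgan import (CganConfig, build_generator, load_checkpoint,
                   save_checkpoint)
from .nn.losses import mse_loss
from .volio import Volume3D


@dataclass
class BaselineConfig:
    volume_shape: tuple[int, int, int] = (32, 128, 128)
    cond_dim: int = 17
    epochs: int = 1200
    learning_rate: float = 1e-3
    batch_size: int = 16
    encoder_mode: str = "trainable"        # trainable | pretrained_frozen
    base_channels: int = 8
    bridge_ridge: float = 1.0              # ridge penalty of the latent->code bridge
    seed: int = 0

    def __post_init__(self):
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.encoder_mode not in ("trainable", "pretrained_frozen"):
            raise ValueError(f"unknown encoder_mode {self.encoder_mode}")
        bad = [s for s in self.volume_shape if s % 8 != 0 or s < 8]
        if bad:
            raise ValueError(
                f"volume shape {self.volume_shape} needs every axis a multiple "
                "of 8 (>= 8)")


@dataclass
class BaselineCheckpoint:
    config: BaselineConfig
    encoder_state: dict[str, np.ndarray]
    decoder_state: dict[str, np.ndarray]
    bridge: dict[str, np.ndarray]          # latent -> code linear map (coef, intercept)
    epoch: int
    losses: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self.config,
                        {"encoder": self.encoder_state,
                         "decoder": self.decoder_state,
                         "bridge": self.bridge},
                        {"epoch": self.epoch, "losses": self.losses})

    @classmethod
    def load(cls, path: str | Path) -> "BaselineCheckpoint":
        cfg, states, meta = load_checkpoint(path)
        return cls(config=BaselineConfig(**cfg), encoder_state=states["encoder"],
                   decoder_state=states["decoder"], bridge=states["bridge"],
                   epoch=meta["epoch"], losses=meta["losses"])


def _build_encoder(config: BaselineConfig, rng: np.random.Generator) -> nn.Sequential:
    b = config.base_channels
    d, h, w = (s // 8 for s in config.volume_shape)
    return nn.Sequential(
        nn.ConvDown2(1, b, rng, is_first=True), nn.LeakyReLU(0.2),
        nn.ConvDown2(b, 2 * b, rng), nn.LeakyReLU(0.2),
        nn.ConvDown2(2 * b, 4 * b, rng), nn.LeakyReLU(0.2),
        nn.Flatten(),
        nn.Dense(4 * b * d * h * w, config.cond_dim, rng),
    )


def _decoder_config(config: BaselineConfig) -> CganConfig:
    return CganConfig(volume_shape=config.volume_shape,
                      cond_dim=config.cond_dim, noise_dim=0,
                      base_channels=config.base_channels,
                      seed=config.seed)


def train_baseline(records: list, config: BaselineConfig,
                   progress: bool = False) -> BaselineCheckpoint:
    """Reconstruction training followed by the post-hoc latent bridge."""
    if not records:
        raise ValueError("training set is empty")
    vols, lats = [], []
    for r in records:
        if not r.volumes:
            raise ValueError(f"record {r.patient_id} has no volumes")
        if len(r.latent) != config.cond_dim:
            raise ValueError(
                f"record {r.patient_id}: latent dim {len(r.latent)} != "
                f"cond_dim {config.cond_dim}")
        for v in r.volumes:
            vols.append(v.rescaled((-1.0, 1.0)).data)
            lats.append(np.asarray(r.latent, dtype=np.float32))
    x = np.stack(vols)[:, None].astype(np.float32)
    z_true = np.stack(lats)
    n = x.shape[0]

    rng = np.random.default_rng(config.seed)
    enc = _build_encoder(config, np.random.default_rng(config.seed + 20))
    dec = build_generator(_decoder_config(config),
                          np.random.default_rng(config.seed + 21))
    frozen = config.encoder_mode == "pretrained_frozen"
    params = [(f"dec.{k}", layer, name) for k, layer, name in dec.parameters()]
    if not frozen:
        params += [(f"enc.{k}", layer, name) for k, layer, name in enc.parameters()]
    opt = nn.Adam(params, lr=config.learning_rate)

    hist = []
    bs = max(1, config.batch_size)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep, nb = 0.0, 0
        for i0 in range(0, n, bs):
            idx = order[i0:i0 + bs]
            xb = x[idx]
            code = enc.forward(xb, training=not frozen)
            recon = dec.forward(code, training=True)
            loss, g_rec = mse_loss(recon, xb)
            g_code = dec.backward(g_rec)
            if not frozen:
                enc.backward(g_code)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step()
            ep += loss
            nb += 1
        hist.append(ep / nb)
        if progress and (epoch + 1) % max(1, config.epochs // 10) == 0:
            print(f"epoch {epoch + 1}/{config.epochs}: loss {hist[-1]:.4f}",
                  flush=True)

    # post-hoc bridge: ridge regression of the bottleneck codes on the
    # multi-omic latents, so the decoder can be driven from genomics alone
    codes = np.concatenate([enc.forward(x[i0:i0 + 64], training=False)
                            for i0 in range(0, n, 64)], axis=0)
    zc = np.column_stack([z_true, np.ones(n, dtype=np.float32)])
    lam = config.bridge_ridge
    a = zc.T @ zc + lam * np.eye(zc.shape[1], dtype=np.float32)
    coef = np.linalg.solve(a.astype(np.float64), (zc.T @ codes).astype(np.float64))
    bridge = {"coef": coef[:-1].astype(np.float32),
              "intercept": coef[-1].astype(np.float32)}

    return BaselineCheckpoint(config=config, encoder_state=enc.state_dict(),
                              decoder_state=dec.state_dict(), bridge=bridge,
                              epoch=config.epochs, losses=hist)


def baseline_generate(checkpoint: BaselineCheckpoint,
                      latents: np.ndarray) -> list[Volume3D]:
    """Decode volumes from latent vectors alone (deterministic): the
    bridge predicts bottleneck codes, the decoder renders them."""
    config = checkpoint.config
    latents = np.asarray(latents, dtype=np.float32)
    if latents.size == 0:
        return []
    if latents.ndim != 2 or latents.shape[1] != config.cond_dim:
        raise ValueError(
            f"latents must be (n, {config.cond_dim}), got {latents.shape}")
    dec = build_generator(_decoder_config(config), np.random.default_rng(0))
    dec.load_state_dict(checkpoint.decoder_state)
    codes = latents @ checkpoint.bridge["coef"] + checkpoint.bridge["intercept"]
    codes = codes.astype(np.float32)
    out = []
    for i0 in range(0, latents.shape[0], 32):
        y = dec.forward(codes[i0:i0 + 32], training=False)
        for row in y[:, 0]:
            out.append(Volume3D(np.clip(row, -1.0, 1.0),
                                intensity_range=(-1.0, 1.0)))
    return out


class BaselineSampler:
    """Checkpoint wrapper exposing generate(latents) for FID harnesses."""

    def __init__(self, checkpoint: BaselineCheckpoint):
        self.checkpoint = checkpoint

    def generate(self, latents: np.ndarray) -> list[Volume3D]:
        return baseline_generate(self.checkpoint, latents)
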