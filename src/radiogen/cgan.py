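"""Conditional GAN mapping a multi-omic latent vector to a 3D volume.

The generator projects the condition (optionally concatenated with a
noise vector) to a coarse (D/8, H/8, W/8) grid and upsamples through
three learned 2x transposed-convolution blocks with instance
normalization and leaky activations, ending in tanh so outputs live in
[-1, 1].  The discriminator scores (volume, condition) pairs: the
condition is linearly projected to a few constant channels that are
broadcast-concatenated to the volume, followed by three strided
convolution blocks and a dense head.

Training follows the least-squares GAN reading of an MSE adversarial
loss (real target 1, fake target 0, generator target 1), alternating one
discriminator and one generator step per batch, with an optional paired
reconstruction term on the generator (the data are paired latent/volume
records, and with no noise input the generator is a conditional
regression that the discriminator sharpens).

Default hyperparameters: batch size 2, generator lr 2.5e-5,
discriminator lr 1e-5, MSE adversarial loss, 1200 epochs, leaky slope
0.2.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn.losses import bce_loss, l1_loss, mse_loss
from .volio import Volume3D


@dataclass
class CganConfig:
    volume_shape: tuple[int, int, int] = (32, 128, 128)
    cond_dim: int = 17
    noise_dim: int = 0
    batch_size: int = 2
    lr_generator: float = 2.5e-5
    lr_discriminator: float = 1e-5
    adversarial_loss: str = "MSE"          # MSE | BCE | L1
    epochs: int = 1200
    leaky_slope: float = 0.2
    seed: int = 0
    base_channels: int = 8
    cond_channels: int = 4                 # broadcast condition channels in D
    recon_weight: float = 10.0             # paired reconstruction weight in G loss
    adam_beta1: float = 0.5                # DCGAN-style low momentum for stability

    def __post_init__(self):
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must be in (0,1)")
        if self.noise_dim < 0:
            raise ValueError("noise_dim must be >= 0")
        if self.adversarial_loss not in ("MSE", "BCE", "L1"):
            raise ValueError(f"unknown adversarial loss {self.adversarial_loss}")
        bad = [s for s in self.volume_shape if s % 8 != 0 or s < 8]
        if bad:
            raise ValueError(
                f"volume shape {self.volume_shape} not decomposable by three 2x "
                "upsampling stages; admissible shapes have every axis a "
                "multiple of 8 (>= 8)")


@dataclass
class CganCheckpoint:
    config: CganConfig
    generator_state: dict[str, np.ndarray]
    discriminator_state: dict[str, np.ndarray]
    epoch: int
    g_losses: list[float] = field(default_factory=list)
    d_losses: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self.config, {
            "generator": self.generator_state,
            "discriminator": self.discriminator_state,
        }, {"epoch": self.epoch, "g_losses": self.g_losses,
            "d_losses": self.d_losses})

    @classmethod
    def load(cls, path: str | Path) -> "CganCheckpoint":
        cfg_dict, states, meta = load_checkpoint(path)
        return cls(config=CganConfig(**cfg_dict),
                   generator_state=states["generator"],
                   discriminator_state=states["discriminator"],
                   epoch=meta["epoch"], g_losses=meta["g_losses"],
                   d_losses=meta["d_losses"])


# -- generic self-describing checkpoint archive -----------------------------

def save_checkpoint(path, config, states: dict[str, dict[str, np.ndarray]],
                    meta: dict) -> None:
    """Write config + named parameter groups + metadata into one zip."""
    cfg = asdict(config) if not isinstance(config, dict) else dict(config)
    buf = io.BytesIO()
    arrays = {f"{group}/{key}": arr
              for group, state in states.items() for key, arr in state.items()}
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as z:
        z.writestr("config.json", json.dumps(cfg, default=_json_default))
        z.writestr("meta.json", json.dumps(meta, default=_json_default))
        z.writestr("params.npz", buf.getvalue())


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_checkpoint(path):
    with zipfile.ZipFile(path) as z:
        cfg = json.loads(z.read("config.json"))
        meta = json.loads(z.read("meta.json"))
        with np.load(io.BytesIO(z.read("params.npz"))) as npz:
            states: dict[str, dict[str, np.ndarray]] = {}
            for full_key in npz.files:
                group, key = full_key.split("/", 1)
                states.setdefault(group, {})[key] = npz[full_key]
    if "volume_shape" in cfg:
        cfg["volume_shape"] = tuple(cfg["volume_shape"])
    return cfg, states, meta


# -- model builders ---------------------------------------------------------

def build_generator(config: CganConfig,
                    rng: np.random.Generator | None = None) -> nn.Sequential:
    """Condition (+ noise) vector -> volume in [-1, 1]."""
    rng = rng or np.random.default_rng(config.seed)
    d, h, w = (s // 8 for s in config.volume_shape)
    c4, c2, c1 = 4 * config.base_channels, 2 * config.base_channels, \
        config.base_channels
    slope = config.leaky_slope
    return nn.Sequential(
        nn.Dense(config.cond_dim + config.noise_dim, c4 * d * h * w, rng),
        nn.Reshape((c4, d, h, w)),
        nn.LeakyReLU(slope),
        nn.ConvUp2(c4, c2, rng), nn.InstanceNorm3d(c2), nn.LeakyReLU(slope),
        nn.ConvUp2(c2, c1, rng), nn.InstanceNorm3d(c1), nn.LeakyReLU(slope),
        nn.ConvUp2(c1, 1, rng),
        nn.Tanh(),
    )


class Discriminator:
    """(volume, condition) -> realness score per item."""

    def __init__(self, config: CganConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed + 1)
        self.config = config
        cc = config.cond_channels
        b = config.base_channels
        slope = config.leaky_slope
        d, h, w = (s // 8 for s in config.volume_shape)
        self.cond_proj = nn.Dense(config.cond_dim, cc, rng)
        self.trunk = nn.Sequential(
            nn.ConvDown2(1 + cc, b, rng), nn.LeakyReLU(slope),
            nn.ConvDown2(b, 2 * b, rng), nn.LeakyReLU(slope),
            nn.ConvDown2(2 * b, 4 * b, rng), nn.LeakyReLU(slope),
            nn.Flatten(),
            nn.Dense(4 * b * d * h * w, 1, rng),
        )

    def forward(self, volumes: np.ndarray, conds: np.ndarray,
                training: bool = False) -> np.ndarray:
        if volumes.shape[2:] != tuple(self.config.volume_shape):
            raise ValueError(
                f"volume shape {volumes.shape[2:]} does not match "
                f"configured {self.config.volume_shape}")
        n = volumes.shape[0]
        maps = self.cond_proj.forward(conds.astype(np.float32),
                                      training=training)      # (n, cc)
        self._map_shape = volumes.shape[2:]
        planes = np.broadcast_to(
            maps[:, :, None, None, None],
            (n, maps.shape[1]) + self._map_shape).astype(np.float32)
        x = np.concatenate([volumes, planes], axis=1)
        return self.trunk.forward(x, training=training)

    def backward(self, gscore: np.ndarray) -> np.ndarray:
        """Returns the gradient w.r.t. the input volume channel."""
        gx = self.trunk.backward(gscore)
        g_vol = gx[:, :1]
        g_planes = gx[:, 1:]
        self.cond_proj.backward(g_planes.sum(axis=(2, 3, 4)))
        return np.ascontiguousarray(g_vol)

    def parameters(self):
        pairs = [(f"cond.{name}", self.cond_proj, name)
                 for name in sorted(self.cond_proj.params)]
        pairs += [(f"trunk.{k}", layer, name)
                  for k, layer, name in self.trunk.parameters()]
        return pairs

    def state_dict(self):
        return {key: layer.params[name].copy()
                for key, layer, name in self.parameters()}

    def load_state_dict(self, state):
        for key, layer, name in self.parameters():
            layer.params[name] = state[key].astype(np.float32).copy()


def build_discriminator(config: CganConfig,
                        rng: np.random.Generator | None = None) -> Discriminator:
    return Discriminator(config, rng)


# -- training ---------------------------------------------------------------

def _adv_loss(kind: str):
    if kind == "MSE":
        return mse_loss
    if kind == "L1":
        return l1_loss

    def bce_on_score(score, target):
        # BCE reading: sigmoid on the raw score
        p = 1.0 / (1.0 + np.exp(-np.clip(score, -60, 60)))
        loss, gp = bce_loss(p, target)
        return loss, gp * p * (1 - p)

    return bce_on_score


def _training_arrays(records, config):
    vols, conds = [], []
    for r in records:
        if not r.volumes:
            raise ValueError(f"record {r.patient_id} has no volumes")
        if len(r.latent) != config.cond_dim:
            raise ValueError(
                f"record {r.patient_id}: latent dim {len(r.latent)} != "
                f"configured cond_dim {config.cond_dim}")
        for v in r.volumes:
            vols.append(v.rescaled((-1.0, 1.0)).data)
            conds.append(np.asarray(r.latent, dtype=np.float32))
    return (np.stack(vols)[:, None].astype(np.float32), np.stack(conds))


def train_cgan(records: list, config: CganConfig,
               progress: bool = False) -> CganCheckpoint:
    """Alternating least-squares adversarial training; fully seeded."""
    if not records:
        raise ValueError("training set is empty")
    x_real, conds = _training_arrays(records, config)
    n = x_real.shape[0]

    rng = np.random.default_rng(config.seed)
    gen = build_generator(config, np.random.default_rng(config.seed + 10))
    dis = build_discriminator(config, np.random.default_rng(config.seed + 11))
    beta1 = config.adam_beta1
    opt_g = nn.Adam(gen.parameters(), lr=config.lr_generator,
                    betas=(beta1, 0.999))
    opt_d = nn.Adam(dis.parameters(), lr=config.lr_discriminator,
                    betas=(beta1, 0.999))
    loss_fn = _adv_loss(config.adversarial_loss)

    g_hist, d_hist = [], []
    bs = max(1, config.batch_size)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        g_ep, d_ep, nb = 0.0, 0.0, 0
        for i0 in range(0, n, bs):
            idx = order[i0:i0 + bs]
            xb, cb = x_real[idx], conds[idx]
            zin = cb if config.noise_dim == 0 else np.concatenate(
                [cb, rng.standard_normal(
                    (len(idx), config.noise_dim)).astype(np.float32)], axis=1)

            # discriminator step (generator output detached)
            fake = gen.forward(zin, training=True)
            s_real = dis.forward(xb, cb, training=True)
            l_real, g_real = loss_fn(s_real, 1.0)
            dis.backward(g_real)
            grads_real = {key: layer.grads[name].copy()
                          for key, layer, name in dis.parameters()}
            s_fake = dis.forward(fake, cb, training=True)
            l_fake, g_fake = loss_fn(s_fake, 0.0)
            dis.backward(g_fake)
            for key, layer, name in dis.parameters():
                layer.grads[name] = 0.5 * (layer.grads[name] + grads_real[key])
            d_loss = 0.5 * (l_real + l_fake)
            opt_d.step()

            # generator step
            fake = gen.forward(zin, training=True)
            s_fake = dis.forward(fake, cb, training=True)
            l_adv, g_adv = loss_fn(s_fake, 1.0)
            g_vol = dis.backward(g_adv)
            g_loss = l_adv
            if config.recon_weight > 0:
                l_rec, g_rec = mse_loss(fake, xb)
                g_vol = g_vol + config.recon_weight * g_rec
                g_loss = g_loss + config.recon_weight * l_rec
            gen.backward(g_vol)
            opt_g.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(
                    f"non-finite GAN loss at epoch {epoch}")
            g_ep += g_loss
            d_ep += d_loss
            nb += 1
        g_hist.append(g_ep / nb)
        d_hist.append(d_ep / nb)
        if progress and (epoch + 1) % max(1, config.epochs // 10) == 0:
            print(f"epoch {epoch + 1}/{config.epochs}: "
                  f"G {g_hist[-1]:.4f}  D {d_hist[-1]:.4f}", flush=True)

    return CganCheckpoint(config=config, generator_state=gen.state_dict(),
                          discriminator_state=dis.state_dict(),
                          epoch=config.epochs, g_losses=g_hist, d_losses=d_hist)


def generate_volumes(checkpoint: CganCheckpoint, latents: np.ndarray,
                     seed: int = 0) -> list[Volume3D]:
    """One volume per latent row; deterministic when noise_dim == 0."""
    config = checkpoint.config
    latents = np.asarray(latents, dtype=np.float32)
    if latents.size == 0:
        return []
    if latents.ndim != 2 or latents.shape[1] != config.cond_dim:
        raise ValueError(
            f"latents must be (n, {config.cond_dim}), got {latents.shape}")
    gen = build_generator(config, np.random.default_rng(0))
    gen.load_state_dict(checkpoint.generator_state)
    rng = np.random.default_rng(seed)
    out: list[Volume3D] = []
    step = 32
    for i0 in range(0, latents.shape[0], step):
        z = latents[i0:i0 + step]
        if config.noise_dim > 0:
            z = np.concatenate(
                [z, rng.standard_normal(
                    (z.shape[0], config.noise_dim)).astype(np.float32)], axis=1)
        y = gen.forward(z, training=False)
        for row in y[:, 0]:
            out.append(Volume3D(np.clip(row, -1.0, 1.0),
                                intensity_range=(-1.0, 1.0)))
    return out


class CganSampler:
    """Checkpoint wrapper exposing generate(latents) for FID harnesses."""

    def __init__(self, checkpoint: CganCheckpoint, seed: int = 0):
        self.checkpoint = checkpoint
        self.seed = seed

    def generate(self, latents: np.ndarray) -> list[Volume3D]:
        return generate_volumes(self.checkpoint, latents, seed=self.seed)
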