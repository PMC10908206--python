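"""Fréchet distance between real and generated volume sets.

Features come from a pluggable volumetric extractor; the default is a
small frozen random-weight 3D conv net.  Random frozen conv features
preserve the *ranking* behaviour of the metric at phantom scale while
keeping the package download-free, but absolute values are not comparable
to scores computed with a pretrained medical-image network.

The squared Fréchet distance between Gaussians (mu_a, S_a), (mu_b, S_b):

    d^2 = |mu_a - mu_b|^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2})

computed via the symmetric eigendecomposition route
Tr((S_a S_b)^{1/2}) = Tr((S_a^{1/2} S_b S_a^{1/2})^{1/2}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .volio import Volume3D


@dataclass
class GaussianFeatureStats:
    """Sufficient statistics of a feature set for the Fréchet distance."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = self.mean.shape[0]
        if self.covariance.shape != (d, d):
            raise ValueError("covariance shape must match mean dimension")
        asym = np.abs(self.covariance - self.covariance.T).max()
        if asym > 1e-8:
            raise ValueError(f"covariance not symmetric (max asymmetry {asym:.2e})")


class FeatureExtractor:
    """Fixed-parameter volumetric feature function volume -> d-vector.

    Features are the per-channel spatial mean and standard deviation of
    every conv block, not just the deepest one: shallow-layer statistics
    carry the high-frequency texture content that distinguishes sharp
    from blurry volumes, mirroring the blur sensitivity of pretrained
    medical-image feature networks.
    """

    def __init__(self, blocks: list[nn.Sequential],
                 volume_shape: tuple[int, int, int],
                 feature_dim: int, name: str = "frozen-random-conv3d"):
        self.blocks = blocks
        self.volume_shape = tuple(volume_shape)
        self.feature_dim = feature_dim
        self.name = name

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        """batch (n, D, H, W) in [0,1] -> (n, d) feature matrix."""
        x = batch[:, None].astype(np.float32)
        feats = []
        for block in self.blocks:
            x = block.forward(x, training=False)       # (n, C, d', h', w')
            feats.append(x.mean(axis=(2, 3, 4)))
            feats.append(x.std(axis=(2, 3, 4)))
        return np.concatenate(feats, axis=1).astype(np.float64)


def default_extractor(volume_shape: tuple[int, int, int],
                      channels: tuple[int, ...] = (8, 16, 32),
                      seed: int = 12345) -> FeatureExtractor:
    """Frozen, fixed-seed random 3D conv net with multi-scale features."""
    rng = np.random.default_rng(seed)
    blocks = []
    in_ch = 1
    for ch in channels:
        blocks.append(nn.Sequential(nn.ConvDown2(in_ch, ch, rng),
                                    nn.LeakyReLU(0.2)))
        in_ch = ch
    return FeatureExtractor(blocks, volume_shape,
                            feature_dim=2 * sum(channels))


def extract_features(volumes: list[Volume3D],
                     extractor: FeatureExtractor) -> np.ndarray:
    """Stack volumes (rescaled to [0,1]) and run the extractor."""
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"volumes have mixed shapes: {shapes}")
    shape = volumes[0].shape
    if extractor.volume_shape and tuple(extractor.volume_shape) != shape:
        raise ValueError(
            f"extractor expects shape {extractor.volume_shape}, got {shape}")
    batch = np.stack([v.rescaled((0.0, 1.0)).data for v in volumes])
    feats = []
    step = 64
    for i in range(0, len(batch), step):
        feats.append(extractor(batch[i:i + step]))
    return np.concatenate(feats, axis=0)


def fit_gaussian(features: np.ndarray) -> GaussianFeatureStats:
    """Sample mean and (n-1)-denominator covariance, symmetry enforced."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2D feature matrix with at least 2 rows")
    mu = features.mean(axis=0)
    cov = np.cov(features, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = 0.5 * (cov + cov.T)
    return GaussianFeatureStats(mean=mu, covariance=cov, n=features.shape[0])


def _sqrt_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, eigenvalues
    clipped at zero."""
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(stats_a: GaussianFeatureStats,
                     stats_b: GaussianFeatureStats) -> float:
    """Squared Fréchet (2-Wasserstein) distance between two Gaussians."""
    if stats_a.mean.shape != stats_b.mean.shape:
        raise ValueError(
            f"feature dimensions differ: {stats_a.mean.shape[0]} vs "
            f"{stats_b.mean.shape[0]}")
    mu_d = stats_a.mean - stats_b.mean
    sa, sb = stats_a.covariance, stats_b.covariance
    try:
        root_a = _sqrt_psd(sa)
        inner = root_a @ sb @ root_a
        tr_sqrt = float(np.sqrt(np.clip(
            np.linalg.eigvalsh(0.5 * (inner + inner.T)), 0.0, None)).sum())
    except np.linalg.LinAlgError:
        eps = 1e-6 * float(np.mean(np.diag(sa) + np.diag(sb)) / 2.0 + 1e-12)
        jit = eps * np.eye(sa.shape[0])
        root_a = _sqrt_psd(sa + jit)
        inner = root_a @ (sb + jit) @ root_a
        tr_sqrt = float(np.sqrt(np.clip(
            np.linalg.eigvalsh(0.5 * (inner + inner.T)), 0.0, None)).sum())
    d2 = float(mu_d @ mu_d + np.trace(sa) + np.trace(sb) - 2.0 * tr_sqrt)
    return max(0.0, d2)


def fid_between(real: list[Volume3D], fake: list[Volume3D],
                extractor: FeatureExtractor) -> float:
    return frechet_distance(fit_gaussian(extract_features(real, extractor)),
                            fit_gaussian(extract_features(fake, extractor)))


def fid_with_uncertainty(real_volumes: list[Volume3D],
                         fake_volumes: list[Volume3D],
                         extractor: FeatureExtractor,
                         n_boot: int = 20, seed: int = 0) -> tuple[float, float]:
    """Bootstrap mean and spread (std over resamples) of the FID.

    Resampling is paired: when the two sets have equal size (generated
    volumes are patient-matched to real ones) one index draw per replicate
    is applied to both sets, so identical sets score exactly zero; unequal
    sizes fall back to independent draws.  Features are extracted once.
    n_boot=1 reports spread 0.
    """
    if len(real_volumes) < 2 or len(fake_volumes) < 2:
        raise ValueError("both volume sets need at least 2 members")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fr = extract_features(real_volumes, extractor)
    ff = extract_features(fake_volumes, extractor)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        ir = rng.integers(0, fr.shape[0], size=fr.shape[0])
        jf = ir if fr.shape[0] == ff.shape[0] else \
            rng.integers(0, ff.shape[0], size=ff.shape[0])
        vals.append(frechet_distance(fit_gaussian(fr[ir]),
                                     fit_gaussian(ff[jf])))
    vals = np.asarray(vals)
    spread = float(vals.std(ddof=0)) if len(vals) > 1 else 0.0
    return float(vals.mean()), spread


@dataclass
class CrossvalFidResult:
    table: "object"                      # pandas DataFrame: fold, fid_mean, fid_spread
    best_fold: int
    best_artifact: object = None         # whatever the trainer returned for it
    artifacts: list = field(default_factory=list)


def crossval_fid(real_records: list, trainer, k: int, extractor: FeatureExtractor,
                 n_boot: int = 20, seed: int = 0) -> CrossvalFidResult:
    """k-fold FID evaluation of a conditional generator.

    ``trainer(train_records, fold_seed)`` must return an object with a
    ``generate(latents) -> list[Volume3D]`` method.  For each fold the
    model is trained on the other k-1 folds, asked to generate volumes for
    the held-out latents, and scored against the held-out real volumes.
    The fold with the lowest mean FID is selected.
    """
    import pandas as pd

    from .volio import kfold_indices

    folds = kfold_indices(len(real_records), k, seed=seed)
    rows, artifacts = [], []
    for fold_id, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train = [r for i, r in enumerate(real_records) if i not in test_set]
        test = [real_records[i] for i in sorted(test_set)]
        model = trainer(train, seed + 1000 + fold_id)
        latents = np.stack([r.latent for r in test])
        fake = model.generate(latents)
        real_vols = [r.volumes[0] for r in test]
        mean, spread = fid_with_uncertainty(real_vols, fake, extractor,
                                            n_boot=n_boot,
                                            seed=seed + 2000 + fold_id)
        rows.append({"fold": fold_id, "fid_mean": mean, "fid_spread": spread,
                     "n_test": len(test)})
        artifacts.append(model)
    table = pd.DataFrame(rows)
    best = int(table["fid_mean"].idxmin())
    return CrossvalFidResult(table=table, best_fold=best,
                             best_artifact=artifacts[best], artifacts=artifacts)
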