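"""Synthetic radiogenomic phantom cohorts.

Each simulated patient carries a low-dimensional multi-omic latent vector
(the kind produced by factorizing expression / methylation / copy-number
tensors), per-gene binary mutation labels, a 5-class molecular subtype,
and one or more 3D phantom "MRI" volumes whose lesion appearance is
driven by the latent vector.  This gives every downstream stage —
conditional generation, Fréchet-distance evaluation, mutation and subtype
classification — a ground truth with known, tunable effect sizes.

Label model
-----------
For gene g with effect vector w_g and intercept b_g,

    P(mutated) = logistic(w_g · z + b_g),

and the subtype is a categorical draw from softmax(S z) with S the
5 x latent_dim coefficient matrix.  Subtypes are coded Normal=0, Basal=1,
LumA=2, LumB=3, HER2=4.

Phantom model
-------------
A fixed ellipsoidal "breast" of baseline intensity contains a single
Gaussian lesion blob whose amplitude and radius increase monotonically
with the scalar score s = lesion_effect · z, plus i.i.d. Gaussian voxel
noise.  Intensities live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volio import Volume3D

#: subtype integer coding used throughout
SUBTYPE_CODES = {"Normal": 0, "Basal": 1, "LumA": 2, "LumB": 3, "HER2": 4}

DEFAULT_LATENT_DIM = 17
DEFAULT_VOLUME_SHAPE = (32, 128, 128)
TEST_VOLUME_SHAPE = (8, 32, 32)

# mutation prevalences of the three driver genes in the reference cohort
# (mutated / total): TP53 235/690, PIK3CA 247/690, CDH1 112/690
DEFAULT_GENE_PREVALENCE = {"TP53": 235 / 690, "PIK3CA": 247 / 690, "CDH1": 112 / 690}


@dataclass
class GeneSpec:
    """Latent -> mutation-label link for one gene."""

    name: str
    effect: np.ndarray          # latent_dim effect vector
    intercept: float = 0.0

    def __post_init__(self):
        self.effect = np.asarray(self.effect, dtype=float)


@dataclass
class CohortSpec:
    n_patients: int
    latent_dim: int = DEFAULT_LATENT_DIM
    volume_shape: tuple[int, int, int] = DEFAULT_VOLUME_SHAPE
    gene_specs: list[GeneSpec] = field(default_factory=list)
    subtype_coeffs: np.ndarray | None = None      # 5 x latent_dim
    lesion_effect: np.ndarray | None = None       # latent_dim
    noise_sd: float = 0.05
    volumes_per_patient: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.latent_dim < 1:
            raise ValueError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if len(self.volume_shape) != 3 or any(s < 4 for s in self.volume_shape):
            raise ValueError(
                f"volume_shape entries must all be >= 4, got {self.volume_shape}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.volumes_per_patient < 1:
            raise ValueError("volumes_per_patient must be >= 1")
        if self.subtype_coeffs is None:
            self.subtype_coeffs = np.zeros((5, self.latent_dim))
        self.subtype_coeffs = np.asarray(self.subtype_coeffs, dtype=float)
        if self.subtype_coeffs.shape != (5, self.latent_dim):
            raise ValueError(
                f"subtype_coeffs must be 5 x {self.latent_dim}, "
                f"got {self.subtype_coeffs.shape}")
        if self.lesion_effect is None:
            self.lesion_effect = np.zeros(self.latent_dim)
        self.lesion_effect = np.asarray(self.lesion_effect, dtype=float)
        if self.lesion_effect.shape != (self.latent_dim,):
            raise ValueError("lesion_effect length must equal latent_dim")
        for g in self.gene_specs:
            if g.effect.shape != (self.latent_dim,):
                raise ValueError(
                    f"gene {g.name}: effect length {g.effect.shape[0]} "
                    f"!= latent_dim {self.latent_dim}")


@dataclass
class PatientRecord:
    patient_id: str
    latent: np.ndarray
    mutation_labels: dict[str, int]
    subtype: int
    volumes: list[Volume3D] = field(default_factory=list)
    provenance: str = "real"

    def __post_init__(self):
        for gene, lab in self.mutation_labels.items():
            if lab not in (0, 1):
                raise ValueError(f"mutation label for {gene} must be 0/1, got {lab}")
        if self.subtype not in (0, 1, 2, 3, 4):
            raise ValueError(f"subtype must be in 0..4, got {self.subtype}")
        if self.provenance not in ("real", "generated"):
            raise ValueError(f"provenance must be real|generated, got {self.provenance}")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def assign_labels(latent: np.ndarray, gene_specs: list[GeneSpec],
                  subtype_coeffs: np.ndarray,
                  rng: np.random.Generator | int) -> tuple[dict[str, int], int]:
    """Draw mutation labels and a subtype for one latent vector."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    latent = np.asarray(latent, dtype=float)
    labels = {}
    for g in gene_specs:
        if g.effect.shape != latent.shape:
            raise ValueError(
                f"gene {g.name}: effect length {g.effect.shape[0]} != "
                f"latent length {latent.shape[0]}")
        p = _logistic(float(g.effect @ latent) + g.intercept)
        labels[g.name] = int(rng.random() < p)
    subtype_coeffs = np.asarray(subtype_coeffs, dtype=float)
    if subtype_coeffs.shape[1] != latent.shape[0]:
        raise ValueError("subtype_coeffs width must equal latent length")
    scores = subtype_coeffs @ latent
    scores -= scores.max()
    p = np.exp(scores)
    p /= p.sum()
    subtype = int(rng.choice(len(p), p=p))
    return labels, subtype


def lesion_center(shape: tuple[int, int, int]) -> tuple[float, float, float]:
    """Fixed lesion position, off-center inside the breast ellipsoid."""
    d, h, w = shape
    return (0.5 * (d - 1), 0.42 * (h - 1), 0.58 * (w - 1))


def lesion_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of the region the lesion blob can occupy."""
    d, h, w = shape
    zc, yc, xc = lesion_center(shape)
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                             indexing="ij")
    r = 0.16 * min(h, w)
    return ((zz - zc) / max(1.0, 0.75 * r)) ** 2 + ((yy - yc) / r) ** 2 + \
        ((xx - xc) / r) ** 2 <= 1.0


def _breast_mask(shape: tuple[int, int, int]) -> np.ndarray:
    d, h, w = shape
    zz, yy, xx = np.meshgrid(np.linspace(-1, 1, d), np.linspace(-1, 1, h),
                             np.linspace(-1, 1, w), indexing="ij")
    return (zz / 0.95) ** 2 + (yy / 0.85) ** 2 + (xx / 0.9) ** 2 <= 1.0


def render_phantom(latent: np.ndarray, shape: tuple[int, int, int],
                   lesion_effect: np.ndarray, noise_sd: float,
                   rng: np.random.Generator | int) -> Volume3D:
    """Render one phantom volume for a latent vector.

    The lesion amplitude is 0.15 + 0.45 * logistic(s) and its radius grows
    by up to 30% with tanh(s/2), s = lesion_effect . latent, so any summary
    statistic of the blob is strictly monotone in s.
    """
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError(f"volume shape entries must all be >= 4, got {shape}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    latent = np.asarray(latent, dtype=float)
    lesion_effect = np.asarray(lesion_effect, dtype=float)
    if lesion_effect.shape != latent.shape:
        raise ValueError("lesion_effect length must equal latent length")
    s = float(lesion_effect @ latent)

    d, h, w = shape
    vol = np.zeros(shape, dtype=np.float32)
    vol[_breast_mask(shape)] = 0.35

    amplitude = 0.15 + 0.45 * _logistic(s)
    base_r = 0.10 * min(h, w)
    radius = base_r * (1.0 + 0.3 * np.tanh(s / 2.0))
    zc, yc, xc = lesion_center(shape)
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                             indexing="ij")
    q = ((zz - zc) / max(1.0, 0.75 * radius)) ** 2 + \
        ((yy - yc) / radius) ** 2 + ((xx - xc) / radius) ** 2
    vol += (amplitude * np.exp(-0.5 * q)).astype(np.float32)

    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
    np.clip(vol, 0.0, 1.0, out=vol)
    return Volume3D(vol, intensity_range=(0.0, 1.0))


def simulate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Simulate a full cohort; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_patients):
        latent = rng.standard_normal(spec.latent_dim)
        labels, subtype = assign_labels(latent, spec.gene_specs,
                                        spec.subtype_coeffs, rng)
        volumes = [
            render_phantom(latent, spec.volume_shape, spec.lesion_effect,
                           spec.noise_sd, rng)
            for _ in range(spec.volumes_per_patient)
        ]
        records.append(PatientRecord(
            patient_id=f"SYN-{i:04d}", latent=latent, mutation_labels=labels,
            subtype=subtype, volumes=volumes, provenance="real"))
    return records


def intercept_for_prevalence(target: float, effect_scale: float = 0.0) -> float:
    """Logit intercept giving the target marginal prevalence.

    With a nonzero effect vector w the marginal prevalence is
    E[logistic(w.z + b)] over z ~ N(0, I), which is flatter than
    logistic(b), so the intercept must be solved for.  ``effect_scale``
    is |w|; the 1-D expectation is evaluated by Gauss-Hermite quadrature
    and inverted with a bracketing root finder (exact at effect 0).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must be in (0,1)")
    logit = float(np.log(target / (1.0 - target)))
    if effect_scale == 0.0:
        return logit
    from scipy.optimize import brentq

    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def marginal(b):
        return float(weights @ _logistic(effect_scale * nodes + b)) - target

    span = 2.0 + abs(logit) * (1.0 + 2.0 * effect_scale)
    return float(brentq(marginal, logit - span, logit + span, xtol=1e-10))


def default_gene_specs(latent_dim: int = DEFAULT_LATENT_DIM,
                       effect_size: float = 0.0,
                       prevalences: dict[str, float] | None = None) -> list[GeneSpec]:
    """Gene specs matching the reference-cohort prevalences.

    With ``effect_size`` > 0 each gene loads on the first latent axis and
    the intercept carries the logistic-normal correction so the marginal
    prevalence still lands near the target.
    """
    prevalences = prevalences or DEFAULT_GENE_PREVALENCE
    specs = []
    for name, prev in prevalences.items():
        effect = np.zeros(latent_dim)
        effect[0] = effect_size
        specs.append(GeneSpec(name=name, effect=effect,
                              intercept=intercept_for_prevalence(prev,
                                                                 effect_size)))
    return specs
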