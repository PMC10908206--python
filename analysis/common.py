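"""Shared study conditions and artifact paths for the analysis scripts.

The phantom study runs at desk scale: 200 patients, 8 x 32 x 32 volumes
(the full 32 x 128 x 128 resolution is supported by every component but
is not needed to exercise the pipeline's claims).  Mutation prevalences
follow the reference cohort (TP53 235/690, PIK3CA 247/690, CDH1
112/690); the lesion effect and the TP53 effect load on the same latent
axis so the mutation signal is visible in the images.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from radiogen.baselines import BaselineConfig
from radiogen.cgan import CganConfig
from radiogen.classify import CnnConfig
from radiogen.cohort import CohortSpec, GeneSpec, intercept_for_prevalence

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

SHAPE = (8, 32, 32)
LATENT_DIM = 17
N_PATIENTS = 200
NOISE_SD = 0.05

# (name, prevalence, lesion-axis loading, private axis, private loading):
# the phantom exposes exactly one image scalar (the lesion score on latent
# axis 0), so each label's image-predictability is set by its loading on
# that axis; the graded loadings mirror the genes' reported ordering of
# image AUCs (TP53 strongest), and the private axes keep the labels from
# being deterministic functions of one another.
GENES = [("TP53", 235 / 690, 4.0, 1, 1.0),
         ("PIK3CA", 247 / 690, 2.5, 2, 2.0),
         ("CDH1", 112 / 690, 2.0, 3, 2.2)]


def cohort_spec(seed: int) -> CohortSpec:
    gene_specs = []
    for name, prev, shared, axis, private in GENES:
        eff = np.zeros(LATENT_DIM)
        eff[0] = shared
        eff[axis] = private
        gene_specs.append(GeneSpec(
            name, eff,
            intercept_for_prevalence(prev, float(np.linalg.norm(eff)))))
    # subtype softmax loadings graded along the lesion axis so the classes
    # are ordinally separated in the one image-visible direction
    sub = np.zeros((5, LATENT_DIM))
    for k in range(5):
        sub[k, 0] = (k - 2) * 1.5
        sub[k, 4 + k] = 0.8
    lesion = np.zeros(LATENT_DIM)
    lesion[0] = 2.0
    return CohortSpec(n_patients=N_PATIENTS, latent_dim=LATENT_DIM,
                      volume_shape=SHAPE, gene_specs=gene_specs,
                      subtype_coeffs=sub, lesion_effect=lesion,
                      noise_sd=NOISE_SD, seed=seed)


def cgan_config(seed: int) -> CganConfig:
    """Desk-scale training recipe (the full-scale defaults follow the
    reference hyperparameters; see CganConfig)."""
    return CganConfig(volume_shape=SHAPE, cond_dim=LATENT_DIM, batch_size=16,
                      lr_generator=1e-3, lr_discriminator=2e-4, epochs=500,
                      base_channels=8, recon_weight=10.0, seed=seed)


def baseline_config(seed: int, mode: str = "trainable") -> BaselineConfig:
    return BaselineConfig(volume_shape=SHAPE, cond_dim=LATENT_DIM, epochs=500,
                          learning_rate=1e-3, batch_size=16, base_channels=8,
                          encoder_mode=mode, seed=seed)


def cnn_config(seed: int, n_outputs: int = 1) -> CnnConfig:
    return CnnConfig(volume_shape=SHAPE, batch_size=16, epochs=15,
                     learning_rate=1e-3, plateau_patience=5,
                     n_outputs=n_outputs, seed=seed)
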