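"""Synthetic cohort generator: label model, phantom rendering, and
reproducibility guarantees."""

import numpy as np
import pytest
from scipy import stats as sps

from radiogen.cohort import (CohortSpec, GeneSpec, assign_labels,
                             default_gene_specs, intercept_for_prevalence,
                             lesion_mask, render_phantom, simulate_cohort)

from conftest import TINY_SHAPE


class TestSimulateCohort:
    def test_empty_cohort(self):
        assert simulate_cohort(CohortSpec(n_patients=0)) == []

    def test_default_latent_dimension_is_17(self):
        recs = simulate_cohort(CohortSpec(n_patients=3,
                                          volume_shape=TINY_SHAPE))
        assert all(len(r.latent) == 17 for r in recs)

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=-1)
        with pytest.raises(ValueError):
            CohortSpec(n_patients=1, volume_shape=(2, 16, 16))
        with pytest.raises(ValueError):
            CohortSpec(n_patients=1, noise_sd=-0.1)

    def test_prevalence_hits_target_within_99pct_binomial_interval(self):
        """Intercept tuned for 235/690 mutated; the observed count must
        fall in the central 99% binomial interval around that target."""
        n, target = 690, 235 / 690
        spec = CohortSpec(
            n_patients=n, volume_shape=TINY_SHAPE,
            gene_specs=default_gene_specs(prevalences={"TP53": target}),
            seed=5)
        recs = simulate_cohort(spec)
        count = sum(r.mutation_labels["TP53"] for r in recs)
        lo = sps.binom.ppf(0.005, n, target)
        hi = sps.binom.ppf(0.995, n, target)
        assert lo <= count <= hi

    def test_identical_specs_give_identical_cohorts(self):
        spec = dict(n_patients=6, latent_dim=4, volume_shape=TINY_SHAPE,
                    gene_specs=[GeneSpec("G", np.ones(4), 0.1)],
                    lesion_effect=np.r_[1.0, 0, 0, 0], noise_sd=0.05, seed=3)
        a = simulate_cohort(CohortSpec(**spec))
        b = simulate_cohort(CohortSpec(**spec))
        for ra, rb in zip(a, b):
            assert ra.patient_id == rb.patient_id
            assert np.array_equal(ra.latent, rb.latent)
            assert ra.mutation_labels == rb.mutation_labels
            assert ra.subtype == rb.subtype
            assert ra.volumes[0].data.tobytes() == rb.volumes[0].data.tobytes()

    def test_volumes_have_declared_shape_and_range(self):
        recs = simulate_cohort(CohortSpec(
            n_patients=4, latent_dim=3, volume_shape=TINY_SHAPE,
            lesion_effect=np.r_[2.0, 0, 0], noise_sd=0.2, seed=0))
        for r in recs:
            v = r.volumes[0]
            assert v.shape == TINY_SHAPE
            assert v.data.min() >= 0.0 and v.data.max() <= 1.0

    def test_multiple_volumes_per_patient(self):
        recs = simulate_cohort(CohortSpec(
            n_patients=2, latent_dim=3, volume_shape=TINY_SHAPE,
            volumes_per_patient=3, noise_sd=0.05, seed=0))
        assert all(len(r.volumes) == 3 for r in recs)
        # noise differs between repeat scans of the same patient
        assert not np.array_equal(recs[0].volumes[0].data,
                                  recs[0].volumes[1].data)


class TestAssignLabels:
    def test_zero_effects_give_half_prevalence(self):
        rng = np.random.default_rng(0)
        spec = [GeneSpec("G", np.zeros(3), 0.0)]
        coeffs = np.zeros((5, 3))
        n = 10_000
        hits = sum(assign_labels(rng.standard_normal(3), spec, coeffs, rng)[0]["G"]
                   for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) <= 3 * se

    def test_saturated_negative_intercept_never_mutates(self):
        rng = np.random.default_rng(1)
        spec = [GeneSpec("G", np.zeros(3), -50.0)]
        labels = [assign_labels(rng.standard_normal(3), spec,
                                np.zeros((5, 3)), rng)[0]["G"]
                  for _ in range(200)]
        assert set(labels) == {0}

    def test_zero_subtype_coeffs_uniform_over_five_classes(self):
        rng = np.random.default_rng(2)
        n = 10_000
        counts = np.zeros(5)
        for _ in range(n):
            _, s = assign_labels(rng.standard_normal(3), [], np.zeros((5, 3)),
                                 rng)
            counts[s] += 1
        se = np.sqrt(0.2 * 0.8 / n)
        assert np.all(np.abs(counts / n - 0.2) <= 4 * se)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            assign_labels(np.zeros(3), [GeneSpec("G", np.zeros(4), 0.0)],
                          np.zeros((5, 3)), 0)


class TestRenderPhantom:
    def test_zero_latent_no_noise_is_reproducible_baseline(self):
        a = render_phantom(np.zeros(3), TINY_SHAPE, np.zeros(3), 0.0, 0)
        b = render_phantom(np.zeros(3), TINY_SHAPE, np.zeros(3), 0.0, 1)
        assert np.array_equal(a.data, b.data)      # noise-free: seed moot

    def test_same_latent_and_seed_bit_identical(self):
        z = np.r_[0.7, -0.2, 1.1]
        a = render_phantom(z, TINY_SHAPE, np.r_[1.0, 0, 0], 0.1, 42)
        b = render_phantom(z, TINY_SHAPE, np.r_[1.0, 0, 0], 0.1, 42)
        assert a.data.tobytes() == b.data.tobytes()

    def test_lesion_intensity_monotone_in_effect_score(self):
        effect = np.r_[1.0, 0.0, 0.0]
        mask = lesion_mask(TINY_SHAPE)
        means = []
        for z0 in (-2.0, 0.0, 2.0):
            vol = render_phantom(np.r_[z0, 0.0, 0.0], TINY_SHAPE, effect,
                                 0.0, 0)
            means.append(vol.data[mask].mean())
        assert means[0] < means[1] < means[2]

    def test_intercept_for_prevalence_inverts_logistic(self):
        for p in (0.1, 0.34, 0.5, 0.9):
            b = intercept_for_prevalence(p)
            assert 1.0 / (1.0 + np.exp(-b)) == pytest.approx(p)
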