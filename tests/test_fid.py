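"""Fréchet-distance module: hand-computed cases, brute-force oracle
agreement, and the bootstrap/cross-validation harnesses."""

import numpy as np
import pytest
import scipy.linalg

from radiogen.fid import (GaussianFeatureStats, crossval_fid,
                          default_extractor, extract_features, fid_between,
                          fid_with_uncertainty, fit_gaussian,
                          frechet_distance)
from radiogen.volio import Volume3D

from conftest import TINY_SHAPE


def stats(mean, cov, n=10):
    return GaussianFeatureStats(np.asarray(mean, float),
                                np.asarray(cov, float), n)


def oracle_frechet(sa, sb, mu_a, mu_b):
    """Independent route: scipy sqrtm of the (possibly asymmetric)
    product, as in the classical FID implementation."""
    diff = np.asarray(mu_a) - np.asarray(mu_b)
    covmean = scipy.linalg.sqrtm(np.asarray(sa) @ np.asarray(sb))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    return float(diff @ diff + np.trace(sa) + np.trace(sb)
                 - 2.0 * np.trace(covmean))


def random_psd(rng, d):
    a = rng.standard_normal((d, d))
    return a @ a.T + 0.1 * np.eye(d)


class TestFrechetDistance:
    def test_identical_stats_zero(self):
        rng = np.random.default_rng(0)
        s = random_psd(rng, 4)
        mu = rng.standard_normal(4)
        assert frechet_distance(stats(mu, s), stats(mu, s)) <= 1e-8

    def test_univariate_unit_mean_shift(self):
        a = stats([0.0], [[1.0]])
        b = stats([1.0], [[1.0]])
        assert frechet_distance(a, b) == pytest.approx(1.0, abs=1e-10)

    def test_commuting_covariances(self):
        a = stats([0.0, 0.0], np.eye(2))
        b = stats([0.0, 0.0], 4.0 * np.eye(2))
        # Tr(I + 4I - 2*2I) = 2
        assert frechet_distance(a, b) == pytest.approx(2.0, abs=1e-10)

    def test_matches_sqrtm_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            sa, sb = random_psd(rng, 5), random_psd(rng, 5)
            mu_a, mu_b = rng.standard_normal(5), rng.standard_normal(5)
            ours = frechet_distance(stats(mu_a, sa), stats(mu_b, sb))
            ref = oracle_frechet(sa, sb, mu_a, mu_b)
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = stats(rng.standard_normal(3), random_psd(rng, 3))
            b = stats(rng.standard_normal(3), random_psd(rng, 3))
            assert frechet_distance(a, b) == pytest.approx(
                frechet_distance(b, a), abs=1e-8)

    def test_strictly_increases_with_mean_separation(self):
        rng = np.random.default_rng(3)
        sa, sb = random_psd(rng, 3), random_psd(rng, 3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        dists = [frechet_distance(stats(np.zeros(3), sa),
                                  stats(t * direction, sb))
                 for t in (0.0, 0.5, 1.0, 2.0)]
        assert all(d2 > d1 for d1, d2 in zip(dists, dists[1:]))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            frechet_distance(stats([0.0], [[1.0]]),
                             stats([0.0, 0.0], np.eye(2)))


class TestFitGaussian:
    def test_hand_example_n_minus_one_denominator(self):
        g = fit_gaussian(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert np.allclose(g.mean, [1.0, 1.0])
        assert np.allclose(g.covariance, [[2.0, 2.0], [2.0, 2.0]])

    def test_identical_rows_zero_covariance(self):
        g = fit_gaussian(np.ones((5, 3)))
        assert np.allclose(g.covariance, 0.0)

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            fit_gaussian(np.ones((1, 3)))


class TestExtractor:
    def test_feature_matrix_shape_and_determinism(self):
        ex = default_extractor(TINY_SHAPE)
        rng = np.random.default_rng(0)
        vols = [Volume3D(rng.random(TINY_SHAPE).astype(np.float32))
                for _ in range(5)]
        feats = extract_features(vols, ex)
        assert feats.shape == (5, ex.feature_dim)
        assert np.array_equal(feats, extract_features(vols, ex))

    def test_duplicate_volumes_identical_rows(self):
        ex = default_extractor(TINY_SHAPE)
        v = Volume3D(np.random.default_rng(1).random(TINY_SHAPE).astype(np.float32))
        feats = extract_features([v, v, v], ex)
        assert np.array_equal(feats[0], feats[1])
        assert np.array_equal(feats[0], feats[2])

    def test_shape_mismatch_raises(self):
        ex = default_extractor(TINY_SHAPE)
        with pytest.raises(ValueError):
            extract_features([Volume3D(np.zeros((8, 8, 8), dtype=np.float32))], ex)


class TestBootstrap:
    def _vols(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [Volume3D((0.3 + 0.1 * rng.random(TINY_SHAPE)).astype(np.float32))
                for _ in range(n)]

    def test_identical_sets_score_zero(self):
        vols = self._vols(10)
        ex = default_extractor(TINY_SHAPE)
        mean, spread = fid_with_uncertainty(vols, vols, ex, n_boot=20, seed=0)
        assert mean >= 0.0
        assert mean <= 1e-10

    def test_single_resample_spread_zero(self):
        ex = default_extractor(TINY_SHAPE)
        _, spread = fid_with_uncertainty(self._vols(8), self._vols(8, seed=5),
                                         ex, n_boot=1, seed=0)
        assert spread == 0.0

    def test_undersized_sets_raise(self):
        ex = default_extractor(TINY_SHAPE)
        with pytest.raises(ValueError):
            fid_with_uncertainty(self._vols(1), self._vols(5), ex)

    def test_bootstrap_mean_near_closed_form_on_injected_gaussians(self):
        """Bypass the extractor: known Gaussians in feature space."""
        rng = np.random.default_rng(11)
        d = 4
        mu_a, mu_b = np.zeros(d), np.full(d, 0.8)
        sa, sb = np.eye(d), 1.5 * np.eye(d)
        closed = frechet_distance(stats(mu_a, sa), stats(mu_b, sb))
        n = 4000
        fa = rng.multivariate_normal(mu_a, sa, size=n)
        fb = rng.multivariate_normal(mu_b, sb, size=n)
        vals = []
        for k in range(30):
            ia = rng.integers(0, n, n)
            ib = rng.integers(0, n, n)
            vals.append(frechet_distance(fit_gaussian(fa[ia]),
                                         fit_gaussian(fb[ib])))
        vals = np.asarray(vals)
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - closed) <= 3 * se + 0.05 * closed


class TestCrossvalFid:
    def test_table_shape_selection_and_determinism(self, tiny_cohort):
        ex = default_extractor(TINY_SHAPE)

        class CannedModel:
            """Deterministic stand-in trainer: returns noisy copies of a
            fixed template so FID varies across folds."""

            def __init__(self, seed):
                self.rng_seed = seed

            def generate(self, latents):
                rng = np.random.default_rng(self.rng_seed)
                return [Volume3D((0.3 + 0.05 * rng.random(TINY_SHAPE))
                                 .astype(np.float32)) for _ in latents]

        def trainer(recs, fold_seed):
            return CannedModel(fold_seed)

        res = crossval_fid(tiny_cohort, trainer, k=3, extractor=ex,
                           n_boot=5, seed=4)
        assert len(res.table) == 3
        assert res.best_fold == int(res.table["fid_mean"].idxmin())
        res2 = crossval_fid(tiny_cohort, trainer, k=3, extractor=ex,
                            n_boot=5, seed=4)
        assert res.table.equals(res2.table)
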