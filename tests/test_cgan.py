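"""Conditional GAN: architecture contracts, training determinism, and
checkpoint round-trips (all at tiny scale)."""

import numpy as np
import pytest

from radiogen.cgan import (CganCheckpoint, CganConfig, build_discriminator,
                           build_generator, generate_volumes, train_cgan)

from conftest import TINY_SHAPE


def tiny_config(**kw):
    base = dict(volume_shape=TINY_SHAPE, cond_dim=5, batch_size=4,
                lr_generator=1e-3, lr_discriminator=5e-4, epochs=3,
                base_channels=4, seed=0)
    base.update(kw)
    return CganConfig(**base)


class TestConfig:
    def test_defaults_match_reference_hyperparameters(self):
        cfg = CganConfig()
        assert cfg.batch_size == 2
        assert cfg.lr_generator == 2.5e-5
        assert cfg.lr_discriminator == 1e-5
        assert cfg.adversarial_loss == "MSE"
        assert cfg.epochs == 1200
        assert cfg.leaky_slope == 0.2

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            CganConfig(lr_generator=0.0)
        with pytest.raises(ValueError):
            CganConfig(epochs=0)
        with pytest.raises(ValueError):
            CganConfig(leaky_slope=1.5)

    def test_indecomposable_shape_lists_admissible(self):
        with pytest.raises(ValueError, match="multiple of 8"):
            CganConfig(volume_shape=(10, 32, 32))


class TestGenerator:
    def test_output_shape_and_tanh_range(self):
        gen = build_generator(tiny_config())
        z = np.random.default_rng(0).standard_normal((3, 5)).astype(np.float32)
        y = gen.forward(z)
        assert y.shape == (3, 1) + TINY_SHAPE
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_eval_forward_deterministic(self):
        gen = build_generator(tiny_config())
        z = np.random.default_rng(1).standard_normal((2, 5)).astype(np.float32)
        assert np.array_equal(gen.forward(z), gen.forward(z))


class TestDiscriminator:
    def test_scores_finite_per_item(self):
        cfg = tiny_config()
        dis = build_discriminator(cfg)
        rng = np.random.default_rng(0)
        vols = rng.standard_normal((4, 1) + TINY_SHAPE).astype(np.float32)
        conds = rng.standard_normal((4, 5)).astype(np.float32)
        s = dis.forward(vols, conds)
        assert s.shape == (4, 1)
        assert np.all(np.isfinite(s))
        # numeric sanity at the extremes of the intensity range
        for fill in (0.0, 1.0):
            s = dis.forward(np.full((2, 1) + TINY_SHAPE, fill, np.float32),
                            np.zeros((2, 5), np.float32))
            assert np.all(np.isfinite(s))

    def test_leaky_slope_honored(self):
        from radiogen import nn
        lrelu = nn.LeakyReLU(0.2)
        assert lrelu.forward(np.array([-1.0]))[0] == pytest.approx(-0.2)
        cfg = tiny_config(leaky_slope=0.3)
        dis = build_discriminator(cfg)
        slopes = [lay.slope for lay in dis.trunk.layers
                  if isinstance(lay, nn.LeakyReLU)]
        assert slopes and all(s == 0.3 for s in slopes)

    def test_volume_shape_mismatch_raises(self):
        dis = build_discriminator(tiny_config())
        with pytest.raises(ValueError):
            dis.forward(np.zeros((1, 1, 8, 8, 8), np.float32),
                        np.zeros((1, 5), np.float32))


class TestTraining:
    def test_same_seed_identical_loss_history(self, tiny_cohort):
        cfg = tiny_config(epochs=3)
        a = train_cgan(tiny_cohort, cfg)
        b = train_cgan(tiny_cohort, cfg)
        assert a.g_losses == b.g_losses
        assert a.d_losses == b.d_losses

    def test_losses_finite_and_nonnegative(self, tiny_cohort):
        ckpt = train_cgan(tiny_cohort, tiny_config(epochs=3))
        assert len(ckpt.g_losses) == 3
        assert all(np.isfinite(v) and v >= 0
                   for v in ckpt.g_losses + ckpt.d_losses)

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train_cgan([], tiny_config())

    def test_checkpoint_roundtrip_bit_identical(self, tiny_cohort, tmp_path):
        ckpt = train_cgan(tiny_cohort, tiny_config(epochs=2))
        path = tmp_path / "gan.ckpt"
        ckpt.save(path)
        back = CganCheckpoint.load(path)
        for key, arr in ckpt.generator_state.items():
            assert np.array_equal(arr, back.generator_state[key])
        lat = np.stack([r.latent for r in tiny_cohort[:3]])
        a = generate_volumes(ckpt, lat)
        b = generate_volumes(back, lat)
        for va, vb in zip(a, b):
            assert va.data.tobytes() == vb.data.tobytes()


@pytest.fixture(scope="module")
def ckpt(tiny_cohort):
    return train_cgan(tiny_cohort, tiny_config(epochs=2))


class TestGenerate:

    def test_one_volume_per_latent_row(self, ckpt):
        lat = np.random.default_rng(0).standard_normal((7, 5))
        vols = generate_volumes(ckpt, lat)
        assert len(vols) == 7
        assert all(v.shape == TINY_SHAPE for v in vols)
        assert all(v.data.min() >= -1.0 and v.data.max() <= 1.0 for v in vols)

    def test_deterministic_without_noise_input(self, ckpt):
        lat = np.random.default_rng(1).standard_normal((3, 5))
        a = generate_volumes(ckpt, lat, seed=0)
        b = generate_volumes(ckpt, lat, seed=99)   # seed moot with noise_dim=0
        for va, vb in zip(a, b):
            assert np.array_equal(va.data, vb.data)

    def test_empty_latents(self, ckpt):
        assert generate_volumes(ckpt, np.zeros((0, 5))) == []

    def test_dimension_mismatch_raises(self, ckpt):
        with pytest.raises(ValueError):
            generate_volumes(ckpt, np.zeros((2, 9)))
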