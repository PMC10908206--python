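"""Volume I/O, resizing, normalization, and reproducible splits/folds."""

import numpy as np
import pytest

from radiogen.volio import (Volume3D, kfold_indices, normalize_intensity,
                            read_volume, resize_volume, split_train_test,
                            write_volume)

from conftest import TINY_SHAPE


@pytest.mark.parametrize("suffix", [".npz", ".nii.gz"])
def test_roundtrip_preserves_data(tmp_path, suffix):
    rng = np.random.default_rng(0)
    vol = Volume3D(rng.random((8, 32, 32)).astype(np.float32))
    path = tmp_path / f"vol{suffix}"
    write_volume(vol, path)
    back = read_volume(path)
    assert back.shape == vol.shape
    assert np.abs(back.data - vol.data).max() <= 1e-6


def test_zero_volume_roundtrip(tmp_path):
    vol = Volume3D(np.zeros((32, 128, 128), dtype=np.float32))
    path = tmp_path / "zeros.npz"
    write_volume(vol, path)
    assert np.all(read_volume(path).data == 0.0)


def test_read_missing_path_names_file(tmp_path):
    missing = tmp_path / "nope.npz"
    with pytest.raises(IOError, match="nope.npz"):
        read_volume(missing)


def test_unsupported_format_rejected(tmp_path):
    with pytest.raises(IOError):
        write_volume(Volume3D(np.zeros((4, 4, 4))), tmp_path / "vol.txt")


class TestResize:
    def test_identity_when_target_equals_shape(self):
        v = Volume3D(np.random.default_rng(0).random((32, 128, 128)))
        out = resize_volume(v, (32, 128, 128))
        assert np.array_equal(out.data, v.data.astype(np.float32))

    def test_downsample_to_working_resolution(self):
        v = Volume3D(np.random.default_rng(1).random((64, 256, 256)))
        assert resize_volume(v).shape == (32, 128, 128)

    def test_constant_volume_stays_constant(self):
        v = Volume3D(np.full((16, 64, 64), 0.7))
        out = resize_volume(v, (8, 32, 32))
        assert np.abs(out.data - 0.7).max() <= 1e-6

    def test_resize_back_recovers_smooth_phantom(self):
        from radiogen.cohort import render_phantom
        v = render_phantom(np.r_[1.0], (16, 32, 32), np.r_[1.0], 0.0, 0)
        small = resize_volume(v, (8, 16, 16))
        back = resize_volume(small, (16, 32, 32))
        lo, hi = v.intensity_range
        assert np.abs(back.data - v.data).mean() < 0.05 * (hi - lo)


class TestNormalize:
    def test_minmax_maps_to_unit_interval(self):
        v = Volume3D(np.array([[[0.0, 5.0, 10.0]]]), intensity_range=(0, 10))
        out = normalize_intensity(v, "minmax")
        assert np.allclose(out.data, [[[0.0, 0.5, 1.0]]])

    def test_tanh_mode_maps_to_symmetric_interval(self):
        v = Volume3D(np.array([[[0.0, 5.0, 10.0]]]), intensity_range=(0, 10))
        out = normalize_intensity(v, "tanh")
        assert np.allclose(out.data, [[[-1.0, 0.0, 1.0]]])

    def test_constant_volume_maps_to_midpoint(self):
        v = Volume3D(np.full((2, 4, 4), 3.3), intensity_range=(0, 10))
        assert np.allclose(normalize_intensity(v, "minmax").data, 0.5)
        assert np.allclose(normalize_intensity(v, "tanh").data, 0.0)


class TestSplit:
    def _records(self, n, prevalence, seed=0):
        rng = np.random.default_rng(seed)
        labels = (rng.random(n) < prevalence).astype(int)
        return [(i, int(lab)) for i, lab in enumerate(labels)]

    def test_reference_cohort_test_size(self):
        recs = [(i, 1 if i < 235 else 0) for i in range(690)]
        train, test = split_train_test(recs, 0.2,
                                       stratify_key=lambda r: r[1], seed=0)
        assert len(test) == 138
        assert len(train) == 552

    def test_stratified_prevalence_within_one_sample(self):
        recs = [(i, 1 if i < 235 else 0) for i in range(690)]
        _, test = split_train_test(recs, 0.2, stratify_key=lambda r: r[1],
                                   seed=1)
        n_pos = sum(lab for _, lab in test)
        expected = 0.2 * 235
        assert abs(n_pos - expected) <= 1.0

    def test_disjoint_exhaustive_and_deterministic(self):
        recs = self._records(97, 0.3)
        a = split_train_test(recs, 0.25, stratify_key=lambda r: r[1], seed=9)
        b = split_train_test(recs, 0.25, stratify_key=lambda r: r[1], seed=9)
        assert a == b
        train, test = a
        assert len(train) + len(test) == 97
        assert set(i for i, _ in train).isdisjoint(i for i, _ in test)

    def test_singleton_stratum_goes_to_train_with_warning(self):
        recs = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 1)]
        with pytest.warns(UserWarning, match="fewer than 2"):
            train, test = split_train_test(recs, 0.4,
                                           stratify_key=lambda r: r[1], seed=0)
        assert (4, 1) in train

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError):
            split_train_test([(0, 0), (1, 1)], 1.5)


class TestKfold:
    def test_reference_58_samples_10_folds(self):
        folds = kfold_indices(58, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [5, 5, 6, 6, 6, 6, 6, 6, 6, 6]

    def test_singleton_folds(self):
        folds = kfold_indices(10, 10, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_partition_property(self):
        folds = kfold_indices(37, 5, seed=3)
        combined = np.concatenate(folds)
        assert sorted(combined.tolist()) == list(range(37))

    def test_deterministic_given_seed(self):
        a = kfold_indices(40, 7, seed=5)
        b = kfold_indices(40, 7, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_n_less_than_k_raises(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 10)
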