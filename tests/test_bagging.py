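"""Pre-processing and bag decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import milenface as mf
from milenface.bagging import DegenerateImageError


def _img(pixels, label=0):
    return mf.EnFaceImage(np.asarray(pixels, dtype=float), bag_label=label)


class TestDenoiseStandardize:
    def test_output_is_standardized(self, rng):
        out = mf.denoise_standardize(_img(rng.random((50, 60))), sigma=1.0)
        assert abs(out.pixels.mean()) < 1e-6
        assert abs(out.pixels.std() - 1.0) < 1e-6

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            mf.denoise_standardize(_img(np.full((10, 10), 3.0)), sigma=1.0)

    def test_idempotent_without_blur(self, rng):
        once = mf.denoise_standardize(_img(rng.random((32, 32))), sigma=1.0)
        twice = mf.denoise_standardize(once, sigma=1.0, blur=False)
        assert np.allclose(once.pixels, twice.pixels, atol=1e-6)

    def test_gaussian_blur_matches_dense_convolution_oracle(self):
        """sigma=1 blur of an impulse equals brute-force truncated-kernel
        convolution with symmetric boundary handling."""
        impulse = np.zeros((7, 7))
        impulse[3, 3] = 1.0
        impulse[0, 2] = 0.5  # exercise the boundary too
        sigma, radius = 1.0, 4  # truncation at 4 sigma
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = np.pad(impulse, radius, mode="symmetric")
        expected = np.zeros_like(impulse)
        for i in range(7):
            for j in range(7):
                expected[i, j] = np.sum(padded[i : i + 9, j : j + 9] * kernel)
        expected = (expected - expected.mean()) / expected.std()
        out = mf.denoise_standardize(_img(impulse), sigma=sigma)
        assert np.allclose(out.pixels, expected, atol=1e-10)


class TestMakeBag:
    def test_clinical_geometry(self):
        """2044x2048 on a 10x10 grid: 100 instances of 204x204, offset (2, 4)."""
        bag = mf.make_bag(_img(np.zeros((2044, 2048))), 10)
        assert len(bag) == 100
        assert bag.instance_shape == (204, 204)
        assert bag.crop_offset == (2, 4)

    def test_exact_division(self, rng):
        bag = mf.make_bag(_img(rng.random((20, 20))), 2)
        assert len(bag) == 4
        assert bag.instance_shape == (10, 10)
        assert bag.crop_offset == (0, 0)

    def test_grid_one_is_identity(self, rng):
        pix = rng.random((13, 17))
        bag = mf.make_bag(_img(pix), 1)
        assert len(bag) == 1
        assert np.array_equal(bag.instances[0], pix)

    def test_oversized_grid_raises(self):
        with pytest.raises(ValueError):
            mf.make_bag(_img(np.zeros((5, 40))), 8)

    def test_row_major_order(self, rng):
        pix = np.arange(16.0).reshape(4, 4)
        bag = mf.make_bag(_img(pix), 2)
        assert bag.instances[1][0, 0] == pix[0, 2]  # second instance: top-right
        assert bag.instances[2][0, 0] == pix[2, 0]  # third: bottom-left


class TestStitch:
    def test_block_matrix_construction(self):
        tiles = [np.full((10, 10), v) for v in (1.0, 2.0, 3.0, 4.0)]
        out, covered = mf.stitch_instances(tiles, 2)
        assert out.shape == (20, 20)
        assert covered.all()
        assert out[0, 0] == 1 and out[0, 19] == 2 and out[19, 0] == 3 and out[19, 19] == 4

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            mf.stitch_instances([np.zeros((4, 4))] * 3, 2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        h=st.integers(8, 40),
        w=st.integers(8, 40),
        g=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    def test_inverse_of_make_bag_on_cropped_region(self, h, w, g, seed):
        if g > min(h, w):
            return
        pix = np.random.default_rng(seed).random((h, w))
        bag = mf.make_bag(_img(pix), g)
        out, covered = mf.stitch_instances(
            bag.instances, g, bag.crop_offset, bag.full_shape, fill_value=-1.0
        )
        assert out.shape == pix.shape
        assert np.array_equal(out[covered], pix[covered])
        assert np.all(out[~covered] == -1.0)
        assert covered.sum() == (h // g) * g * (w // g) * g


class _ForcedRng:
    """Duck-typed rng forcing the rotation count and jitter draws."""

    def __init__(self, k, delta=0.0, gamma=1.0):
        self._k, self._delta, self._gamma = k, delta, gamma
        self._uniform_calls = 0

    def integers(self, lo, hi):
        return self._k

    def uniform(self, lo, hi):
        self._uniform_calls += 1
        return self._delta if self._uniform_calls % 2 == 1 else self._gamma


class TestAugment:
    def test_null_augmentation_is_identity(self, rng):
        inst = rng.standard_normal((8, 8))
        out = mf.augment_instance(inst, _ForcedRng(0), 0.0, 0.0)
        assert np.array_equal(out, inst)

    def test_half_turn_twice_restores_orientation(self, rng):
        inst = rng.standard_normal((8, 8))
        out = mf.augment_instance(
            mf.augment_instance(inst, _ForcedRng(2), 0.0, 0.0), _ForcedRng(2), 0.0, 0.0
        )
        assert np.allclose(out, inst)

    def test_deterministic_under_fixed_seed(self, rng):
        inst = rng.standard_normal((8, 8))
        a = mf.augment_instance(inst, np.random.default_rng(9))
        b = mf.augment_instance(inst, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_jitter_applied_as_affine_map(self, rng):
        inst = rng.standard_normal((8, 8))
        out = mf.augment_instance(inst, _ForcedRng(0, delta=0.25, gamma=1.1), 0.5, 0.5)
        assert np.allclose(out, 1.1 * inst + 0.25)
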