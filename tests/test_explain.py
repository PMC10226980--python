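"""Grad-CAM heatmaps and stitched saliency overlays."""

import numpy as np
import pytest

import milenface as mf
from milenface.explain import explain_bag, grad_cam, lesion_mass
from milenface.nn import Conv2d, Dense, GlobalAvgPool, Network, SeLU


def _one_conv_net(conv_weights, conv_bias, head_weights):
    """conv(1x1) -> GAP -> dense, with hand-set weights."""
    c = len(conv_bias)
    conv = Conv2d(1, c, 1, name="conv")
    conv.params["weight"] = np.asarray(conv_weights, dtype=np.float32).reshape(1, 1, 1, c)
    conv.params["bias"] = np.asarray(conv_bias, dtype=np.float32)
    head = Dense(c, 1, name="head")
    head.params["weight"] = np.asarray(head_weights, dtype=np.float32).reshape(c, 1)
    head.params["bias"] = np.zeros(1, dtype=np.float32)
    return Network([conv, GlobalAvgPool("gap"), head])


class TestGradCam:
    def test_matches_one_layer_analytic_oracle(self, rng):
        """For score = sum_c v_c * mean(A_c) with A_c = w_c*x + b_c, the
        channel weight is v_c / (H*W) and the map is ReLU(sum_c a_c A_c)."""
        w, b, v = [0.7, -0.4], [0.1, 0.0], [1.5, 2.0]
        net = _one_conv_net(w, b, v)
        x = rng.standard_normal((4, 4))
        cam = grad_cam(net, x, target_layer="conv")
        a = [vc / 16.0 for vc in v]
        expected = np.maximum(
            sum(ac * (wc * x + bc) for ac, wc, bc in zip(a, w, b)), 0.0
        )
        assert np.allclose(cam, expected, atol=1e-5)

    def test_all_negative_contributions_clip_to_zero(self):
        net = _one_conv_net([1.0], [5.0], [-1.0])  # A positive, weight negative
        cam = grad_cam(net, np.ones((4, 4)), target_layer="conv")
        assert np.all(cam == 0.0)

    def test_uniform_input_gives_uniform_interior_map(self):
        rng = np.random.default_rng(0)
        conv = Conv2d(1, 3, 3, rng, name="conv")
        net = Network([conv, SeLU(), GlobalAvgPool("gap"), Dense(3, 1, rng, name="head")])
        cam = grad_cam(net, np.full((8, 8), 0.7), target_layer="conv")
        interior = cam[2:-2, 2:-2]
        assert np.ptp(interior) < 1e-4

    def test_layer_without_spatial_extent_rejected(self):
        net = _one_conv_net([1.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="spatial"):
            grad_cam(net, np.ones((4, 4)), target_layer="head")

    def test_default_target_on_instance_classifier(self, rng):
        net = mf.build_instance_classifier(
            mf.InstanceClassifierSpec(2, (2, 2, 3, 3)), 16, seed=0
        )
        cam = grad_cam(net, rng.standard_normal((16, 16)))
        assert cam.shape == (16, 16)
        assert cam.min() >= 0.0


def _brightness_net():
    """A fixed net whose score and feature maps grow with local brightness."""
    conv = Conv2d(1, 2, 3, name="conv")
    conv.params["weight"] = np.full((3, 3, 1, 2), 0.1, dtype=np.float32)
    conv.params["bias"] = np.zeros(2, dtype=np.float32)
    head = Dense(2, 1, name="head")
    head.params["weight"] = np.ones((2, 1), dtype=np.float32)
    head.params["bias"] = np.zeros(1, dtype=np.float32)
    return Network([conv, GlobalAvgPool("gap"), head])


class TestExplainBag:
    def _bag_with_blob(self, cell):
        pixels = np.zeros((32, 32))
        gi, gj = divmod(cell, 2)
        pixels[gi * 16 + 4 : gi * 16 + 12, gj * 16 + 4 : gj * 16 + 12] = 3.0
        return mf.make_bag(mf.EnFaceImage(pixels, bag_label=1), 2)

    def test_identical_instances_identical_maps(self, rng):
        inst = rng.standard_normal((16, 16))
        pixels = np.tile(inst, (2, 2))
        bag = mf.make_bag(mf.EnFaceImage(pixels, bag_label=1), 2)
        sal = explain_bag(_brightness_net(), bag)
        for m in sal.per_instance[1:]:
            assert np.allclose(m, sal.per_instance[0], atol=1e-6)

    def test_joint_normalization_maps_bag_extremes_to_unit_interval(self, rng):
        bag = self._bag_with_blob(0)
        sal = explain_bag(_brightness_net(), bag)
        flat = np.concatenate([m.ravel() for m in sal.normalized])
        assert flat.max() == pytest.approx(1.0)
        assert flat.min() == pytest.approx(0.0)
        raw = np.concatenate([m.ravel() for m in sal.per_instance])
        assert sal.vmin == pytest.approx(raw.min())
        assert sal.vmax == pytest.approx(raw.max())

    @pytest.mark.parametrize("cell", [0, 1, 2, 3])
    def test_translating_lesion_moves_stitched_argmax(self, cell):
        """A bright blob planted in grid cell (i, j) must put the stitched
        map's argmax into that cell."""
        sal = explain_bag(_brightness_net(), self._bag_with_blob(cell))
        r, c = np.unravel_index(np.argmax(sal.stitched), sal.stitched.shape)
        assert (r // 16) * 2 + (c // 16) == cell

    def test_stitched_geometry_matches_bag(self):
        bag = self._bag_with_blob(0)
        sal = explain_bag(_brightness_net(), bag)
        assert sal.stitched.shape == bag.full_shape
        assert sal.coverage.all()


def test_lesion_mass_detects_concentrated_saliency(rng):
    stitched = np.zeros((32, 32))
    mask = np.zeros((32, 32), dtype=bool)
    mask[4:10, 4:10] = True
    stitched[mask] = 1.0
    inside, control = lesion_mass(stitched, mask, rng)
    assert inside == 1.0
    assert control < inside


def test_overlay_and_raw_map_files(tmp_path, rng):
    bag = mf.make_bag(mf.EnFaceImage(rng.random((32, 32)), bag_label=1), 2)
    sal = explain_bag(_brightness_net(), bag)
    from milenface.explain import save_overlay, save_raw_map

    save_overlay(rng.random((32, 32)), sal, tmp_path / "o.png")
    save_raw_map(sal, tmp_path / "m.tif")
    import imageio.v3 as iio
    import tifffile

    assert iio.imread(tmp_path / "o.png").shape == (32, 32, 3)
    assert np.allclose(tifffile.imread(tmp_path / "m.tif"), sal.stitched, atol=1e-6)
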