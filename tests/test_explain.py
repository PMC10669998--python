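"""Grad-CAM heatmaps: contracts, a constructed-network oracle, overlays."""

import numpy as np
import pytest

from octattn.explain import Heatmap, default_target_layer, grad_cam, overlay
from octattn.network import NetworkConfig, StageConfig, build_network
from octattn.nn.layers import Layer, Linear, PointwiseConv


def _net(seed=0):
    cfg = NetworkConfig(
        input_side=16, input_channels=1, stem_filters=4, stem_kernel=2,
        stem_stride=2,
        stages=(StageConfig(4, repeats=1),
                StageConfig(8, repeats=1, followed_by_downsample=False)),
        num_classes=2,
    )
    return build_network(cfg, seed=seed, dtype=np.float64)


class TestGradCam:
    def test_contract_bounds_and_shape(self):
        net = _net()
        x = np.random.default_rng(0).normal(size=(1, 16, 16))
        hm = grad_cam(net, x)
        assert hm.values.shape == (16, 16)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0
        assert hm.target_layer == default_target_layer(net) == "stage2_block1"

    def test_logit_shift_invariance(self):
        """Adding a constant to all logits (via FC biases) leaves the map unchanged."""
        net = _net(seed=1)
        x = np.random.default_rng(1).normal(size=(1, 16, 16))
        hm1 = grad_cam(net, x, target_class=0)
        net.blocks["head"].fc.params["bias"] += 11.0
        hm2 = grad_cam(net, x, target_class=0)
        np.testing.assert_allclose(hm1.values, hm2.values, atol=1e-12)

    def test_auto_selects_argmax_class(self):
        net = _net(seed=2)
        x = np.random.default_rng(2).normal(size=(1, 16, 16))
        probs = net.forward(x[None])
        hm = grad_cam(net, x, target_class="auto")
        assert hm.target_class == int(np.argmax(probs[0]))

    def test_head_is_not_a_valid_target(self):
        net = _net()
        x = np.zeros((1, 16, 16))
        with pytest.raises(ValueError, match="spatial"):
            grad_cam(net, x, target_layer="head")

    def test_left_half_localization_on_constructed_network(self):
        """Oracle: a hand-built one-conv network whose class-0 score sums one
        channel over the left image half must concentrate heatmap mass there.

        The class-0 logit is the sum over the left half of channel 0 of a
        1x1 convolution of the input, so d(score)/d(feature) is the left-half
        indicator on channel 0 and zero on channel 1.  Spatial averaging
        turns that into channel weights (1/2, 0), so symbolically the
        rectified weighted sum is A_0 / 2 — the (positive) feature itself —
        and the normalized heatmap equals the input scaled by its maximum.
        With a bright left half in the input, heatmap mass sits on the left.
        """
        rng = np.random.default_rng(3)

        class HalfSumHead(Layer):
            """FC equivalent of summing channel 0 over the left half."""

            def __init__(self, side):
                super().__init__()
                self.side = side
                self.in_channels = 2
                self.fc = Linear(2, 2, rng, np.float64)

            @property
            def children(self):
                return {"fc": self.fc}

            def forward_logits(self, x, training=False):
                self._x = x
                left = x[:, 0, :, : self.side // 2].sum(axis=(1, 2))
                return np.stack([left, np.zeros_like(left)], axis=1)

            def backward(self, dlogits):
                dx = np.zeros_like(self._x)
                dx[:, 0, :, : self.side // 2] = dlogits[:, 0][:, None, None]
                return dx

        from octattn.network import AttentionGatedNet

        side = 8
        conv = PointwiseConv(1, 2, rng, np.float64)
        conv.params["weight"][:] = [[1.0], [1.0]]
        conv.params["bias"][:] = 0.0

        class ConvBlock(Layer):
            @property
            def children(self):
                return {"conv": conv}

            def forward(self, x, training=False):
                return conv.forward(x, training)

            def backward(self, dy):
                return conv.backward(dy)

        cfg = NetworkConfig(input_side=side, input_channels=1, stem_filters=1,
                            stem_kernel=1, stem_stride=1,
                            stages=(StageConfig(1, repeats=1,
                                                followed_by_downsample=False),),
                            num_classes=2)
        net = AttentionGatedNet.__new__(AttentionGatedNet)
        net.config = cfg
        net.blocks = {"conv": ConvBlock(), "head": HalfSumHead(side)}
        net.dtype = np.float64
        net.input_mean = np.zeros(1)

        x = rng.uniform(0.1, 0.2, size=(1, side, side))  # positive activations
        x[0, :, : side // 2] += 0.7                      # bright left half
        hm = grad_cam(net, x, target_class=0, target_layer="conv")
        left = hm.values[:, : side // 2].mean()
        right = hm.values[:, side // 2:].mean()
        assert left > right
        # symbolic gradient: cam = A_0 / 2 = x / 2, normalized to x / max(x)
        np.testing.assert_allclose(hm.values, x[0] / x[0].max(), atol=1e-9)

    def test_zero_map_stays_zero(self):
        net = _net(seed=4)
        # zero FC weights: d(logit)/d(feature) = 0 -> all-zero rectified map
        net.blocks["head"].fc.params["weight"][:] = 0
        x = np.random.default_rng(4).normal(size=(1, 16, 16))
        hm = grad_cam(net, x, target_class=0)
        np.testing.assert_array_equal(hm.values, 0.0)


class TestOverlay:
    def test_alpha_zero_returns_original(self):
        img = np.random.default_rng(0).random((4, 4))
        hm = Heatmap(values=np.random.default_rng(1).random((4, 4)),
                     target_class=0, target_layer="x")
        out = overlay(hm, img, alpha=0.0)
        np.testing.assert_allclose(out, np.repeat(img[:, :, None], 3, axis=2))

    def test_alpha_one_returns_pure_colormap(self):
        import matplotlib

        img = np.zeros((2, 2))
        vals = np.array([[0.0, 0.5], [0.75, 1.0]])
        hm = Heatmap(values=vals, target_class=0, target_layer="x")
        out = overlay(hm, img, colormap="jet", alpha=1.0)
        expect = matplotlib.colormaps["jet"](vals)[:, :, :3]
        np.testing.assert_allclose(out, expect)

    def test_half_alpha_blend_is_the_average(self):
        import matplotlib

        img = np.full((1, 1), 0.4)
        vals = np.array([[0.3]])
        hm = Heatmap(values=vals, target_class=0, target_layer="x")
        out = overlay(hm, img, colormap="jet", alpha=0.5)
        cmap_px = matplotlib.colormaps["jet"](vals)[0, 0, :3]
        np.testing.assert_allclose(out[0, 0], 0.5 * 0.4 + 0.5 * cmap_px)

    def test_dimension_mismatch_raises(self):
        hm = Heatmap(values=np.zeros((4, 4)), target_class=0, target_layer="x")
        with pytest.raises(ValueError, match="does not match"):
            overlay(hm, np.zeros((5, 5)))


def test_heatmap_validates_range():
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        Heatmap(values=np.array([[2.0]]), target_class=0, target_layer="x")


def test_bipolar_heatmaps_localize_to_the_rnfl_band(surrogate_run):
    """Statistical localization on the synthetic dataset: over >= 20 bipolar
    scans, the trained classifier's Grad-CAM heatmaps put more mean
    activation inside the RNFL band region (the strip of rows the band
    occupies across the curved surface, where the class effect is rendered)
    than outside it.

    Uses the full-scale surrogate experiment's trained network: at 224 px
    the band strip spans several cells of the deepest 7x7 feature map, which
    is the coarsest resolution at which the localization claim is testable.
    """
    from octattn.io import load_images
    from octattn.synthetic import DatasetManifest

    result, _report, out = surrogate_run
    net = result.network
    manifest = DatasetManifest.from_csv(out / "manifest.csv")
    bip_df = manifest.subset(case="left_to_right")
    bip_df = bip_df[bip_df["class"] == "bipolar"].head(24)
    assert len(bip_df) >= 20
    Xb, _, _ = load_images(bip_df, side=224, class_names=["bipolar", "control"])

    # rows [surface_min, surface_max + RNFL thickness]: base 0.22 * side plus
    # parabola (<= 6 px), foveal dip (<= 10 px) and the 14 px band
    side = 224
    top = int(0.22 * side) - 2
    bottom = int(0.22 * side + 6 + 10 + 14) + 2
    inside, outside = [], []
    for i in range(len(Xb)):
        hm = grad_cam(net, Xb[i], target_class=0)
        mask = np.zeros_like(hm.values, dtype=bool)
        mask[top:bottom, :] = True
        inside.append(hm.values[mask].mean())
        outside.append(hm.values[~mask].mean())
    assert np.mean(inside) > np.mean(outside)
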