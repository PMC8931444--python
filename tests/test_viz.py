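import numpy as np
import pytest
from scipy.special import expit

from opus2g.viz import (ColorMap2D, VizParams, enhance_us,
                        local_contrast_norm, power_unsharp, render_dual_band,
                        render_hybrid, render_unmixing, sigmoid_norm)


class TestVizParams:
    def test_defaults_valid(self):
        VizParams()

    @pytest.mark.parametrize("kwargs", [
        dict(a=0.9, b=0.1),
        dict(a=0.0),
        dict(b=1.0),
        dict(Pa=99.0, Pb=1.0),
        dict(r=0),
        dict(gamma=0.0),
        dict(s=0.0),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VizParams(**kwargs)


def lcn_oracle(img, r, n):
    """Per-pixel loop oracle for local contrast normalization."""
    h, w = img.shape
    vals = img[img != 0] if np.any(img) else img
    floor = np.percentile(vals, n)
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            acc, cnt = 0.0, 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if abs(di) + abs(dj) > r:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += img[ii, jj]
                        cnt += 1
            out[i, j] = img[i, j] / max(acc / cnt, floor)
    return out


class TestLocalContrastNorm:
    def test_matches_brute_force_oracle(self, rng):
        img = rng.random((32, 32))
        img[img < 0.2] = 0.0    # exercise the nonzero-percentile path
        out = local_contrast_norm(img, r=3, n=90.0)
        assert np.allclose(out, lcn_oracle(img, 3, 90.0), atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            local_contrast_norm(np.zeros((8, 8)), r=2, n=95.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            local_contrast_norm(np.full((4, 4), -1.0), r=2, n=95.0)

    def test_high_floor_rescales_uniformly(self, rng):
        # with n = 100 the floor is the global max >= any local mean, so the
        # output is img / max(img)
        img = rng.random((16, 16)) + 0.5
        out = local_contrast_norm(img, r=2, n=100.0,
                                  nonzero_percentiles=False)
        assert np.allclose(out, img / img.max())


class TestSigmoidNorm:
    def test_percentile_fixed_points(self, rng):
        img = rng.random((64, 64))
        Pa, Pb, a, b = 5.0, 95.0, 0.05, 0.95
        va = np.percentile(img, Pa)
        vb = np.percentile(img, Pb)
        out = sigmoid_norm(img, Pa, Pb, a, b, nonzero_percentiles=False)
        # pixels at exactly the percentile values map to a and b
        i = np.unravel_index(np.argmin(np.abs(img - va)), img.shape)
        assert out[i] == pytest.approx(a, abs=0.01)
        j = np.unravel_index(np.argmin(np.abs(img - vb)), img.shape)
        assert out[j] == pytest.approx(b, abs=0.01)

    def test_matches_elementwise_oracle(self, rng):
        from scipy.special import logit
        img = rng.standard_normal((32, 32))
        Pa, Pb, a, b = 2.0, 98.0, 0.1, 0.9
        va, vb = np.percentile(img, Pa), np.percentile(img, Pb)
        la, lb = logit(a), logit(b)
        oracle = expit((lb - la) * (img - va) / (vb - va) + la)
        out = sigmoid_norm(img, Pa, Pb, a, b, nonzero_percentiles=False)
        assert np.allclose(out, oracle, atol=1e-12)

    def test_output_in_unit_interval_and_monotone(self, rng):
        img = 100.0 * rng.standard_normal((32, 32))
        out = sigmoid_norm(img, 2.0, 98.0, 0.05, 0.95,
                           nonzero_percentiles=False)
        assert out.min() > 0 and out.max() < 1
        order = np.argsort(img.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= 0)

    def test_degenerate_percentiles_rejected(self):
        with pytest.raises(ValueError, match="percentile"):
            sigmoid_norm(np.ones((4, 4)), 2.0, 98.0, 0.05, 0.95,
                         nonzero_percentiles=False)


class TestPowerUnsharp:
    def test_identity_when_neutral(self, rng):
        img = rng.random((16, 16))
        assert np.allclose(power_unsharp(img, 1.0, 0.0, 2.0), img)

    def test_constant_image_unchanged_by_unsharp(self):
        img = np.full((16, 16), 0.7)
        out = power_unsharp(img, 1.0, 2.0, 2.0)
        assert np.allclose(out, img, atol=1e-12)

    def test_gamma_is_power_law(self, rng):
        img = rng.random((8, 8))
        assert np.allclose(power_unsharp(img, 0.5, 0.0, 2.0), np.sqrt(img))

    def test_unsharp_overshoots_step_edge(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        out = power_unsharp(img, 1.0, 1.0, 2.0)
        assert out.max() > 1.0 and out.min() < 0.0    # classic halo

    def test_invalid_rejected(self, rng):
        with pytest.raises(ValueError, match="gamma"):
            power_unsharp(np.ones((4, 4)), 0.0, 0.0, 2.0)
        with pytest.raises(ValueError, match="non-negative"):
            power_unsharp(-np.ones((4, 4)), 0.5, 0.0, 2.0)


class TestEnhanceUS:
    def test_reference_values(self):
        # at the surface, I = 0.9 maps to sigma(0) = 0.5; at 2 cm depth the
        # depth gain multiplies by exp(0.3)
        img = np.full((40, 4), 0.9)
        out = enhance_us(img, skin_row=10, pixel_pitch_mm=1.0)
        assert out[10, 0] == pytest.approx(0.5, abs=1e-12)
        assert out[30, 0] == pytest.approx(np.exp(0.3) * 0.5, abs=1e-12)

    def test_no_gain_above_skin(self):
        img = np.full((20, 3), 0.5)
        out = enhance_us(img, skin_row=10, pixel_pitch_mm=1.0)
        assert np.allclose(out[:11], expit((0.5 - 0.9) / 0.2))

    def test_per_column_skin_line(self):
        img = np.full((20, 2), 0.9)
        out = enhance_us(img, skin_row=np.array([0.0, 10.0]),
                         pixel_pitch_mm=1.0)
        assert out[10, 0] == pytest.approx(np.exp(0.15) * 0.5)
        assert out[10, 1] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            enhance_us(np.full((4, 4), 1.5), 0, 1.0)


class TestColorMap2D:
    def test_corner_colors(self):
        cmap = ColorMap2D()
        assert np.allclose(cmap(0.0, 0.0), [0, 0, 0])
        assert np.allclose(cmap(0.0, 1.0), [1, 1, 0])
        assert np.allclose(cmap(1.0, 0.0), [1, 0, 0])
        assert np.allclose(cmap(1.0, 1.0), [1, 1, 1])

    def test_center_is_mean_of_corners(self):
        cmap = ColorMap2D()
        expected = cmap.corner_colors.reshape(4, 3).mean(axis=0)
        assert np.allclose(cmap(0.5, 0.5), expected)

    def test_bilinear_in_each_argument(self, rng):
        cmap = ColorMap2D()
        l, h = 0.3, 0.7
        left = cmap(0.0, h)
        right = cmap(1.0, h)
        assert np.allclose(cmap(l, h), (1 - l) * left + l * right)

    def test_output_range_and_clipping(self, rng):
        cmap = ColorMap2D()
        out = cmap(rng.uniform(-1, 2, (8, 8)), rng.uniform(-1, 2, (8, 8)))
        assert out.shape == (8, 8, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_corners_rejected(self):
        with pytest.raises(ValueError, match="corner"):
            ColorMap2D(np.ones((2, 2)))
        with pytest.raises(ValueError, match="corner"):
            ColorMap2D(2.0 * np.ones((2, 2, 3)))


class TestRenderers:
    def test_dual_band_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            render_dual_band(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_dual_band_uses_colormap(self, rng):
        low, high = rng.random((6, 6)), rng.random((6, 6))
        assert np.allclose(render_dual_band(low, high),
                           ColorMap2D()(low, high))

    def test_unmixing_channel_routing(self):
        z = np.zeros((3, 3))
        one = np.ones((3, 3))
        rgb = render_unmixing({"HbO2": one, "Hb": z, "fat": z, "water": z})
        assert np.allclose(rgb[..., 0], 1) and not rgb[..., 1:].any()
        rgb = render_unmixing({"HbO2": z, "Hb": one, "fat": z, "water": z})
        assert np.allclose(rgb[..., 2], 1) and not rgb[..., :2].any()
        rgb = render_unmixing({"HbO2": z, "Hb": z, "fat": one, "water": z})
        assert np.allclose(rgb[..., 1], 1)
        # water is dropped from the display
        rgb = render_unmixing({"HbO2": z, "Hb": z, "fat": z, "water": one})
        assert not rgb.any()

    def test_unmixing_normalization(self, rng):
        z = np.zeros((3, 3))
        r = 5.0 * rng.random((3, 3)) + 1.0
        rgb = render_unmixing({"HbO2": r, "Hb": z, "fat": z, "water": z})
        assert rgb.max() == pytest.approx(1.0)
        rgb2 = render_unmixing({"HbO2": r, "Hb": z, "fat": z, "water": z},
                               normalize=False)
        assert rgb2.max() == pytest.approx(1.0)   # clipped, not scaled
        assert not np.allclose(rgb, rgb2)

    def test_hybrid_zero_oa_is_grayscale_us(self, rng):
        us = rng.random((8, 8))
        out = render_hybrid(np.zeros((8, 8)), us)
        for c in range(3):
            assert np.allclose(out[..., c], us)

    def test_hybrid_full_oa_is_hue(self):
        out = render_hybrid(np.ones((4, 4)), np.zeros((4, 4)),
                            oa_color=(1.0, 0.2, 0.0))
        assert np.allclose(out, np.broadcast_to([1.0, 0.2, 0.0], (4, 4, 3)))

    def test_hybrid_mask_boundary_contour(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        out = render_hybrid(np.zeros((16, 16)), np.zeros((16, 16)), mask=mask,
                            contour_color=(1.0, 1.0, 1.0))
        # boundary painted white, interior left untinted (black here)
        assert np.allclose(out[4, 4:12], 1.0)
        assert np.allclose(out[8, 8], 0.0)
        assert np.allclose(out[0, 0], 0.0)

    def test_hybrid_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            render_hybrid(np.zeros((4, 4)), np.zeros((5, 5)))
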