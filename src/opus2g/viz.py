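"""Display transforms and renderers.

Optoacoustic intensity decays strongly with depth, so raw reconstructions span
several orders of magnitude.  The display chain normalizes them with:

* local contrast normalization — divide each pixel by the larger of its
  L1-ball neighborhood mean and a global percentile floor;
* sigmoid normalization — a logistic map sending the [Pa, Pb] percentile
  range to [a, b] in (0, 1), squeezing outliers into the unit interval;
* power-law and unsharp masking for fine-detail emphasis;
* depth-gain + sigmoid contrast enhancement for ultrasound.

Renderers: dual-band fusion of a low-LCO and a high-LCO reconstruction through
a bilinear 2-D colormap; RGB chromophore display (HbO2 red, Hb blue, fat
green, water dropped); hybrid overlay of OA signal on grayscale US with an
optional tumor contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit, logit

__all__ = ["VizParams", "ColorMap2D", "local_contrast_norm", "sigmoid_norm",
           "power_unsharp", "enhance_us", "render_dual_band",
           "render_unmixing", "render_hybrid"]


@dataclass(frozen=True)
class VizParams:
    """Manual per-image display parameters.

    r: LCN neighborhood radius (px); n: LCN percentile floor; Pa/Pb and a/b:
    sigmoid source percentiles and target levels; gamma: power-law exponent;
    alpha_um / s: unsharp weight and Gaussian scale (px).
    """

    r: int = 8
    n: float = 95.0
    a: float = 0.05
    b: float = 0.95
    Pa: float = 2.0
    Pb: float = 99.5
    gamma: float = 1.0
    alpha_um: float = 0.0
    s: float = 2.0
    nonzero_percentiles: bool = True

    def __post_init__(self):
        if not (0 < self.a < self.b < 1):
            raise ValueError("need 0 < a < b < 1")
        if not (self.Pa < self.Pb):
            raise ValueError("need Pa < Pb")
        if self.r < 1 or self.gamma <= 0 or self.s <= 0:
            raise ValueError("need r >= 1, gamma > 0, s > 0")


def _percentile(image: np.ndarray, q: float, nonzero: bool) -> float:
    """Percentile over the image, optionally restricted to nonzero pixels.

    OA images are background-dominated; computing display percentiles over
    nonzero pixels only keeps the mapping sensitive to the signal.
    """
    vals = image[image != 0] if nonzero and np.any(image) else image
    return float(np.percentile(vals, q))


def _l1_ball_footprint(r: int) -> np.ndarray:
    idx = np.arange(-r, r + 1)
    return (np.abs(idx[:, None]) + np.abs(idx[None, :])) <= r


def local_contrast_norm(image: np.ndarray, r: int, n: float,
                        nonzero_percentiles: bool = True) -> np.ndarray:
    """I(x) / max(mean over the L1-ball neighborhood of x, n-th percentile).

    The neighborhood is clipped at the image border (the mean runs over the
    in-domain pixels only).  All-zero images have a zero divisor everywhere
    and are rejected.
    """
    img = np.asarray(image, dtype=float)
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    if not np.any(img):
        raise ValueError("all-zero image: zero divisor")
    foot = _l1_ball_footprint(int(r)).astype(float)
    local_sum = ndimage.correlate(img, foot, mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones_like(img), foot, mode="constant",
                               cval=0.0)
    local_mean = local_sum / counts
    floor = _percentile(img, n, nonzero_percentiles)
    return img / np.maximum(local_mean, floor)


def sigmoid_norm(image: np.ndarray, Pa: float, Pb: float, a: float, b: float,
                 nonzero_percentiles: bool = True) -> np.ndarray:
    """Logistic map sending the [Pa, Pb] percentile range to [a, b].

    I -> sigma( (sigma^-1(b) - sigma^-1(a)) (I - P_a)/(P_b - P_a)
                + sigma^-1(a) )
    where P_a, P_b are the percentile *values* of the image.  Monotone; output
    strictly inside (0, 1).
    """
    img = np.asarray(image, dtype=float)
    va = _percentile(img, Pa, nonzero_percentiles)
    vb = _percentile(img, Pb, nonzero_percentiles)
    if not vb > va:
        raise ValueError("degenerate percentiles: Pa and Pb values coincide")
    la, lb = logit(a), logit(b)
    return expit((lb - la) * (img - va) / (vb - va) + la)


def power_unsharp(image: np.ndarray, gamma: float, alpha_um: float,
                  s: float) -> np.ndarray:
    """Power-law I^gamma followed by unsharp masking I + alpha (I - G_s * I)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    img = np.asarray(image, dtype=float)
    if np.any(img < 0):
        raise ValueError("image must be non-negative for the power law")
    out = img ** gamma
    if alpha_um != 0.0:
        blurred = ndimage.gaussian_filter(out, s)
        out = out + alpha_um * (out - blurred)
    return out


def enhance_us(us: np.ndarray, skin_row, pixel_pitch_mm: float) -> np.ndarray:
    """Depth-gain and contrast enhancement for a [0, 1] ultrasound image.

    I_enh(x) = exp(0.15 d) * sigma((I(x) - 0.9) / 0.2), with d the depth of
    the pixel below the tissue surface in centimetres (clamped to 0 above the
    surface).
    """
    img = np.asarray(us, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("US image must be normalized to [0, 1]")
    h, w = img.shape
    skin = np.broadcast_to(np.asarray(skin_row), (w,)).astype(float)
    rows = np.arange(h)[:, None]
    depth_cm = np.maximum(rows - skin[None, :], 0.0) * pixel_pitch_mm / 10.0
    return np.exp(0.15 * depth_cm) * expit((img - 0.9) / 0.2)


@dataclass(frozen=True)
class ColorMap2D:
    """Bilinear 2-D colormap over (low-band, high-band) in [0,1]^2.

    ``corner_colors[i, j]`` is the RGB at low = i, high = j.  The default
    renders large low-frequency structures red, fine high-frequency detail
    yellow, and joint maxima white.
    """

    corner_colors: np.ndarray = field(
        default_factory=lambda: np.array(
            [[[0.0, 0.0, 0.0],    # low 0, high 0: black
              [1.0, 1.0, 0.0]],   # low 0, high 1: yellow
             [[1.0, 0.0, 0.0],    # low 1, high 0: red
              [1.0, 1.0, 1.0]]])) # low 1, high 1: white

    def __post_init__(self):
        c = np.asarray(self.corner_colors, dtype=float)
        if c.shape != (2, 2, 3) or c.min() < 0 or c.max() > 1:
            raise ValueError("corner_colors must be (2,2,3) RGB in [0,1]")
        object.__setattr__(self, "corner_colors", c)

    def __call__(self, low: np.ndarray, high: np.ndarray) -> np.ndarray:
        l = np.clip(np.asarray(low, float), 0, 1)[..., None]
        h = np.clip(np.asarray(high, float), 0, 1)[..., None]
        c = self.corner_colors
        rgb = ((1 - l) * (1 - h) * c[0, 0] + (1 - l) * h * c[0, 1]
               + l * (1 - h) * c[1, 0] + l * h * c[1, 1])
        return np.clip(rgb, 0.0, 1.0)


def render_dual_band(low: np.ndarray, high: np.ndarray,
                     cmap: ColorMap2D | None = None) -> np.ndarray:
    """Fuse a low-LCO and a high-LCO image (both in [0,1]) into RGB."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if low.shape != high.shape:
        raise ValueError("band images must share shape")
    return (cmap or ColorMap2D())(low, high)


def render_unmixing(coeffs, normalize: bool = True) -> np.ndarray:
    """Chromophore RGB: HbO2 -> red, Hb -> blue, fat -> green; water dropped."""
    r = np.asarray(coeffs["HbO2"], dtype=float)
    b = np.asarray(coeffs["Hb"], dtype=float)
    g = np.asarray(coeffs["fat"], dtype=float)
    rgb = np.stack([r, g, b], axis=-1)
    if normalize and rgb.max() > 0:
        rgb = rgb / rgb.max()
    return np.clip(rgb, 0.0, 1.0)


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    return m & ~ndimage.binary_erosion(m)


def render_hybrid(oa: np.ndarray, us: np.ndarray, mask=None,
                  oa_color=(1.0, 0.0, 0.0),
                  contour_color=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Overlay OA signal (single hue, alpha = intensity) on grayscale US.

    ``oa`` and ``us`` must be in [0, 1].  If a tumor-core mask is given, its
    boundary is drawn in ``contour_color``; the interior is left untinted.
    """
    oa = np.asarray(oa, dtype=float)
    us = np.asarray(us, dtype=float)
    if oa.shape != us.shape:
        raise ValueError("OA and US must share shape")
    alpha = np.clip(oa, 0.0, 1.0)[..., None]
    base = np.repeat(np.clip(us, 0.0, 1.0)[..., None], 3, axis=-1)
    hue = np.asarray(oa_color, dtype=float)
    out = (1.0 - alpha) * base + alpha * hue
    if mask is not None:
        out[_mask_boundary(mask)] = np.asarray(contour_color, dtype=float)
    return np.clip(out, 0.0, 1.0)
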