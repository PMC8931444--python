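"""Image-quality metrics: contrast-to-noise ratio and FWHM resolution.

CNR compares the tissue band under the skin (object) with the signal-free
area above the skin (background):

    CNR = 10 log10[ (mu_OBJ - mu_BKG) / (sigma_OBJ + sigma_BKG) ]

where, following the source convention of this pipeline, sigma denotes the
*variance* of the region.  A ``denominator="std"`` switch provides the more
common standard-deviation form.  FWHM of a line profile across a small vessel
is the standard resolution proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegionMasks", "CNRReport", "compute_cnr", "fwhm"]


@dataclass
class RegionMasks:
    """Object/background masks for CNR.

    The object is the tissue from the skin line down to ``max_depth_mm``
    (1.5 cm) below it; the background is the area above the skin line.
    """

    object_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self):
        om = np.asarray(self.object_mask, dtype=bool)
        bm = np.asarray(self.background_mask, dtype=bool)
        if om.shape != bm.shape:
            raise ValueError("masks must share shape")
        if np.any(om & bm):
            raise ValueError("object and background masks overlap")
        if not om.any() or not bm.any():
            raise ValueError("both masks must be non-empty")
        self.object_mask = om
        self.background_mask = bm

    @classmethod
    def from_skin_line(cls, shape, skin_row, pixel_pitch_mm: float,
                       max_depth_mm: float = 15.0) -> "RegionMasks":
        """Build masks from a per-column skin row index (or a scalar)."""
        h, w = shape
        skin = np.broadcast_to(np.asarray(skin_row), (w,)).astype(float)
        rows = np.arange(h)[:, None]
        depth_px = max_depth_mm / pixel_pitch_mm
        obj = (rows >= skin[None, :]) & (rows <= skin[None, :] + depth_px)
        bkg = rows < skin[None, :]
        return cls(obj, bkg)


@dataclass
class CNRReport:
    cnr_db: float
    mu_obj: float
    mu_bkg: float
    var_obj: float
    var_bkg: float
    denominator: str = "variance"
    flagged: bool = False           # numerator <= 0: CNR undefined
    variant: tuple | None = None


def compute_cnr(image: np.ndarray, masks: RegionMasks,
                denominator: str = "variance",
                variant: tuple | None = None) -> CNRReport:
    """Contrast-to-noise ratio of an image given object/background masks.

    A non-positive contrast (mu_OBJ <= mu_BKG) yields a flagged report with
    ``cnr_db = nan`` rather than an exception, so batch statistics can skip
    undefined entries.  A zero denominator is rejected.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if denominator not in ("variance", "std"):
        raise ValueError("denominator must be 'variance' or 'std'")

    obj = img[masks.object_mask]
    bkg = img[masks.background_mask]
    mu_o, mu_b = float(obj.mean()), float(bkg.mean())
    var_o, var_b = float(obj.var()), float(bkg.var())
    denom = (var_o + var_b) if denominator == "variance" \
        else (np.sqrt(var_o) + np.sqrt(var_b))
    if denom == 0:
        raise ValueError("zero denominator: regions have no variance")

    numer = mu_o - mu_b
    if numer <= 0:
        return CNRReport(float("nan"), mu_o, mu_b, var_o, var_b,
                         denominator, flagged=True, variant=variant)
    return CNRReport(10.0 * np.log10(numer / denom), mu_o, mu_b,
                     var_o, var_b, denominator, flagged=False,
                     variant=variant)


def fwhm(profile: np.ndarray, pitch_um: float) -> float:
    """Full width at half maximum of a 1-D line profile, in micrometres.

    The half-maximum crossings flanking the (unique) global peak are located
    by linear interpolation.  Profiles whose peak touches the boundary, or
    that never fall to half maximum on either side, are rejected.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be 1-D with >= 3 samples")
    i_max = int(np.argmax(p))
    if i_max in (0, p.size - 1):
        raise ValueError("profile peak lies on the boundary")
    peak = p[i_max]
    if peak <= max(p[0], p[-1]):
        raise ValueError("no unique global maximum above the boundary values")
    # half maximum relative to the profile baseline, so the width is
    # invariant under positive affine intensity rescaling
    base = float(p.min())
    half = base + 0.5 * (peak - base)

    # walk left
    left = None
    for i in range(i_max, 0, -1):
        if p[i - 1] <= half <= p[i]:
            frac = (p[i] - half) / (p[i] - p[i - 1])
            left = i - frac
            break
    # walk right
    right = None
    for i in range(i_max, p.size - 1):
        if p[i + 1] <= half <= p[i]:
            frac = (p[i] - half) / (p[i] - p[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        raise ValueError("profile does not fall to half maximum on both sides")
    return float((right - left) * pitch_um)
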