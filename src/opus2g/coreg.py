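"""OA/US co-registration.

The scanner beamforms ultrasound images under a homogeneous speed-of-sound
assumption, so they are spatially distorted relative to the dual-SoS
optoacoustic reconstructions.  The distortion is estimated as the affine
transform between two OA reconstructions of the *same* signals — one with the
dual-SoS model, one with the uniform model — and then applied to the US
images.  US frames recorded concurrently with an averaged multispectral OA
frame are averaged to raise their SNR.

Affine transforms use the resampling convention in (row, col) = (y, x) pixel
coordinates: ``warp(img, T)(x) = img(A x + t)``.  ``estimate_affine`` returns
the transform that resamples the uniform-SoS image (and hence the US image)
into the dual-SoS frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = ["AffineTransform", "USImage", "estimate_affine", "warp_us",
           "average_concurrent_us"]

log = logging.getLogger(__name__)

_PERM = np.array([[0.0, 1.0], [1.0, 0.0]])  # swap (x, y) <-> (y, x)


@dataclass
class AffineTransform:
    """2x3 matrix [A | t] acting on (y, x) pixel coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("linear part is singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform(np.hstack([Ainv,
                                          (-Ainv @ self.translation)[:, None]]))

    def deviation_from_identity(self) -> float:
        """Frobenius norm of [A - I | t]."""
        d = self.matrix - np.hstack([np.eye(2), np.zeros((2, 1))])
        return float(np.linalg.norm(d))


@dataclass
class USImage:
    """Grayscale pulse-echo ultrasound frame with its acquisition time."""

    pixels: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("US pixels must be finite")
        self.pixels = p


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def estimate_affine(oa_dual: np.ndarray, oa_single: np.ndarray,
                    iterations: int = 500) -> AffineTransform:
    """Affine mapping the dual-SoS frame onto the uniform-SoS image.

    Maximizes normalized cross-correlation with a multi-resolution
    regular-step gradient descent, initialized at the identity
    (deterministic: dense sampling, no randomness).  If the optimized
    transform does not improve the similarity over the identity, the
    identity is returned with a warning.
    """
    fixed = np.asarray(oa_dual, dtype=float)
    moving = np.asarray(oa_single, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("images must share shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("constant image: affine estimation undefined")

    f = sitk.GetImageFromArray(fixed)
    m = sitk.GetImageFromArray(moving)
    tx = sitk.CenteredTransformInitializer(
        f, m, sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-6, numberOfIterations=iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2, 1, 0])
    reg.Execute(f, m)

    # sitk acts on (x, y) physical points around a center:
    # p_mov = A (p_fix - c) + c + t; convert to (y, x) with a plain offset.
    A_xy = np.array(tx.GetMatrix()).reshape(2, 2)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    off_xy = c - A_xy @ c + t
    A_yx = _PERM @ A_xy @ _PERM
    off_yx = _PERM @ off_xy
    candidate = AffineTransform(np.hstack([A_yx, off_yx[:, None]]))

    # accept only if the similarity improved over the identity
    warped = warp_us(USImage(moving), candidate).pixels
    if _ncc(warped, fixed) <= _ncc(moving, fixed):
        log.warning("affine estimation did not improve over identity; "
                    "returning identity")
        return AffineTransform.identity()
    return candidate


def warp_us(us: USImage, affine: AffineTransform) -> USImage:
    """Resample a US image into the dual-SoS OA frame.

    The identity transform returns the input unchanged (no interpolation).
    """
    if affine.deviation_from_identity() == 0.0:
        return USImage(us.pixels.copy(), us.timestamp)
    warped = ndimage.affine_transform(us.pixels, affine.linear,
                                      offset=affine.translation,
                                      order=1, mode="nearest")
    return USImage(warped, us.timestamp)


def average_concurrent_us(us_sequence, window: tuple) -> USImage:
    """Average the US frames whose timestamps fall in the closed window.

    ``window`` is (t_start, t_end) in seconds — the timeframe of one
    multispectral OA frame (1.1 s on this scanner).
    """
    t0, t1 = window
    selected = [u for u in us_sequence if t0 <= u.timestamp <= t1]
    if not selected:
        raise ValueError(f"no US frames inside the window [{t0}, {t1}] s")
    shapes = {u.pixels.shape for u in selected}
    if len(shapes) != 1:
        raise ValueError("selected US frames differ in shape")
    mean = np.mean([u.pixels for u in selected], axis=0)
    return USImage(mean, float(np.mean([u.timestamp for u in selected])))
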