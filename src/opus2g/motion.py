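"""Elastic motion correction and frame compounding.

Consecutive multispectral frames are blurred by tissue/probe motion; to
compound them without losing resolution the pipeline estimates two levels of
smooth displacement fields:

* T1 (intra-frame): each single-wavelength image in a frame is registered to
  that frame's 800 nm image.  Images above 890 nm look spectrally different
  (fat dominates) and cannot be registered reliably; they reuse the 890 nm
  field.
* T2 (inter-frame): per-frame mean images (over 700-890 nm, T1-warped) are
  registered to the middle frame's mean.

The final image at each wavelength is the average over frames of the
T2∘T1-warped images.

Registration maximizes the ANTs local (neighborhood) cross-correlation by
gradient flow on a dense displacement field: at each iteration the analytic
derivative of the windowed correlation with respect to the warped image drives
a force field, which is Gaussian-smoothed and added to the displacement.  The
scheme runs sequentially at quarter, half and full resolution, each level
initializing the next.  It is fully deterministic.

Displacement fields use the resampling convention: ``warped(x) = image(x + d(x))``
with ``d`` stored as ``(..., 2)`` arrays of (dy, dx) in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter, zoom

from .spectral import MultispectralFrame

__all__ = ["DisplacementField", "RegistrationParams", "register_elastic",
           "warp_image", "compose_fields", "correct_and_average"]


@dataclass(frozen=True)
class RegistrationParams:
    """Hyperparameters of the elastic registration.

    ``window_radius`` is the half-width of the local correlation window (px);
    ``sigma_update``/``sigma_field`` smooth the per-iteration update and the
    accumulated field; ``step_px`` caps the largest per-iteration displacement
    update; ``shrink_factors`` define the coarse-to-fine schedule.
    """

    window_radius: int = 4
    iterations: int = 50
    step_px: float = 1.0
    sigma_update: float = 2.0
    sigma_field: float = 0.5
    shrink_factors: tuple = (4, 2, 1)


@dataclass
class DisplacementField:
    """Dense displacement field, (H, W, 2) of (dy, dx) in pixels."""

    vectors: np.ndarray
    smoothness_scale: float = 2.0

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 3 or v.shape[-1] != 2:
            raise ValueError("vectors must be (H, W, 2)")
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement field must be finite")
        self.vectors = v

    @classmethod
    def zero(cls, shape) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (2,)))

    @property
    def shape(self):
        return self.vectors.shape[:2]

    @property
    def is_zero(self) -> bool:
        return not np.any(self.vectors)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


def warp_image(image: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Resample ``image`` at x + d(x) (linear interpolation, border replication).

    An exactly-zero field returns an untouched copy, so motion-free inputs
    pass through bit-exactly.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != field.shape:
        raise ValueError("image and field shapes differ")
    if field.is_zero:
        return image.copy()
    yy, xx = np.mgrid[0:image.shape[0], 0:image.shape[1]].astype(float)
    return map_coordinates(image,
                           [yy + field.vectors[..., 0],
                            xx + field.vectors[..., 1]],
                           order=1, mode="nearest")


def compose_fields(outer: DisplacementField,
                   inner: DisplacementField) -> DisplacementField:
    """Field of applying ``inner`` then ``outer`` as resampling warps.

    warp(warp(I, inner), outer)(x) = I(x + d(x)) with
    d(x) = outer(x) + inner(x + outer(x)).
    """
    if outer.shape != inner.shape:
        raise ValueError("fields must share shape")
    if outer.is_zero:
        return DisplacementField(inner.vectors.copy(),
                                 inner.smoothness_scale)
    yy, xx = np.mgrid[0:outer.shape[0], 0:outer.shape[1]].astype(float)
    ys = yy + outer.vectors[..., 0]
    xs = xx + outer.vectors[..., 1]
    inner_dy = map_coordinates(inner.vectors[..., 0], [ys, xs],
                               order=1, mode="nearest")
    inner_dx = map_coordinates(inner.vectors[..., 1], [ys, xs],
                               order=1, mode="nearest")
    combined = outer.vectors + np.stack([inner_dy, inner_dx], axis=-1)
    return DisplacementField(combined, outer.smoothness_scale)


def _local_cc_force(fixed: np.ndarray, warped: np.ndarray,
                    radius: int) -> np.ndarray:
    """Gradient of the windowed (ANTs) cross-correlation wrt the displacement.

    With window means removed, CC = A^2 / (B C) where A = <Ib, Jb>,
    B = <Ib, Ib>, C = <Jb, Jb> over the window; its derivative with respect to
    the warped image J at the window centre is 2A/(BC) (Ib - (A/C) Jb), which
    is chained with the spatial gradient of J.
    """
    size = 2 * radius + 1
    mu_f = uniform_filter(fixed, size)
    mu_w = uniform_filter(warped, size)
    ib = fixed - mu_f
    jb = warped - mu_w
    n = size * size
    A = uniform_filter(ib * jb, size) * n
    B = uniform_filter(ib * ib, size) * n
    C = uniform_filter(jb * jb, size) * n
    eps = 1e-12 * max(float(fixed.std()) ** 2, np.finfo(float).tiny)
    coef = 2.0 * A / (B * C + eps) * (ib - (A / (C + eps)) * jb)
    gy, gx = np.gradient(warped)
    return coef[..., None] * np.stack([gy, gx], axis=-1)


def _register_level(fixed, moving, vectors, params: RegistrationParams):
    for _ in range(params.iterations):
        fld = DisplacementField(vectors)
        warped = warp_image(moving, fld) if not fld.is_zero else moving.copy()
        force = _local_cc_force(fixed, warped, params.window_radius)
        force[..., 0] = gaussian_filter(force[..., 0], params.sigma_update)
        force[..., 1] = gaussian_filter(force[..., 1], params.sigma_update)
        peak = np.max(np.hypot(force[..., 0], force[..., 1]))
        if peak < 1e-30:
            break
        vectors = vectors + (params.step_px / peak) * force
        if params.sigma_field > 0:
            vectors[..., 0] = gaussian_filter(vectors[..., 0],
                                              params.sigma_field)
            vectors[..., 1] = gaussian_filter(vectors[..., 1],
                                              params.sigma_field)
    return vectors


def register_elastic(moving: np.ndarray, fixed: np.ndarray,
                     params: RegistrationParams | None = None
                     ) -> DisplacementField:
    """Estimate a smooth displacement field aligning ``moving`` onto ``fixed``.

    Identical inputs short-circuit to the zero field.  A constant fixed image
    has zero local variance everywhere and is rejected.
    """
    params = params or RegistrationParams()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("moving and fixed must share shape")
    if fixed.std() == 0:
        raise ValueError("fixed image is constant: nothing to register to")
    if np.array_equal(moving, fixed):
        return DisplacementField.zero(fixed.shape)

    vectors = None
    for shrink in params.shrink_factors:
        if shrink > 1:
            f = zoom(gaussian_filter(fixed, shrink / 2.0), 1.0 / shrink,
                     order=1)
            m = zoom(gaussian_filter(moving, shrink / 2.0), 1.0 / shrink,
                     order=1)
        else:
            f, m = fixed, moving
        if vectors is None:
            vectors = np.zeros(f.shape + (2,))
        elif vectors.shape[:2] != f.shape:
            zf = (f.shape[0] / vectors.shape[0],
                  f.shape[1] / vectors.shape[1])
            vectors = np.stack(
                [zoom(vectors[..., 0], zf, order=1) * zf[0],
                 zoom(vectors[..., 1], zf, order=1) * zf[1]], axis=-1)
        vectors = _register_level(f, m, vectors, params)
    return DisplacementField(vectors, params.sigma_update)


def correct_and_average(frames, reference_wavelength: int = 800,
                        t1_band: tuple = (700, 890),
                        params: RegistrationParams | None = None,
                        return_fields: bool = False):
    """Motion-correct and average consecutive multispectral frames.

    Within each frame, images in ``t1_band`` are registered to the frame's
    ``reference_wavelength`` image (T1); wavelengths above the band reuse the
    field of the band's top wavelength.  Per-frame mean images over the band
    are registered to the middle frame's mean (T2).  The output at each
    wavelength is the mean over frames of the T2∘T1-warped images.

    With ``return_fields=True`` also returns the estimated fields for audit:
    ``(frame, {"t1": {(frame_index, wavelength): field}, "t2": {frame_index:
    field}})``.
    """
    frames = list(frames)
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    grids = {tuple(f.wavelengths) for f in frames}
    if len(grids) != 1:
        raise ValueError("frames must share the wavelength grid")
    wavelengths = frames[0].wavelengths
    if reference_wavelength not in wavelengths:
        raise ValueError(f"reference wavelength {reference_wavelength} nm "
                         "missing from the stack")
    lo, hi = t1_band
    band = [w for w in wavelengths if lo <= w <= hi]
    if not band:
        raise ValueError("no wavelengths inside the T1 band")
    top = band[-1]

    # T1: intra-frame alignment to the reference wavelength
    t1 = []
    for f in frames:
        ref = f.images[reference_wavelength]
        fields = {}
        for w in band:
            try:
                fields[w] = register_elastic(f.images[w], ref, params)
            except ValueError as exc:
                raise ValueError(
                    f"T1 registration failed for frame {f.frame_index} at "
                    f"{w} nm: {exc}") from exc
        for w in wavelengths:
            if w not in fields:
                fields[w] = fields[top]
        t1.append(fields)

    # per-frame mean over the T1-warped band
    means = []
    for f, fields in zip(frames, t1):
        warped = [warp_image(f.images[w], fields[w]) for w in band]
        means.append(np.mean(warped, axis=0))

    # T2: inter-frame alignment of mean images to the middle frame
    mid = int(np.ceil(len(frames) / 2)) - 1
    t2 = []
    for i, m in enumerate(means):
        try:
            t2.append(register_elastic(m, means[mid], params))
        except ValueError as exc:
            raise ValueError(f"T2 registration failed for frame "
                             f"{frames[i].frame_index}: {exc}") from exc

    out = {}
    for w in wavelengths:
        acc = [warp_image(f.images[w], compose_fields(t2[i], t1[i][w]))
               for i, f in enumerate(frames)]
        out[w] = np.mean(acc, axis=0)
    result = MultispectralFrame(out, frame_index=frames[mid].frame_index,
                                strict=frames[0].strict)
    if return_fields:
        fields = {
            "t1": {(f.frame_index, w): t1[i][w]
                   for i, f in enumerate(frames) for w in wavelengths},
            "t2": {f.frame_index: t2[i] for i, f in enumerate(frames)},
        }
        return result, fields
    return result
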