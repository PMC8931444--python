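"""Two-medium refracted travel times.

Sound emitted at a tissue pixel reaches a detector element through the heavy
water cavity after crossing the planar water/tissue interface.  By Fermat's
principle the propagation time is the minimum over all single-breakpoint paths
crossing the interface; the minimum-time condition is Snell's law.  The travel
time t(x_b) as a function of the interface breakpoint x_b is convex, so its
derivative has a single root bracketed by the lateral coordinates of the
element and the pixel; we locate it by vectorized bisection.
"""

from __future__ import annotations

import numpy as np

from .geometry import MM, ProbeGeometry

__all__ = ["compute_travel_time", "refracted_breakpoint"]

_BISECT_ITERS = 90  # interval shrinks by 2^-90: well below 1e-12 relative


def _snell_derivative(xb, xe, ye, xp, yp, yi, cw, ct):
    d1 = np.hypot(xb - xe, yi - ye)
    d2 = np.hypot(xp - xb, yp - yi)
    # guard degenerate zero-length legs
    d1 = np.where(d1 == 0, np.finfo(float).tiny, d1)
    d2 = np.where(d2 == 0, np.finfo(float).tiny, d2)
    return (xb - xe) / (cw * d1) + (xb - xp) / (ct * d2)


def refracted_breakpoint(element_mm, pixel_mm, interface_depth_mm,
                         sos_water, sos_tissue):
    """Interface crossing point x (mm) of the minimum-time path (vectorized)."""
    xe, ye = np.asarray(element_mm, float)[..., 0], np.asarray(element_mm, float)[..., 1]
    xp, yp = np.asarray(pixel_mm, float)[..., 0], np.asarray(pixel_mm, float)[..., 1]
    lo = np.minimum(xe, xp)
    hi = np.maximum(xe, xp)
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        g = _snell_derivative(mid, xe, ye, xp, yp, interface_depth_mm,
                              sos_water, sos_tissue)
        lo = np.where(g < 0, mid, lo)
        hi = np.where(g < 0, hi, mid)
    return 0.5 * (lo + hi)


def compute_travel_time(pixel_mm, element_mm, geometry: ProbeGeometry,
                        sos_mode: str = "dual"):
    """Propagation time (s) from tissue pixel(s) to element(s).

    Parameters are (x, y) points in mm; both arguments broadcast.  In
    ``uniform`` mode the medium is homogeneous at ``sos_tissue`` and the path
    is the straight line.  In ``dual`` mode the Fermat minimum over
    single-breakpoint paths through the planar interface is returned; a pixel
    on the interface directly below the element reduces to the straight
    water-only path, and equal speeds reduce to the straight-line time.

    Pixels strictly above the interface are not modelled and raise ValueError.
    """
    pixel = np.asarray(pixel_mm, dtype=float)
    element = np.asarray(element_mm, dtype=float)
    if pixel.shape[-1] != 2 or element.shape[-1] != 2:
        raise ValueError("points must be (..., 2) arrays of (x, y) in mm")
    pixel, element = np.broadcast_arrays(pixel, element)

    if sos_mode not in ("uniform", "dual"):
        raise ValueError(f"unknown sos_mode {sos_mode!r}")

    if sos_mode == "uniform":
        d = np.hypot(pixel[..., 0] - element[..., 0],
                     pixel[..., 1] - element[..., 1])
        return d * MM / geometry.sos_tissue

    yi = geometry.interface_depth_mm
    cw, ct = geometry.sos_water, geometry.sos_tissue
    tol = 1e-9  # mm; guards float noise on "at the interface"
    if np.any(pixel[..., 1] < yi - tol):
        raise ValueError("pixel above the water/tissue interface is not modelled")
    if np.any(element[..., 1] >= yi):
        raise ValueError("element must lie on the water side of the interface")

    if cw == ct:
        d = np.hypot(pixel[..., 0] - element[..., 0],
                     pixel[..., 1] - element[..., 1])
        return d * MM / cw

    xe, ye = element[..., 0], element[..., 1]
    xp, yp = pixel[..., 0], np.maximum(pixel[..., 1], yi)

    # A pixel exactly on the interface is handled by the same minimization:
    # its fastest path may still cross the interface away from the pixel and
    # run along it in the faster medium; directly below the element it
    # degenerates to the straight water-only path.
    xb = refracted_breakpoint(element, np.stack([xp, yp], axis=-1), yi, cw, ct)
    d1 = np.hypot(xb - xe, yi - ye)
    d2 = np.hypot(xp - xb, yp - yi)
    return (d1 * MM) / cw + (d2 * MM) / ct


def travel_time_matrix(geometry: ProbeGeometry, sos_mode: str = "dual"):
    """(n_elements, n_pixels) travel times for the geometry's grid."""
    elements = geometry.element_positions_mm[:, None, :]
    pixels = geometry.pixel_positions_mm()[None, :, :]
    return compute_travel_time(pixels, elements, geometry, sos_mode)
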