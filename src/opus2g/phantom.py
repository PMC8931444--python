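"""Synthetic phantoms, signal simulation, noise and motion injection.

Scanner data is proprietary, so every pipeline stage is exercised on synthetic
ground truth: 2-D chromophore-concentration maps built from simple primitives
(disk/ellipse "vessels", a skin layer), turned into per-wavelength
initial-pressure maps through the chromophore library, and propagated to
arc-detector signals by a direct dense summation that is implemented
independently of the sparse forward-model assembly (it serves as its oracle).

Noise emulation covers the artifacts the real pipeline has to suppress:
per-channel white noise, channel-shared ("coherent") electrical noise that
reconstructs onto isochrone rings, multiplicative single-wavelength intensity
spikes, and smooth seeded inter-/intra-frame motion with ground-truth fields
returned for registration scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .geometry import MM, ProbeGeometry, TIRKernel
from .motion import DisplacementField, warp_image
from .spectral import (CHROMOPHORE_NAMES, ChromophoreLibrary,
                       MultispectralFrame)
from .travel import compute_travel_time

__all__ = ["Structure", "PhantomSpec", "Phantom", "NoiseSpec", "make_phantom",
           "vessel_grid_spec", "simulate_signals", "add_signal_noise",
           "random_smooth_field", "inject_noise_and_motion"]


@dataclass(frozen=True)
class Structure:
    """An elliptical absorber (a vessel cross-section) or a skin layer.

    ``concentrations`` maps chromophore name -> concentration (arbitrary
    units).  For ``kind="skin"``, ``center_mm[1]`` is the skin depth and
    ``radii_mm[1]`` the layer thickness; the layer spans the full width.
    """

    kind: str                      # "ellipse" | "skin"
    center_mm: tuple               # (x, y)
    radii_mm: tuple                # (rx, ry)
    concentrations: dict

    def __post_init__(self):
        if self.kind not in ("ellipse", "skin"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    structures: tuple
    jitter_mm: float = 0.0         # seeded random jitter of structure centres


@dataclass
class Phantom:
    """Ground-truth chromophore maps on the reconstruction grid."""

    chromophore_maps: np.ndarray   # (H, W, 4) in CHROMOPHORE_NAMES order
    geometry: ProbeGeometry
    seed: int
    spec: PhantomSpec | None = None

    def pressure_map(self, wavelength: float, library: ChromophoreLibrary,
                     fluence_mu_eff_per_cm: float | None = None) -> np.ndarray:
        """Initial pressure at one wavelength.

        p0 = sum_k concentration_k * absorption_k(lambda), optionally damped
        by a single-exponential depth fluence exp(-mu_eff * depth).  Fluence
        is off by default so inversion tests keep a linear ground truth.
        """
        absorb = np.array([library.absorption(name, wavelength)
                           for name in CHROMOPHORE_NAMES])
        p = self.chromophore_maps @ absorb
        if fluence_mu_eff_per_cm is not None:
            y, _ = self.geometry.grid_coordinates_mm()
            depth_cm = np.maximum(y - self.geometry.interface_depth_mm,
                                  0.0) / 10.0
            p = p * np.exp(-fluence_mu_eff_per_cm * depth_cm)[:, None]
        return p


def vessel_grid_spec(n_vessels: int = 5) -> PhantomSpec:
    """Default preset: a shallow skin layer over a loose grid of vessels.

    Vessels alternate between oxygenated (HbO2-dominated) and deoxygenated
    (Hb-dominated) blood; the bulk positions form a coarse grid with seeded
    jitter so different seeds give different but comparable phantoms.
    """
    structures = [Structure("skin", (0.0, 1.2), (0.0, 0.6),
                            {"Hb": 0.4, "water": 0.3})]
    cols = [-8.0, 0.0, 8.0]
    depths = [8.0, 14.0, 20.0]
    k = 0
    for d in depths:
        for c in cols:
            if k >= n_vessels:
                break
            blood = {"HbO2": 1.0, "Hb": 0.15} if k % 2 == 0 else \
                {"HbO2": 0.2, "Hb": 1.0}
            radius = 0.6 + 0.35 * (k % 3)
            structures.append(Structure("ellipse", (c, d), (radius, radius),
                                        blood))
            k += 1
    structures.append(Structure("ellipse", (5.0, 17.0), (2.5, 1.5),
                                {"fat": 1.0}))
    return PhantomSpec(tuple(structures), jitter_mm=1.0)


def make_phantom(spec: PhantomSpec, geometry: ProbeGeometry,
                 seed: int = 0) -> Phantom:
    """Rasterize a phantom spec onto the geometry's grid (reproducible).

    Overlapping structures add.  Structures (after jitter) must stay inside
    the field of view.
    """
    rng = np.random.default_rng(seed)
    y, x = geometry.grid_coordinates_mm()
    xx, yy = np.meshgrid(x, y)
    maps = np.zeros(geometry.grid_shape + (len(CHROMOPHORE_NAMES),))

    for s in spec.structures:
        cx, cy = s.center_mm
        if spec.jitter_mm > 0 and s.kind == "ellipse":
            cx = cx + rng.uniform(-spec.jitter_mm, spec.jitter_mm)
            cy = cy + rng.uniform(-spec.jitter_mm, spec.jitter_mm)
        if s.kind == "ellipse":
            rx, ry = s.radii_mm
            if (abs(cx) + rx > geometry.fov_mm[0] / 2
                    or cy + ry > y[-1] or cy - ry < y[0]):
                raise ValueError("structure outside the field of view")
            inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        else:  # skin layer
            thickness = s.radii_mm[1]
            inside = (yy >= cy) & (yy <= cy + thickness)
        for name, conc in s.concentrations.items():
            maps[..., CHROMOPHORE_NAMES.index(name)] += conc * inside
    return Phantom(maps, geometry, seed, spec)


def simulate_signals(pressure: np.ndarray, geometry: ProbeGeometry,
                     tir: TIRKernel, sos_mode: str = "dual") -> np.ndarray:
    """Direct dense summation of detector signals from a pressure map.

    Every source pixel deposits its amplitude (2-D geometric decay 1/sqrt(r))
    at its Fermat travel time via linear interpolation onto the sample grid;
    the dense trace is then derivative-shaped and convolved with the TIR.
    Deliberately a per-element accumulation loop, kept independent from the
    sparse matrix assembly in :mod:`opus2g.forward` so the two cross-validate.
    """
    p = np.asarray(pressure, dtype=float)
    if p.shape != tuple(geometry.grid_shape):
        raise ValueError("pressure map does not match the geometry grid")
    fs = geometry.sampling_rate
    n_t = geometry.n_samples
    pitch = min(geometry.pixel_pitch_mm)
    pixels = geometry.pixel_positions_mm()
    pvals = p.ravel()
    nz = np.flatnonzero(pvals)
    out = np.zeros((geometry.n_elements, n_t))
    deriv = np.array([0.5, 0.0, -0.5]) * fs

    for i, el in enumerate(geometry.element_positions_mm):
        if nz.size == 0:
            break
        t = compute_travel_time(pixels[nz], el, geometry, sos_mode)
        r = np.hypot(pixels[nz, 0] - el[0], pixels[nz, 1] - el[1])
        amp = pvals[nz] / np.sqrt(np.maximum(r, pitch))
        frac = t * fs
        k0 = np.floor(frac).astype(int)
        w1 = frac - k0
        dense = np.zeros(n_t + 1)
        ok = (k0 >= 0) & (k0 < n_t)
        np.add.at(dense, k0[ok], amp[ok] * (1.0 - w1[ok]))
        ok1 = (k0 + 1 >= 0) & (k0 + 1 < n_t)
        np.add.at(dense, k0[ok1] + 1, amp[ok1] * w1[ok1])
        trace = np.convolve(dense[:n_t], deriv)[1:1 + n_t]
        trace = np.convolve(trace, tir.samples)[
            tir.origin_index:tir.origin_index + n_t]
        out[i] = trace
    return out


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model of the acquisition chain.

    white_sigma: per-sample white noise std (signal units);
    coherent_amp: amplitude of a time-domain trace shared by all channels
    (electrical pickup; reconstructs onto isochrone rings);
    spike_prob: probability of a multiplicative single-wavelength spike per
    pixel; spike_gain: its multiplier.
    """

    white_sigma: float = 0.0
    coherent_amp: float = 0.0
    spike_prob: float = 0.0
    spike_gain: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.white_sigma, self.coherent_amp, self.spike_prob) < 0:
            raise ValueError("noise parameters must be non-negative")


def add_signal_noise(signals: np.ndarray, noise: NoiseSpec,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """White + coherent (channel-shared) noise on one signal frame."""
    rng = rng or np.random.default_rng(noise.seed)
    s = np.asarray(signals, dtype=float).copy()
    if noise.coherent_amp > 0:
        shared = rng.standard_normal(s.shape[-1]) * noise.coherent_amp
        s = s + shared[None, :]
    if noise.white_sigma > 0:
        s = s + rng.standard_normal(s.shape) * noise.white_sigma
    return s


def random_smooth_field(shape, max_px: float,
                        rng: np.random.Generator,
                        n_bumps: int = 3) -> DisplacementField:
    """Seeded smooth warp: a sum of Gaussian bumps, peak magnitude max_px."""
    h, w = shape
    if max_px > min(h, w) / 4:
        raise ValueError("motion amplitude beyond a quarter of the image")
    if max_px == 0:
        return DisplacementField.zero(shape)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    vec = np.zeros(shape + (2,))
    for _ in range(n_bumps):
        cy, cx = rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)
        sig = rng.uniform(min(h, w) / 10.0, min(h, w) / 5.0)
        amp = rng.uniform(-1.0, 1.0, size=2)
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2))
        vec[..., 0] += amp[0] * bump
        vec[..., 1] += amp[1] * bump
    peak = np.max(np.hypot(vec[..., 0], vec[..., 1]))
    if peak > 0:
        vec *= max_px / peak
    return DisplacementField(vec)


def inject_noise_and_motion(frames, noise: NoiseSpec,
                            inter_frame_px: float = 0.0,
                            intra_frame_px: float = 0.0,
                            seed: int = 0):
    """Corrupt reconstructed multispectral frames with spikes and motion.

    Applies, per frame, a seeded smooth inter-frame warp (shared by all its
    wavelengths) composed with small per-wavelength intra-frame warps, then
    multiplicative single-wavelength spikes.  Returns ``(corrupted_frames,
    truth)`` where ``truth["fields"][(frame_index, wavelength)]`` is the
    resampling field that was applied, for registration scoring.  Zero noise
    and zero motion return an identical copy.
    """
    rng = np.random.default_rng(seed)
    out_frames, fields = [], {}
    for f in frames:
        shape = f.shape
        inter = random_smooth_field(shape, inter_frame_px, rng)
        images = {}
        for w in f.wavelengths:
            intra = random_smooth_field(shape, intra_frame_px, rng)
            total = DisplacementField(inter.vectors + intra.vectors)
            img = warp_image(f.images[w], total)
            if noise.spike_prob > 0:
                spikes = rng.random(shape) < noise.spike_prob
                img = np.where(spikes, img * noise.spike_gain, img)
            images[w] = img
            fields[(f.frame_index, w)] = total
        out_frames.append(MultispectralFrame(images, f.frame_index,
                                             strict=f.strict))
    return out_frames, {"fields": fields}
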