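"""Probe geometry and detector impulse response.

The handheld probe is a curvilinear array of piezoelectric elements arranged on
a circular arc, coupled to the tissue through a heavy-water-filled cavity.
Sound travels through two media: the cavity (heavy water) and the tissue, with
refraction at their planar interface.

Coordinate convention: x is lateral (mm), y is depth (mm) increasing away from
the probe.  The arc's centre of curvature sits at the origin; elements lie
above the water/tissue interface (y < interface_depth), the imaging field of
view below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = ["ProbeGeometry", "TIRKernel", "desk_geometry", "full_geometry"]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class TIRKernel:
    """Total impulse response of the detection chain.

    A single shared 1-D temporal kernel, applied by convolution to every
    element's trace.  ``origin_index`` is the sample corresponding to t = 0,
    so a kernel ``[1.0]`` with origin 0 is the identity.
    """

    samples: np.ndarray
    origin_index: int = 0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float).ravel()
        if samples.size == 0:
            raise ValueError("TIR kernel must be non-empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("TIR kernel must be finite")
        if not (0 <= self.origin_index < samples.size):
            raise ValueError("origin_index outside kernel support")
        object.__setattr__(self, "samples", samples)

    @classmethod
    def delta(cls) -> "TIRKernel":
        """Identity kernel (no TIR shaping)."""
        return cls(np.array([1.0]), 0)

    @classmethod
    def derivative_of_gaussian(cls, sampling_rate: float,
                               center_frequency: float = 4e6,
                               n_sigmas: float = 4.0) -> "TIRKernel":
        """Band-limited derivative-of-Gaussian kernel.

        The derivative of a Gaussian of width sigma has its spectral peak at
        f_p = 1/(2*pi*sigma); sigma is chosen so f_p equals the transducer
        centre frequency (4 MHz for this probe).
        """
        sigma_t = 1.0 / (2.0 * np.pi * center_frequency)
        sigma_s = sigma_t * sampling_rate
        half = max(int(np.ceil(n_sigmas * sigma_s)), 2)
        n = np.arange(-half, half + 1, dtype=float)
        k = -n / sigma_s**2 * np.exp(-0.5 * (n / sigma_s) ** 2)
        peak = np.max(np.abs(k))
        if peak > 0:
            k = k / peak
        return cls(k, half)

    @classmethod
    def from_text(cls, path) -> "TIRKernel":
        """Load a kernel from a 1-column text file; origin at the midpoint."""
        samples = np.loadtxt(path, dtype=float).ravel()
        return cls(samples, samples.size // 2)

    @property
    def is_delta(self) -> bool:
        k = np.zeros_like(self.samples)
        k[self.origin_index] = 1.0
        return bool(np.array_equal(self.samples, k))


@dataclass(frozen=True)
class ProbeGeometry:
    """Curvilinear array + two-medium acoustic configuration.

    Defaults describe the clinical probe: 256 elements on a 145 deg arc with
    6 cm between the endpoint elements, heavy-water cavity (1397 m/s) above a
    planar interface, 40 mm x 40 mm field of view on a 401 x 401 grid.
    """

    n_elements: int = 256
    arc_coverage_deg: float = 145.0
    endpoint_distance_mm: float = 60.0
    interface_depth_mm: float = 0.0
    sos_water: float = 1397.0
    sos_tissue: float = 1510.0
    sampling_rate: float = 4e7
    n_samples: int = 2304
    fov_mm: tuple = (40.0, 40.0)           # (lateral, depth)
    grid_shape: tuple = (401, 401)         # (rows = depth, cols = lateral)
    fov_offset_mm: float = 0.0             # FOV top edge below the interface

    def __post_init__(self):
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")
        if not (0 < self.arc_coverage_deg < 360):
            raise ValueError("arc coverage must be in (0, 360) degrees")
        if min(self.fov_mm) <= 0 or min(self.grid_shape) < 2:
            raise ValueError("FOV and grid must be positive")
        if self.sos_water <= 0 or self.sos_tissue <= 0:
            raise ValueError("speeds of sound must be positive")
        # upper band-pass cut-off is 8 MHz: require Nyquist margin
        if self.sampling_rate < 2 * 8e6:
            raise ValueError("sampling rate below Nyquist for the 8 MHz band edge")
        if np.max(self.element_positions_mm[:, 1]) >= self.interface_depth_mm:
            raise ValueError("elements must lie strictly above the interface")

    @property
    def arc_radius_mm(self) -> float:
        half = np.deg2rad(self.arc_coverage_deg) / 2.0
        return self.endpoint_distance_mm / (2.0 * np.sin(half))

    @property
    def element_positions_mm(self) -> np.ndarray:
        """(n_elements, 2) array of (x, y) in mm.

        Elements sit on a circle of radius R centred at the origin, at angles
        spanning the arc coverage around the upward (-y) direction, so the arc
        opens toward increasing depth.
        """
        half = np.deg2rad(self.arc_coverage_deg) / 2.0
        phi = np.linspace(-half, half, self.n_elements)
        r = self.arc_radius_mm
        return np.column_stack([r * np.sin(phi), -r * np.cos(phi)])

    @property
    def pixel_pitch_mm(self) -> tuple:
        return (self.fov_mm[1] / (self.grid_shape[0] - 1),
                self.fov_mm[0] / (self.grid_shape[1] - 1))

    def grid_coordinates_mm(self) -> tuple:
        """Pixel-centre coordinates: (y depth (rows,), x lateral (cols,))."""
        x = np.linspace(-self.fov_mm[0] / 2.0, self.fov_mm[0] / 2.0,
                        self.grid_shape[1])
        y0 = self.interface_depth_mm + self.fov_offset_mm
        y = np.linspace(y0, y0 + self.fov_mm[1], self.grid_shape[0])
        return y, x

    def pixel_positions_mm(self) -> np.ndarray:
        """(n_pixels, 2) array of (x, y) in mm, row-major over the grid."""
        y, x = self.grid_coordinates_mm()
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.asdict(), fh)

    def asdict(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "arc_coverage_deg": self.arc_coverage_deg,
            "endpoint_distance_mm": self.endpoint_distance_mm,
            "interface_depth_mm": self.interface_depth_mm,
            "sos_water": self.sos_water,
            "sos_tissue": self.sos_tissue,
            "sampling_rate": self.sampling_rate,
            "n_samples": self.n_samples,
            "fov_mm": list(self.fov_mm),
            "grid_shape": list(self.grid_shape),
            "fov_offset_mm": self.fov_offset_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeGeometry":
        d = dict(d)
        if "fov_mm" in d:
            d["fov_mm"] = tuple(d["fov_mm"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ProbeGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def scaled(self, **kwargs) -> "ProbeGeometry":
        return replace(self, **kwargs)


def full_geometry(**overrides) -> ProbeGeometry:
    """Clinical-scale geometry (256 elements, 401x401 grid)."""
    return ProbeGeometry(**overrides)


def desk_geometry(n_elements: int = 64, grid: int = 101,
                  n_samples: int = 1024, **overrides) -> ProbeGeometry:
    """Reduced geometry for desk-scale simulation and testing.

    Same arc but fewer elements, a 30 mm x 30 mm FOV and a 20 MS/s rate so the
    whole FOV stays inside a 1024-sample recording window.
    """
    params = dict(
        n_elements=n_elements,
        grid_shape=(grid, grid),
        fov_mm=(30.0, 30.0),
        sampling_rate=2e7,
        n_samples=n_samples,
    )
    params.update(overrides)
    return ProbeGeometry(**params)
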