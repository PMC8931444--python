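"""Spectral processing of multispectral image stacks.

Two operations exploit the smooth wavelength dependence of tissue absorption:

* spectral median — per pixel, the median over a narrow (40 nm) wavelength
  window, which rejects single-wavelength noise spikes such as the ring
  artifacts produced by coherent electrical noise;
* linear unmixing — per pixel, the non-negative least-squares decomposition of
  the measured spectrum onto the absorption spectra of oxyhemoglobin,
  deoxyhemoglobin, fat and water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import nnls

__all__ = ["ChromophoreLibrary", "MultispectralFrame", "CoefficientMaps",
           "spectral_median", "unmix", "WAVELENGTH_GRID"]

#: Acquisition wavelength grid: 28 wavelengths, 700-970 nm at 10 nm steps.
WAVELENGTH_GRID = tuple(range(700, 980, 10))

CHROMOPHORE_NAMES = ("HbO2", "Hb", "fat", "water")


@dataclass
class MultispectralFrame:
    """Ordered map wavelength (nm) -> single-wavelength image.

    The clinical acquisition covers the full 28-wavelength grid; desk-scale
    stacks may carry a contiguous subset of it (``strict=False``).
    """

    images: dict
    frame_index: int = 0
    strict: bool = True

    def __post_init__(self):
        self.images = {int(k): np.asarray(v, dtype=float)
                       for k, v in self.images.items()}
        wl = self.wavelengths
        if any(w % 10 != 0 for w in wl):
            raise ValueError("wavelengths must lie on the 10 nm grid")
        if self.strict and tuple(wl) != WAVELENGTH_GRID:
            raise ValueError("strict stack requires the full 28-wavelength "
                             "700-970 nm grid")
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError("all images in a frame must share one shape")

    @property
    def wavelengths(self):
        return sorted(self.images)

    @property
    def shape(self):
        return next(iter(self.images.values())).shape

    def as_array(self) -> np.ndarray:
        """(n_wavelengths, H, W) cube in wavelength order."""
        return np.stack([self.images[w] for w in self.wavelengths])


@dataclass
class CoefficientMaps:
    """Per-pixel non-negative chromophore coefficients (arbitrary units)."""

    maps: dict  # name -> 2-D array

    def __post_init__(self):
        for name in CHROMOPHORE_NAMES:
            if name not in self.maps:
                raise ValueError(f"missing coefficient map {name!r}")
        for name, m in self.maps.items():
            if np.any(np.asarray(m) < 0):
                raise ValueError(f"negative coefficients in {name!r}")

    def __getitem__(self, name):
        return self.maps[name]


@dataclass
class ChromophoreLibrary:
    """Absorption spectra matrix for HbO2, Hb, fat and water.

    Values are a relative-unit tabulation resampled to the 10 nm acquisition
    grid, approximating published near-infrared absorption compilations
    (hemoglobin per Prahl's tabulation; lipid and water per standard
    laboratory spectra).  For quantitative work supply your own table via
    :meth:`from_csv`.
    """

    wavelengths: np.ndarray
    spectra: np.ndarray            # (n_wavelengths, 4)
    names: tuple = CHROMOPHORE_NAMES

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (self.wavelengths.size, len(self.names)):
            raise ValueError("spectra must be (n_wavelengths, n_chromophores)")
        if np.any(self.spectra < 0):
            raise ValueError("absorption spectra must be non-negative")
        if np.any(~np.any(self.spectra, axis=0)):
            raise ValueError("library contains an all-zero chromophore column")

    @classmethod
    def default(cls) -> "ChromophoreLibrary":
        path = resources.files("opus2g.data") / "chromophores.csv"
        with resources.as_file(path) as p:
            return cls.from_csv(p)

    @classmethod
    def from_csv(cls, path) -> "ChromophoreLibrary":
        raw = np.genfromtxt(path, delimiter=",", names=True)
        wl = raw["wavelength_nm"]
        spectra = np.column_stack([raw[name] for name in CHROMOPHORE_NAMES])
        return cls(wl, spectra)

    def absorption(self, name: str, wavelength: float) -> float:
        """Absorption of one chromophore, linearly interpolated in lambda."""
        col = self.names.index(name)
        return float(np.interp(wavelength, self.wavelengths,
                               self.spectra[:, col]))

    def matrix_for(self, wavelengths) -> np.ndarray:
        """Library rows restricted to the requested wavelengths."""
        wl = np.asarray(wavelengths, dtype=float)
        missing = np.setdiff1d(wl, self.wavelengths)
        if missing.size:
            raise ValueError(f"wavelengths not in the library: {missing}")
        idx = np.searchsorted(self.wavelengths, wl)
        return self.spectra[idx]


def spectral_median(stack: MultispectralFrame, wavelength: int,
                    half_window_nm: int = 20) -> np.ndarray:
    """Per-pixel median over the +-20 nm wavelength window around ``wavelength``.

    On the 10 nm grid the 40 nm window contains 5 wavelengths; at the grid
    boundary the window is truncated to the available wavelengths.
    """
    wavelength = int(wavelength)
    if wavelength not in stack.images:
        raise ValueError(f"{wavelength} nm not in the stack")
    window = [w for w in stack.wavelengths
              if abs(w - wavelength) <= half_window_nm]
    cube = np.stack([stack.images[w] for w in window])
    return np.median(cube, axis=0)


def unmix(stack: MultispectralFrame, library: ChromophoreLibrary
          ) -> CoefficientMaps:
    """Pixel-wise non-negative least squares:  min ||S c - p||_2,  c >= 0.

    ``S`` stacks the library absorption spectra at the stack's wavelengths and
    ``p`` is the pixel's measured spectrum.
    """
    S = library.matrix_for(stack.wavelengths)
    cube = stack.as_array()
    n_l, h, w = cube.shape
    P = cube.reshape(n_l, -1)
    out = np.zeros((len(library.names), h * w))
    nonzero = np.flatnonzero(np.any(P != 0, axis=0))
    for j in nonzero:
        out[:, j] = nnls(S, P[:, j])[0]
    maps = {name: out[i].reshape(h, w)
            for i, name in enumerate(library.names)}
    return CoefficientMaps(maps)
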