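"""Discretized acoustic forward model.

The model is a sparse linear operator M mapping an initial-pressure image
(row-major pixel vector) to stacked per-element time traces.  Each pixel
contributes a wavelet at its (possibly refracted) travel time: the arrival is
linearly interpolated onto the sample grid, scaled by 2-D geometric decay
1/sqrt(r), shaped by a discrete temporal derivative, and convolved with the
total impulse response (TIR) of the detection chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ProbeGeometry, TIRKernel
from .travel import compute_travel_time

__all__ = ["ForwardModel", "assemble_forward_model", "apply_model", "apply_adjoint"]

log = logging.getLogger(__name__)


@dataclass
class ForwardModel:
    """Sparse forward operator with its provenance.

    ``matrix`` has shape (n_elements * n_samples, n_pixels); rows are ordered
    element-major (element 0's full trace first).
    """

    matrix: sp.csr_matrix
    geometry: ProbeGeometry
    tir: TIRKernel
    sos_mode: str
    n_zero_columns: int = 0

    @property
    def signal_shape(self) -> tuple:
        return (self.geometry.n_elements, self.geometry.n_samples)

    @property
    def grid_shape(self) -> tuple:
        return tuple(self.geometry.grid_shape)


def _composite_kernel(tir: TIRKernel, sampling_rate: float):
    """Temporal derivative stencil convolved with the TIR.

    Returns (taps, origin): the convolution kernel applied to the interpolated
    delta at the arrival sample.  The central-difference derivative kernel is
    [fs/2, 0, -fs/2] with origin index 1 (offset -1 tap is the future sample).
    """
    deriv = np.array([0.5, 0.0, -0.5]) * sampling_rate
    taps = np.convolve(deriv, tir.samples)
    origin = 1 + tir.origin_index
    return taps, origin


def assemble_forward_model(geometry: ProbeGeometry, tir: TIRKernel,
                           sos_mode: str = "dual",
                           pixel_chunk: int = 4096) -> ForwardModel:
    """Build the sparse operator M for a geometry, TIR kernel and SoS mode.

    Columns are assembled in pixel chunks to bound peak memory.  Pixels whose
    arrival falls entirely outside the recording window produce all-zero
    columns; their count is logged.
    """
    fs = geometry.sampling_rate
    n_el = geometry.n_elements
    n_t = geometry.n_samples
    pitch = min(geometry.pixel_pitch_mm)
    elements = geometry.element_positions_mm
    pixels = geometry.pixel_positions_mm()
    n_pix = pixels.shape[0]

    taps, origin = _composite_kernel(tir, fs)
    offsets = np.arange(taps.size) - origin  # sample offsets of each tap

    blocks = []
    zero_cols = 0
    for start in range(0, n_pix, pixel_chunk):
        chunk = pixels[start:start + pixel_chunk]
        nc = chunk.shape[0]
        t = compute_travel_time(chunk[None, :, :], elements[:, None, :],
                                geometry, sos_mode)          # (n_el, nc)
        frac = t * fs
        k0 = np.floor(frac).astype(np.int64)
        w1 = frac - k0                                        # weight at k0+1
        # 2-D geometric decay 1/sqrt(r) over the element-pixel distance
        r_mm = np.hypot(chunk[None, :, 0] - elements[:, None, 0],
                        chunk[None, :, 1] - elements[:, None, 1])
        amp = 1.0 / np.sqrt(np.maximum(r_mm, pitch))

        el_idx = np.broadcast_to(np.arange(n_el)[:, None], (n_el, nc))
        col = np.broadcast_to(np.arange(nc)[None, :], (n_el, nc))

        rows_parts, cols_parts, data_parts = [], [], []
        for base_off, base_w in ((0, 1.0 - w1), (1, w1)):
            for ti, tap in enumerate(taps):
                if tap == 0.0:
                    continue
                sample = k0 + base_off + offsets[ti]
                valid = (sample >= 0) & (sample < n_t)
                if not np.any(valid):
                    continue
                rows_parts.append(
                    (el_idx[valid] * n_t + sample[valid]).ravel())
                cols_parts.append(col[valid].ravel())
                data_parts.append((amp[valid] * base_w[valid] * tap).ravel())

        if rows_parts:
            rows = np.concatenate(rows_parts)
            cols = np.concatenate(cols_parts)
            data = np.concatenate(data_parts)
        else:
            rows = np.empty(0, np.int64)
            cols = np.empty(0, np.int64)
            data = np.empty(0, float)
        block = sp.coo_matrix((data, (rows, cols)),
                              shape=(n_el * n_t, nc)).tocsc()
        zero_cols += int(np.sum(np.diff(block.indptr) == 0))
        blocks.append(block)

    matrix = sp.hstack(blocks, format="csr")
    if zero_cols:
        log.info("forward model: %d pixels outside the recording window "
                 "(all-zero columns)", zero_cols)
    return ForwardModel(matrix=matrix, geometry=geometry, tir=tir,
                        sos_mode=sos_mode, n_zero_columns=zero_cols)


def apply_model(model: ForwardModel, image: np.ndarray) -> np.ndarray:
    """M @ p: image (grid_shape or flat) -> signals (n_elements, n_samples)."""
    p = np.asarray(image, dtype=float).ravel()
    if p.size != model.matrix.shape[1]:
        raise ValueError(f"image has {p.size} pixels, model expects "
                         f"{model.matrix.shape[1]}")
    return (model.matrix @ p).reshape(model.signal_shape)


def apply_adjoint(model: ForwardModel, signals: np.ndarray) -> np.ndarray:
    """M^T @ s: signals (n_elements, n_samples or flat) -> image grid."""
    s = np.asarray(signals, dtype=float).ravel()
    if s.size != model.matrix.shape[0]:
        raise ValueError(f"signals have {s.size} samples, model expects "
                         f"{model.matrix.shape[0]}")
    return (model.matrix.T @ s).reshape(model.grid_shape)
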