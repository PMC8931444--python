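"""Open HDF5 container, run configuration and pipeline orchestration.

The scanner's native format is proprietary, so the package defines its own
versioned HDF5 schema:

* ``/signals``  — float array (elements, samples, wavelengths, frames) with
  attrs ``sampling_rate``, ``wavelengths`` (nm), ``timestamps`` (frame start
  times, s);
* ``/us``       — float array (frames, H, W) with attr ``timestamps``;
* ``/geometry`` — group whose attrs hold the probe geometry;
* ``/masks``    — optional label image (0 background, 1 tumor core);
* root attr ``schema_version``.

``run_pipeline`` executes the off-line processing DAG: band-pass filter,
dual-SoS reconstruction, motion correction and averaging, uniform-SoS
reconstruction, OA/OA affine estimation, US warping and US averaging —
emitting every intermediate artifact with a config-hash provenance sidecar.
The scanner-side US beamforming and the manual tumor segmentation are inputs,
not computed steps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .coreg import USImage, average_concurrent_us, estimate_affine, warp_us
from .filtering import LCO_PRESETS, bandpass
from .forward import assemble_forward_model
from .geometry import ProbeGeometry, TIRKernel
from .motion import correct_and_average
from .reconstruction import ReconConfig, reconstruct
from .spectral import MultispectralFrame

__all__ = ["SCHEMA_VERSION", "ScanData", "RunConfig", "write_container",
           "read_container", "run_pipeline"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SIGNAL_ATTRS = ("sampling_rate", "wavelengths", "timestamps")


@dataclass
class ScanData:
    """In-memory view of one container: signals, US frames, geometry, masks."""

    signals: np.ndarray            # (elements, samples, wavelengths, frames)
    sampling_rate: float
    wavelengths: np.ndarray        # nm
    timestamps: np.ndarray         # frame start times, s
    geometry: ProbeGeometry
    us: np.ndarray | None = None   # (frames, H, W)
    us_timestamps: np.ndarray | None = None
    masks: np.ndarray | None = None


def write_container(path, scan: ScanData) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        d = f.create_dataset("signals", data=scan.signals)
        d.attrs["sampling_rate"] = scan.sampling_rate
        d.attrs["wavelengths"] = np.asarray(scan.wavelengths)
        d.attrs["timestamps"] = np.asarray(scan.timestamps)
        g = f.create_group("geometry")
        for k, v in scan.geometry.asdict().items():
            g.attrs[k] = v
        if scan.us is not None:
            u = f.create_dataset("us", data=scan.us)
            u.attrs["timestamps"] = np.asarray(scan.us_timestamps)
        if scan.masks is not None:
            f.create_dataset("masks", data=scan.masks.astype(np.uint8))


def read_container(path) -> ScanData:
    """Read and validate a container; schema violations name the culprit."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ValueError(f"{path}: missing root attribute 'schema_version'")
        if int(version) != SCHEMA_VERSION:
            raise ValueError(
                f"{path}: schema_version {version} != supported "
                f"{SCHEMA_VERSION}; upgrade the container")
        if "signals" not in f:
            raise ValueError(f"{path}: missing dataset '/signals'")
        d = f["signals"]
        for attr in _SIGNAL_ATTRS:
            if attr not in d.attrs:
                raise ValueError(
                    f"{path}: /signals missing attribute '{attr}'")
        if "geometry" not in f:
            raise ValueError(f"{path}: missing group '/geometry'")
        geometry = ProbeGeometry.from_dict(
            {k: (v.tolist() if isinstance(v, np.ndarray) else
                 (v.item() if hasattr(v, "item") else v))
             for k, v in f["geometry"].attrs.items()})
        us = us_ts = masks = None
        if "us" in f:
            if "timestamps" not in f["us"].attrs:
                raise ValueError(f"{path}: /us missing attribute 'timestamps'")
            us = f["us"][()]
            us_ts = f["us"].attrs["timestamps"]
        if "masks" in f:
            masks = f["masks"][()]
        return ScanData(
            signals=d[()], sampling_rate=float(d.attrs["sampling_rate"]),
            wavelengths=np.asarray(d.attrs["wavelengths"]),
            timestamps=np.asarray(d.attrs["timestamps"]),
            geometry=geometry, us=us, us_timestamps=us_ts, masks=masks)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from the raw container."""

    lco: int = 700
    alpha: float = 1e-2
    nonneg: bool = True
    max_iterations: int = 10
    inner_iterations: int = 100
    n_motion_frames: int = 3
    reference_wavelength: int = 800
    single_sos_wavelength: int = 800
    frame_duration_s: float = 1.1
    tir: str = "dog"               # "delta" | "dog" | path to a text file
    motion_enabled: bool = True
    seed: int = 0

    def asdict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        payload = json.dumps(self.asdict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def tir_kernel(self, sampling_rate: float) -> TIRKernel:
        if self.tir == "delta":
            return TIRKernel.delta()
        if self.tir == "dog":
            return TIRKernel.derivative_of_gaussian(sampling_rate)
        return TIRKernel.from_text(self.tir)


def _save_stack(path, frame: MultispectralFrame, meta: dict) -> None:
    tifffile.imwrite(path, frame.as_array().astype(np.float32),
                     metadata={"wavelengths_nm": frame.wavelengths, **meta})


def run_pipeline(config: RunConfig, scan: ScanData, outdir) -> dict:
    """Execute the full off-line image-formation DAG on one scan.

    Returns a dict artifact-name -> path.  Deterministic given config + scan.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"config_hash": chash}
    artifacts = {}
    timings = {}
    geometry = scan.geometry
    if config.lco not in LCO_PRESETS:
        raise ValueError(f"step filter: unknown LCO preset {config.lco}")
    spec = LCO_PRESETS[config.lco]
    wavelengths = [int(w) for w in scan.wavelengths]
    n_frames = scan.signals.shape[3]
    if n_frames < config.n_motion_frames:
        raise ValueError(
            f"step motion: need {config.n_motion_frames} frames, "
            f"container has {n_frames}")

    def _step(name, fn):
        t0 = time.perf_counter()
        result = fn()
        timings[name] = time.perf_counter() - t0
        log.info("step %s: %.2f s", name, timings[name])
        return result

    # 1 band-pass filter
    def _filter():
        out = np.empty_like(scan.signals, dtype=float)
        for wi in range(scan.signals.shape[2]):
            for fi in range(n_frames):
                out[:, :, wi, fi] = bandpass(scan.signals[:, :, wi, fi],
                                             spec, scan.sampling_rate)
        return out
    filtered = _step("filter", _filter)
    np.save(outdir / "filtered_signals.npy", filtered)
    artifacts["filtered_signals"] = outdir / "filtered_signals.npy"

    # 2 dual-SoS model-based reconstruction
    tir = config.tir_kernel(scan.sampling_rate)
    model_dual = _step("model_dual",
                       lambda: assemble_forward_model(geometry, tir, "dual"))
    rc = ReconConfig(alpha=config.alpha, nonneg=config.nonneg,
                     max_iterations=config.max_iterations,
                     inner_iterations=config.inner_iterations)

    def _recon_all():
        frames = []
        for fi in range(config.n_motion_frames):
            images = {w: reconstruct(filtered[:, :, wi, fi], model_dual, rc,
                                     wavelength=w).pixels
                      for wi, w in enumerate(wavelengths)}
            frames.append(MultispectralFrame(images, frame_index=fi,
                                             strict=False))
        return frames
    frames = _step("recon_dual", _recon_all)
    for f in frames:
        _save_stack(outdir / f"recon_dual_frame{f.frame_index}.tif", f, meta)
    artifacts["recon_dual"] = outdir / "recon_dual_frame0.tif"

    # 3+4 motion correction and averaging
    def _motion():
        if config.motion_enabled:
            return correct_and_average(
                frames, reference_wavelength=config.reference_wavelength,
                return_fields=True)
        images = {w: np.mean([f.images[w] for f in frames], axis=0)
                  for w in wavelengths}
        return (MultispectralFrame(images,
                                   frames[len(frames) // 2].frame_index,
                                   strict=False), None)
    averaged, motion_fields = _step("motion_average", _motion)
    _save_stack(outdir / "averaged_stack.tif", averaged, meta)
    artifacts["averaged_stack"] = outdir / "averaged_stack.tif"
    if motion_fields is not None:
        with h5py.File(outdir / "motion_fields.h5", "w") as fh:
            fh.attrs["config_hash"] = chash
            for (fi, w), fld in motion_fields["t1"].items():
                fh.create_dataset(f"t1/frame{fi}/wl{w}", data=fld.vectors)
            for fi, fld in motion_fields["t2"].items():
                fh.create_dataset(f"t2/frame{fi}", data=fld.vectors)
        artifacts["motion_fields"] = outdir / "motion_fields.h5"

    # 5 uniform-SoS reconstruction (for the distortion estimate)
    model_uni = _step("model_uniform",
                      lambda: assemble_forward_model(geometry, tir, "uniform"))
    wi_single = wavelengths.index(config.single_sos_wavelength)
    single = _step("recon_single",
                   lambda: reconstruct(filtered[:, :, wi_single, 0],
                                       model_uni, rc).pixels)
    tifffile.imwrite(outdir / "recon_single_sos.tif",
                     single.astype(np.float32), metadata=meta)
    artifacts["recon_single_sos"] = outdir / "recon_single_sos.tif"

    # 6 affine between the two OA variants
    dual_ref = frames[0].images[config.single_sos_wavelength]
    affine = _step("affine", lambda: estimate_affine(dual_ref, single))
    np.savetxt(outdir / "affine.txt", affine.matrix,
               header=f"config_hash={chash}")
    artifacts["affine"] = outdir / "affine.txt"

    # 8+9 US warping and averaging (7: scanner US recon and 10: manual
    # segmentation are container inputs)
    if scan.us is not None:
        warped = _step("us_warp",
                       lambda: [warp_us(USImage(im, float(ts)), affine)
                                for im, ts in zip(scan.us,
                                                  scan.us_timestamps)])
        tifffile.imwrite(outdir / "us_warped.tif",
                         np.stack([u.pixels for u in warped]).astype(
                             np.float32), metadata=meta)
        artifacts["us_warped"] = outdir / "us_warped.tif"

        t0 = float(scan.timestamps[0])
        window = (t0, t0 + config.frame_duration_s)
        us_avg = _step("us_average",
                       lambda: average_concurrent_us(warped, window))
        tifffile.imwrite(outdir / "us_averaged.tif",
                         us_avg.pixels.astype(np.float32), metadata=meta)
        artifacts["us_averaged"] = outdir / "us_averaged.tif"

    sidecar = {
        "config": config.asdict(), "config_hash": chash,
        "schema_version": SCHEMA_VERSION, "timings_s": timings,
        "wavelengths_nm": wavelengths,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    artifacts["provenance"] = outdir / "provenance.json"
    return artifacts
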