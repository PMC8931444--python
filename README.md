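# opus2g

Model-based image formation for handheld optoacoustic–ultrasound (OPUS)
tomography of the breast. The package implements the complete off-line
processing chain of a second-generation handheld scanner that detects
laser-induced ultrasound on a 256-element concave arc coupled through a heavy
water cavity, and interleaves pulse-echo ultrasound frames:

1. **Band-pass filtering** — causal Butterworth cascade (8th-order low-pass at
   8 MHz, 2nd-order high-pass) with three lower-cut-off (LCO) presets: 100,
   300 and 700 kHz. Low LCOs retain bulky, slowly varying absorbers; high
   LCOs emphasize fine vasculature.
2. **Dual speed-of-sound model-based reconstruction** — a sparse linear
   forward model maps the initial-pressure grid to detector traces using
   Fermat (refracted) travel times through the water/tissue interface,
   geometric decay, a temporal-derivative stencil and convolution with the
   detector's total impulse response (TIR). Inversion is non-negative
   Tikhonov-regularized least squares (projected restarted LSQR), with
   optional L-curve selection of the regularization strength α.
3. **Motion-corrected frame compounding** — elastic (free-form) registration
   with a local normalized-cross-correlation variational flow: per-wavelength
   alignment to the 800 nm image inside each multispectral frame (T1, with
   field reuse above 890 nm where blood contrast vanishes), then inter-frame
   alignment to the middle frame (T2), then averaging.
4. **Spectral processing** — per-pixel spectral median over a 40 nm window
   (single-wavelength spike rejection) and non-negative least-squares
   unmixing into HbO₂, Hb, fat and water.
5. **OA/US co-registration** — the scanner beamforms ultrasound under a
   homogeneous speed-of-sound assumption; the resulting distortion is
   estimated as the affine map between dual-SoS and uniform-SoS OA
   reconstructions of the same signals and applied to the US frames, which
   are then averaged over each OA frame's timespan.
6. **Metrics, rendering, simulation** — CNR (variance- or std-denominator)
   and FWHM; local-contrast/sigmoid/power-unsharp display normalization, 2-D
   dual-band colormap fusion, RGB chromophore rendering, hybrid OA-on-US
   overlay; and a synthetic phantom simulator (independent dense forward
   summation, noise and seeded motion injection) that serves as ground truth
   and oracle for every stage.

Scanner raw data is proprietary, so the package defines its own versioned
HDF5 container and ships a phantom generator; everything is exercised
end-to-end on synthetic scans.

## Testing

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per documented
acceptance criterion (forward/adjoint consistency, Fermat-vs-scan travel
times, simulate-then-invert recovery, Tikhonov shrinkage, registration
recovery, motion-free equivalence, unmixing exactness, spike suppression,
the CNR averaging law, equal-SoS degeneracy and Butterworth cut-offs).
`scripts/acceptance.py --seed 1 --out results/acceptance.json` recomputes the
headline quantities from a single seed.

## Worked example

Generate a synthetic scan (64-element desk-scale probe, 101×101 grid, three
wavelengths, three repeat frames) and run the full pipeline:

```bash
opus2g synth --out scan.h5 --elements 32 --grid 51 \
    --wavelengths 790:821:10 --frames 3 --seed 7
opus2g run --in scan.h5 --out run/
```

`run/` then contains the nine artifact classes with a shared config hash:
`filtered_signals.npy`, `recon_dual_frame{0,1,2}.tif`, `averaged_stack.tif`,
`motion_fields.h5`, `recon_single_sos.tif`, `affine.txt`, `us_warped.tif`,
`us_averaged.tif` and `provenance.json` (per-step wall times and the full
configuration). The run is deterministic: re-running with the same container
and config reproduces every artifact bit-for-bit.

Individual stages are available as verbs — `filter`, `recon` (with
`--alpha-grid` for L-curve selection), `motion`, `median`, `unmix`, `coreg`,
`cnr`, `render` — operating on the container, float TIFF stacks (wavelengths
carried in TIFF metadata) and CSV tables.

Representative quantities from `scripts/acceptance.py --seed 1`:

| quantity | value |
| --- | --- |
| forward/adjoint max relative error (20 pairs) | 4.0e-13 |
| Fermat vs breakpoint-scan max relative error (100 pairs) | 2.9e-11 |
| simulate-then-invert Pearson r (101×101, 64 el) | > 0.9999 |
| elastic registration mean endpoint error (3 px warp) | 0.069 px |
| NNLS unmixing max absolute error | 8.2e-15 |
| CNR gain from 3-frame averaging | 4.78 dB (theory 4.77) |
| causal Butterworth cut-off deviation from −3 dB | 0.08% |

## Library layout

| module | contents |
| --- | --- |
| `opus2g.geometry` | probe geometry, grids, TIR kernels |
| `opus2g.travel` | Fermat two-medium travel times |
| `opus2g.forward` | sparse forward-model assembly, adjoint |
| `opus2g.reconstruction` | non-negative Tikhonov LSQR, L-curve |
| `opus2g.filtering` | Butterworth band-pass presets |
| `opus2g.motion` | displacement fields, elastic registration, compounding |
| `opus2g.spectral` | multispectral frames, spectral median, NNLS unmixing |
| `opus2g.coreg` | affine OA/US co-registration, US averaging |
| `opus2g.metrics` | CNR and FWHM |
| `opus2g.viz` | display normalization and renderers |
| `opus2g.phantom` | phantoms, dense signal simulation, noise/motion injection |
| `opus2g.io` | HDF5 container, run configuration, pipeline orchestration |
| `opus2g.cli` | `opus2g` command-line interface |

See `docs/methods.md` for the mathematical model, parameter defaults and
their rationale, and known limitations.
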