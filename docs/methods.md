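# Methods

This document records the mathematical model behind `opus2g`, the default
parameters with their rationale, and the scope and limitations of the
synthetic-data validation.

## Acoustic model

### Geometry

The clinical probe is a concave arc of 256 piezocomposite elements spanning
145° with 60 mm between the endpoint elements, giving an arc radius
`R = 60 / (2 sin 72.5°) ≈ 31.46 mm`. The cavity between the elements and the
tissue is filled with heavy water (speed of sound 1397 m/s at operating
temperature); tissue is modelled as a homogeneous half-space (default
1510 m/s) below a planar interface at depth `interface_depth_mm` (default 0,
i.e. at the arc's chord). The reconstruction grid is 40 × 40 mm at 401 × 401
pixels (0.1 mm pitch); signals are 2304 samples at 40 MS/s.

`desk_geometry()` (64 elements, 101 × 101 grid over 30 × 30 mm, 1024 samples
at 20 MS/s) is the same model at a scale where a full matrix assembly and
inversion runs in seconds on one CPU; all tests use it or smaller variants.

### Travel times (Fermat / dual SoS)

For a tissue pixel `p` and an element `e`, the propagation time is the
minimum over single-breakpoint paths crossing the planar interface:

```
t(x_b) = |e − b| / c_water + |b − p| / c_tissue,   b = (x_b, y_interface)
```

`t(x_b)` is convex in `x_b` and its stationarity condition is Snell's law, so
the breakpoint is located by 90 iterations of vectorized bisection on the
derivative, bracketed by the lateral coordinates of the element and pixel
(interval shrinks by 2⁻⁹⁰, far below 1e−12 relative). Pixels exactly on the
interface go through the same minimization: their fastest path can still run
laterally through the faster medium, and only the pixel directly below the
element degenerates to the straight water-only path. Equal speeds reduce
exactly to the straight-line time; `uniform` mode uses the straight line at
the tissue speed throughout (this is the model mismatch that the OA/US
affine co-registration later estimates).

### Forward model

The sparse operator maps the initial-pressure grid `p` to stacked detector
traces:

* each pixel deposits its amplitude at its travel time by linear
  interpolation between the two neighbouring samples;
* amplitude decays geometrically as `1/√max(r, pitch)` (2-D line-detector
  decay, floored at one pixel pitch to avoid the singularity);
* traces are shaped by a central-difference temporal derivative
  `[0.5, 0, −0.5]·f_s` (optoacoustic signals are the time derivative of the
  spherical mean) and convolved with the total impulse response (TIR) of the
  detection chain.

The TIR is either a measured kernel loaded from text, an identity delta, or a
derivative-of-Gaussian surrogate centred at 4 MHz (the probe's nominal
band). Assembly is chunked (COO → CSC per pixel block, then hstack to CSR);
columns that receive no samples (pixels outside the recording window) are
counted and logged. The adjoint is the exact matrix transpose, verified by
dot tests to < 1e−10.

`phantom.simulate_signals` implements the same physics as an independent
dense per-element accumulation loop, deliberately sharing no code with the
sparse assembly; the two agree to ~1e−16 relative RMS and cross-validate
each other.

## Inversion

Reconstruction solves non-negative Tikhonov least squares

```
min_{p ≥ 0}  ‖M p − s‖² + α ‖p‖²
```

by projected, restarted LSQR on the augmented operator `[M; √α I]`: each
outer restart runs a bounded inner LSQR from the current iterate, projects
onto the non-negative orthant, and accepts the step through a backtracking
line search on the objective, guaranteeing monotone descent. Unconstrained
mode is plain damped LSQR. Defaults (10 restarts × 100 inner iterations)
resolve desk-scale problems to graphical convergence in < 1 s.

**α scale.** Meaningful regularization strengths scale with `σ_max(M)²`
(the matrix includes the `f_s`-scaled derivative stencil, so its norm is
large); sweeps and defaults in tests are expressed as multiples of that
quantity, estimated with a single sparse SVD triplet.

**L-curve.** `select_alpha_lcurve` picks the maximum-curvature point of the
(log residual, log solution norm) curve over a user grid, requiring at least
3 sorted candidates. Curvature uses finite differences with a *speed floor*
of `5e−2 ×` the maximum parametrization speed added to the denominator:
on flat curve segments both derivatives are numerically zero and raw
curvature becomes noise-dominated; the floor suppresses those spurious
maxima while leaving the true corner (where the speed is large) unchanged.
Ties resolve to the larger α (stronger regularization is the safer default).

## Motion correction and compounding

Breathing and hand motion occur both *within* a multispectral frame (one
image per wavelength, acquired sequentially) and *between* repeated frames.
`correct_and_average` applies:

* **T1 (intra-frame):** every wavelength image is elastically registered to
  the frame's 800 nm image. Above 890 nm blood contrast is too weak for
  reliable registration, so the field estimated at the upper edge of the
  700–890 nm band is reused for longer wavelengths.
* **T2 (inter-frame):** each corrected frame's 800 nm image is registered to
  the middle frame's, and the per-frame field is composed with the T1 fields.
* averaging of the aligned stacks.

Elastic registration is an in-house variational flow maximizing local
normalized cross-correlation (window statistics via uniform filters),
with Gaussian-smoothed force (σ = 2 px), per-iteration step capped at 1 px,
field smoothing σ = 0.5 px, 50 iterations per level over a 3-level pyramid
(shrink 4/2/1), and a 9 × 9 px correlation window (`window_radius = 4`).
These defaults recover translations to ~0.05 px and 3 px smooth warps to
< 0.15 px mean endpoint error on smoothed-noise textures. Identical images
short-circuit to an exact zero field, which makes the motion-free
equivalence (`correct_and_average` ≡ plain mean) exact. The displacement
convention is resampling: `warped(x) = img(x + d(x))`; the registration
returns the field aligning moving to fixed, i.e. approximately the negation
of an applied warp.

SimpleITK's displacement-field optimizer was evaluated for this step and
rejected: its gradient-descent steps collapsed to ~0.003 px/iteration on
these textures and endpoint errors stalled at 1–8 px. SimpleITK *is* used
for the affine OA/US stage (below), where its centered affine
initialization and regular-step gradient descent on the full-sampling
correlation metric recover a 2°/1.02×/1.5 px synthetic distortion to
0.2 mdeg / 4e−4 scale / ~1e−3 px.

## Spectral processing

* **Spectral median:** per pixel, the median over a 40 nm window (5
  wavelengths on the 10 nm acquisition grid, truncated at the band edges).
  Chromophore spectra are smooth at this scale, so a single-wavelength
  outlier (laser energy spike, parasitic absorber) cannot move the median.
* **Unmixing:** per-pixel NNLS against a packaged 4-chromophore library
  (HbO₂, Hb, fat, water; 700–970 nm at 10 nm, condition number < 1e4).
  Noiseless non-negative mixtures are recovered to machine precision; the
  non-negativity constraint makes pure-noise pixels resolve to zero rather
  than oscillating.

## OA/US co-registration

The scanner's ultrasound beamformer assumes one homogeneous speed of sound,
so US frames are distorted relative to dual-SoS OA images. Since both OA
variants can be reconstructed from the *same* signals, the distortion is
estimated as the affine transform between the dual-SoS and uniform-SoS
reconstructions and then applied to the US frames. If the optimized
transform does not improve correlation over the identity it is discarded
(identity returned with a warning) — this also makes the equal-SoS
degeneracy exact. US frames acquired during one OA frame's 1.1 s timespan
are averaged after warping.

## Metrics

* **CNR** = `10 log₁₀((μ_obj − μ_bkg) / (σ²_obj + σ²_bkg))` with the
  variance denominator as its primary form (a
  `"std"` switch provides the scale-invariant form). Non-positive contrast
  is reported as flagged/NaN rather than raising. Region masks derive from a
  skin line: object = 15 mm band below it, background = above it.
* **FWHM**: baseline-relative half maximum with linear-interpolated
  crossings on either side of an interior peak.

## Synthetic-data scope and limitations

* All validation is synthetic: phantoms of elliptical absorbers and a skin
  layer, rasterized onto the grid with seeded jitter, converted to initial
  pressure through the chromophore library (optional single-exponential
  depth fluence, off by default to keep inversion ground truth linear).
* Noise injection covers per-channel white noise, channel-shared coherent
  noise (reconstructs onto isochrone rings), multiplicative
  single-wavelength spikes and smooth seeded motion with ground-truth
  fields; it does *not* model element directivity, frequency-dependent
  attenuation, speed-of-sound heterogeneity within tissue, or out-of-plane
  signal.
* The forward model is 2-D; the real probe is a toroidal 3-D aperture.
  Quantities depending on elevational focusing (absolute resolution,
  absolute CNR levels) are not reproduced — acceptance is property-based.
* Reconstruction amplitudes are arbitrary units; no fluence correction means
  chromophore coefficients are relative, not absolute concentrations.
* Clinical image-quality figures require patient data and are out of scope;
  the suite instead verifies the algorithmic laws such figures rest on (e.g.
  the 10·log₁₀(3) ≈ 4.77 dB three-frame averaging gain).
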