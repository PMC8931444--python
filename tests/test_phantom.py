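import numpy as np
import pytest

from opus2g.forward import apply_model, assemble_forward_model
from opus2g.geometry import TIRKernel, desk_geometry
from opus2g.motion import warp_image
from opus2g.phantom import (NoiseSpec, PhantomSpec, Structure,
                            add_signal_noise, inject_noise_and_motion,
                            make_phantom, random_smooth_field,
                            simulate_signals, vessel_grid_spec)
from opus2g.reconstruction import ReconConfig, reconstruct
from opus2g.spectral import (CHROMOPHORE_NAMES, ChromophoreLibrary,
                             MultispectralFrame, unmix)
from opus2g.travel import compute_travel_time


@pytest.fixture(scope="module")
def lib():
    return ChromophoreLibrary.default()


class TestMakePhantom:
    def test_empty_spec_gives_zero_maps(self, mini_geometry):
        ph = make_phantom(PhantomSpec(()), mini_geometry)
        assert ph.chromophore_maps.shape == mini_geometry.grid_shape + (4,)
        assert not ph.chromophore_maps.any()

    def test_seed_reproducibility(self, mini_geometry):
        spec = vessel_grid_spec()
        a = make_phantom(spec, mini_geometry, seed=3).chromophore_maps
        b = make_phantom(spec, mini_geometry, seed=3).chromophore_maps
        c = make_phantom(spec, mini_geometry, seed=4).chromophore_maps
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)    # jitter moves the vessels

    def test_disk_rasterized_where_expected(self, mini_geometry):
        spec = PhantomSpec((Structure("ellipse", (0.0, 15.0), (4.0, 4.0),
                                      {"Hb": 2.0}),))
        ph = make_phantom(spec, mini_geometry)
        hb = ph.chromophore_maps[..., CHROMOPHORE_NAMES.index("Hb")]
        y, x = mini_geometry.grid_coordinates_mm()
        xx, yy = np.meshgrid(x, y)
        inside = (xx ** 2 + (yy - 15.0) ** 2) <= 16.0
        assert np.array_equal(hb == 2.0, inside)

    def test_skin_layer_spans_width(self, mini_geometry):
        spec = PhantomSpec((Structure("skin", (0.0, 2.0), (0.0, 1.0),
                                      {"water": 1.0}),))
        ph = make_phantom(spec, mini_geometry)
        water = ph.chromophore_maps[..., CHROMOPHORE_NAMES.index("water")]
        y, _ = mini_geometry.grid_coordinates_mm()
        rows = (y >= 2.0) & (y <= 3.0)
        assert np.all(water[rows] == 1.0) and not water[~rows].any()

    def test_structure_outside_fov_rejected(self, mini_geometry):
        spec = PhantomSpec((Structure("ellipse", (0.0, 15.0), (40.0, 4.0),
                                      {"Hb": 1.0}),))
        with pytest.raises(ValueError, match="field of view"):
            make_phantom(spec, mini_geometry)

    def test_invalid_structure_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            Structure("cube", (0, 0), (1, 1), {})
        with pytest.raises(ValueError, match="non-negative"):
            Structure("ellipse", (0, 0), (1, 1), {"Hb": -1.0})

    def test_hb_disk_pressure_falls_700_to_880(self, mini_geometry, lib):
        spec = PhantomSpec((Structure("ellipse", (0.0, 15.0), (3.0, 3.0),
                                      {"Hb": 1.0}),))
        ph = make_phantom(spec, mini_geometry)
        assert (ph.pressure_map(700, lib).sum()
                > ph.pressure_map(880, lib).sum())

    def test_fluence_damps_with_depth(self, mini_geometry, lib):
        spec = PhantomSpec((Structure("ellipse", (0.0, 15.0), (3.0, 3.0),
                                      {"Hb": 1.0}),))
        ph = make_phantom(spec, mini_geometry)
        p0 = ph.pressure_map(800, lib)
        p1 = ph.pressure_map(800, lib, fluence_mu_eff_per_cm=1.0)
        nz = p0 > 0
        assert np.all(p1[nz] < p0[nz])


class TestSimulateSignals:
    def test_zero_pressure_gives_zero_signals(self, mini_geometry):
        out = simulate_signals(np.zeros(mini_geometry.grid_shape),
                               mini_geometry, TIRKernel.delta())
        assert out.shape == (mini_geometry.n_elements,
                             mini_geometry.n_samples)
        assert not out.any()

    def test_single_pixel_onset_sample(self, mini_geometry):
        p = np.zeros(mini_geometry.grid_shape)
        p[15, 15] = 1.0
        sig = simulate_signals(p, mini_geometry, TIRKernel.delta())
        pix = mini_geometry.pixel_positions_mm()[15 * 31 + 15]
        el = mini_geometry.element_positions_mm[0]
        t = compute_travel_time(pix, el, mini_geometry)
        k = int(np.floor(t * mini_geometry.sampling_rate))
        first = np.flatnonzero(sig[0])[0]
        # derivative stencil reaches one sample before the arrival bin
        assert abs(first - k) <= 1

    def test_matches_sparse_forward_model(self, mini_geometry, mini_model,
                                          rng):
        img = rng.random(mini_geometry.grid_shape)
        a = simulate_signals(img, mini_geometry, TIRKernel.delta())
        b = apply_model(mini_model, img)
        rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b ** 2))
        assert rms < 0.02

    def test_shape_mismatch_rejected(self, mini_geometry):
        with pytest.raises(ValueError, match="grid"):
            simulate_signals(np.zeros((3, 3)), mini_geometry,
                             TIRKernel.delta())

    def test_linearity(self, mini_geometry, rng):
        a = rng.random(mini_geometry.grid_shape)
        b = rng.random(mini_geometry.grid_shape)
        tir = TIRKernel.delta()
        sab = simulate_signals(a + 2.0 * b, mini_geometry, tir)
        sa = simulate_signals(a, mini_geometry, tir)
        sb = simulate_signals(b, mini_geometry, tir)
        assert np.allclose(sab, sa + 2.0 * sb, atol=1e-12)


class TestNoise:
    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            NoiseSpec(white_sigma=-0.1)

    def test_zero_noise_is_identity(self, rng):
        sig = rng.standard_normal((4, 64))
        out = add_signal_noise(sig, NoiseSpec())
        assert np.array_equal(out, sig)

    def test_coherent_noise_shared_across_channels(self):
        out = add_signal_noise(np.zeros((4, 128)),
                               NoiseSpec(coherent_amp=0.5))
        for ch in range(1, 4):
            assert np.array_equal(out[ch], out[0])
        assert out.std() == pytest.approx(0.5, rel=0.3)

    def test_white_noise_independent_across_channels(self):
        out = add_signal_noise(np.zeros((2, 4096)),
                               NoiseSpec(white_sigma=1.0))
        r = np.corrcoef(out[0], out[1])[0, 1]
        assert abs(r) < 0.1

    def test_seeded_reproducibility(self, rng):
        sig = rng.standard_normal((4, 64))
        ns = NoiseSpec(white_sigma=0.3, coherent_amp=0.2, seed=7)
        assert np.array_equal(add_signal_noise(sig, ns),
                              add_signal_noise(sig, ns))


class TestRandomSmoothField:
    def test_zero_amplitude_is_zero_field(self):
        f = random_smooth_field((32, 32), 0.0, np.random.default_rng(0))
        assert f.is_zero

    def test_peak_magnitude_equals_max_px(self):
        f = random_smooth_field((64, 64), 2.5, np.random.default_rng(1))
        assert f.magnitude().max() == pytest.approx(2.5, abs=1e-9)

    def test_quarter_guard(self):
        with pytest.raises(ValueError, match="quarter"):
            random_smooth_field((32, 32), 9.0, np.random.default_rng(0))

    def test_seeded_reproducibility(self):
        a = random_smooth_field((32, 32), 2.0, np.random.default_rng(5))
        b = random_smooth_field((32, 32), 2.0, np.random.default_rng(5))
        assert np.array_equal(a.vectors, b.vectors)


class TestInjectNoiseAndMotion:
    def make_frames(self, rng, n=2, wls=(800, 850)):
        base = rng.random((32, 32))
        return [MultispectralFrame({w: base for w in wls}, i, strict=False)
                for i in range(n)]

    def test_identity_when_disabled(self, rng):
        frames = self.make_frames(rng)
        out, truth = inject_noise_and_motion(frames, NoiseSpec())
        for f, g in zip(frames, out):
            for w in f.wavelengths:
                assert np.array_equal(f.images[w], g.images[w])
        assert all(truth["fields"][k].is_zero for k in truth["fields"])

    def test_reproducible(self, rng):
        frames = self.make_frames(rng)
        ns = NoiseSpec(spike_prob=0.05)
        a, _ = inject_noise_and_motion(frames, ns, inter_frame_px=2.0,
                                       intra_frame_px=0.5, seed=9)
        b, _ = inject_noise_and_motion(frames, ns, inter_frame_px=2.0,
                                       intra_frame_px=0.5, seed=9)
        for f, g in zip(a, b):
            for w in f.wavelengths:
                assert np.array_equal(f.images[w], g.images[w])

    def test_returned_field_is_the_applied_warp(self, rng):
        frames = self.make_frames(rng, n=1)
        out, truth = inject_noise_and_motion(frames, NoiseSpec(),
                                             inter_frame_px=2.0,
                                             intra_frame_px=0.5, seed=3)
        for w in frames[0].wavelengths:
            d = truth["fields"][(0, w)]
            expected = warp_image(frames[0].images[w], d)
            assert np.array_equal(out[0].images[w], expected)

    def test_spikes_multiply_single_pixels(self, rng):
        frames = self.make_frames(rng, n=1)
        ns = NoiseSpec(spike_prob=0.1, spike_gain=5.0, seed=2)
        out, _ = inject_noise_and_motion(frames, ns)
        for w in frames[0].wavelengths:
            ratio = out[0].images[w] / frames[0].images[w]
            assert set(np.round(np.unique(ratio), 9)) <= {1.0, 5.0}


class TestEndToEnd:
    def test_chromophore_argmax_recovered(self, mini_geometry, mini_model,
                                          lib):
        # phantom -> simulate -> non-negative reconstruction per wavelength
        # -> NNLS unmixing recovers the dominant chromophore in each vessel
        spec = PhantomSpec((
            Structure("ellipse", (-5.0, 12.0), (3.0, 3.0), {"HbO2": 1.0}),
            Structure("ellipse", (5.0, 12.0), (3.0, 3.0), {"Hb": 1.0}),
        ))
        ph = make_phantom(spec, mini_geometry, seed=0)
        import scipy.sparse.linalg as spla
        smax2 = spla.svds(mini_model.matrix, k=1,
                          return_singular_vectors=False)[0] ** 2
        images = {}
        for w in (700, 730, 760, 800, 850, 900):
            s = simulate_signals(ph.pressure_map(w, lib), mini_geometry,
                                 TIRKernel.delta())
            images[w] = reconstruct(s, mini_model,
                                    ReconConfig(alpha=1e-6 * smax2,
                                                nonneg=True)).pixels
        out = unmix(MultispectralFrame(images, strict=False), lib)
        argmax = np.stack([out[n] for n in CHROMOPHORE_NAMES]).argmax(axis=0)
        for name in ("HbO2", "Hb"):
            idx = CHROMOPHORE_NAMES.index(name)
            mask = ph.chromophore_maps[..., idx] > 0
            assert np.mean(argmax[mask] == idx) >= 0.95
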