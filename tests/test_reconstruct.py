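"""Spectral reconstruction chain: reference, apodization, k-resampling, FFT."""

import numpy as np
import pytest

from pericarp_ocm import (
    AScan,
    KResampler,
    OpticalConfig,
    PipelineConfig,
    ReconstructionError,
    ScanConfig,
    SeedPhantom,
    assemble_tomogram,
    compute_reference,
    fringe_spectrum,
    load_tomogram,
    preprocess,
    resample_to_wavenumber,
    save_tomogram,
    simulate_tomogram,
    to_ascan,
)
from pericarp_ocm.reconstruct import get_window, reconstruct_spectra


def _no_reference(spec):
    return np.zeros_like(spec)


class TestReference:
    def test_identical_spectra_subtract_to_zero(self):
        s = np.random.default_rng(0).random(64)
        stack = np.tile(s, (5, 1))
        ref = compute_reference(stack)
        np.testing.assert_allclose(stack - ref, 0.0, atol=1e-14)

    def test_symmetric_pair_recovers_center(self):
        rng = np.random.default_rng(1)
        s, d = rng.random(64), rng.random(64)
        ref = compute_reference(np.stack([s + d, s - d]))
        np.testing.assert_allclose(ref, s, atol=1e-14)

    def test_matches_elementwise_mean_loop(self):
        rng = np.random.default_rng(2)
        cube = rng.random((2, 4, 2, 32))
        ref = compute_reference(cube)
        expected = np.zeros(32)
        count = 0
        for a in range(2):
            for b in range(4):
                for c in range(2):
                    expected += cube[a, b, c]
                    count += 1
        np.testing.assert_allclose(ref, expected / count, atol=1e-12)

    def test_empty_acquisition_raises(self):
        with pytest.raises(ReconstructionError):
            compute_reference(np.empty((0, 64)))


class TestPreprocess:
    def test_raw_equal_reference_gives_zero_any_window(self):
        rng = np.random.default_rng(3)
        s = rng.random(64)
        for window in (np.hanning(64), np.ones(64)):
            np.testing.assert_array_equal(preprocess(s, s, window), np.zeros(64))

    def test_rectangular_window_is_pure_subtraction(self):
        rng = np.random.default_rng(4)
        raw, ref = rng.random(64), rng.random(64)
        np.testing.assert_allclose(
            preprocess(raw, ref, np.ones(64)), raw - ref, atol=1e-15
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ReconstructionError):
            preprocess(np.ones(64), np.ones(32), np.ones(64))

    def test_hann_sidelobes_below_minus_31_db(self, optical_default):
        spec = fringe_spectrum(optical_default, 2000.0, 1e-4)
        mags, pitch = reconstruct_spectra(
            spec, optical_default.wavelength_nm, reference=_no_reference(spec)
        )
        peak_bin = int(np.argmax(mags[5:])) + 5
        peak = mags[peak_bin]
        aside = np.concatenate([mags[5 : peak_bin - 4], mags[peak_bin + 5 :]])
        assert aside.max() / peak <= 10 ** (-31 / 20)


class TestResampling:
    def test_constant_spectrum_stays_constant(self, optical_default):
        lam = optical_default.wavelength_nm
        out = resample_to_wavenumber(np.full(lam.size, 2.5), lam)
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_equidistant_k_input_is_fixed_point(self):
        k = np.linspace(5.9, 6.3, 256)  # rad/nm, equidistant
        lam = 2 * np.pi / k[::-1]  # strictly increasing wavelengths
        rng = np.random.default_rng(5)
        smooth = np.cumsum(rng.standard_normal(256))
        smooth = np.convolve(smooth, np.ones(16) / 16, mode="same")
        out = resample_to_wavenumber(smooth, lam)
        # output is ordered by ascending k, i.e. reversed relative to lambda
        np.testing.assert_allclose(
            out[::-1], smooth, atol=1e-9 * np.abs(smooth).max()
        )

    def test_endpoints_preserved(self, optical_default):
        lam = optical_default.wavelength_nm
        rng = np.random.default_rng(6)
        y = rng.random(lam.size)
        out = resample_to_wavenumber(y, lam)
        assert out[0] == pytest.approx(y[-1], abs=1e-12)  # k ascending = lam reversed
        assert out[-1] == pytest.approx(y[0], abs=1e-12)

    def test_chirp_removal_boosts_deep_peak(self, optical_default):
        spec = fringe_spectrum(optical_default, 2000.0, 1e-4)
        with_rs, _ = reconstruct_spectra(
            spec, optical_default.wavelength_nm, reference=_no_reference(spec)
        )
        without_rs, _ = reconstruct_spectra(
            spec,
            optical_default.wavelength_nm,
            PipelineConfig(resample=False),
            reference=_no_reference(spec),
        )
        assert with_rs.max() >= 5.0 * without_rs[5:].max()

    def test_batch_operator_matches_spline_path(self, optical_default):
        lam = optical_default.wavelength_nm
        rng = np.random.default_rng(7)
        stack = rng.random((64, lam.size))
        resampler = KResampler(lam)
        batch = resampler(stack)
        single = np.stack([resampler(row) for row in stack])
        np.testing.assert_allclose(batch, single, atol=1e-9)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ReconstructionError):
            KResampler(np.array([1000.0, 999.0, 1001.0, 1002.0]))


class TestToAScan:
    def test_half_length_output(self):
        ascan = to_ascan(np.random.default_rng(8).random(2048), dk=1e-5)
        assert isinstance(ascan, AScan)
        assert ascan.magnitude.shape == (1024,)

    def test_zero_spectrum_gives_zero_ascan(self):
        ascan = to_ascan(np.zeros(256), dk=1e-5)
        np.testing.assert_array_equal(ascan.magnitude, 0.0)

    def test_odd_length_rejected(self):
        with pytest.raises(ReconstructionError):
            to_ascan(np.zeros(255), dk=1e-5)

    def test_cosine_reflector_at_analytic_bin(self, optical_default):
        depth = 500.0
        spec = fringe_spectrum(optical_default, depth, 1e-4)
        mags, pitch = reconstruct_spectra(
            spec, optical_default.wavelength_nm, reference=_no_reference(spec)
        )
        # skip the DC region: without reference subtraction it dominates
        assert abs(int(np.argmax(mags[5:])) + 5 - round(depth / pitch)) <= 1

    def test_mirror_symmetry_of_full_transform(self):
        rng = np.random.default_rng(9)
        real_signal = rng.standard_normal(256)
        full = np.abs(np.fft.fft(real_signal))
        np.testing.assert_allclose(full[1:], full[1:][::-1], atol=1e-10)

    def test_linearity_before_magnitude(self, optical_default):
        lam = optical_default.wavelength_nm
        rng = np.random.default_rng(10)
        a, b = rng.random(lam.size), rng.random(lam.size)
        win = get_window("hann", lam.size)
        resampler = KResampler(lam)

        def complex_pipeline(x):
            z, _ = to_ascan(resampler(preprocess(x, np.zeros_like(x), win)),
                            resampler.dk, return_complex=True)
            return z

        lhs = complex_pipeline(2.0 * a + 3.0 * b)
        rhs = 2.0 * complex_pipeline(a) + 3.0 * complex_pipeline(b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestAssemble:
    def test_volume_shape_contract(self, optical_small):
        phantom = SeedPhantom(mean_thickness_um=50.0, thickness_sd_um=0.0)
        scan = ScanConfig(nx=8, ny=8, x_extent_mm=0.4, y_extent_mm=0.4)
        acq = simulate_tomogram(phantom, optical_small, scan, rng_seed=0)
        tom = assemble_tomogram(acq)
        assert tom.volume.shape == (256, 8, 8)
        assert tom.dx_um == pytest.approx(50.0)
        assert tom.dz_um == pytest.approx(optical_small.depth_pitch_um, rel=1e-6)

    def test_missing_spectra_reported(self, optical_small):
        phantom = SeedPhantom(mean_thickness_um=50.0, thickness_sd_um=0.0)
        scan = ScanConfig(nx=4, ny=4, x_extent_mm=0.2, y_extent_mm=0.2)
        acq = simulate_tomogram(phantom, optical_small, scan, rng_seed=0)
        acq.spectra[1, 2] = np.nan
        with pytest.raises(ReconstructionError, match=r"\[1, 2\]"):
            assemble_tomogram(acq)

    def test_repeat_averaging_reduces_background_noise_sqrt10(self, optical_small):
        """Magnitude-averaging 10 repeats shrinks background SD by ~sqrt(10)."""
        phantom = SeedPhantom(mean_thickness_um=50.0, thickness_sd_um=0.0)
        far = dict(x_extent_mm=0.3, y_extent_mm=0.3, x_center_mm=8.0, y_center_mm=8.0)
        scan1 = ScanConfig(nx=12, ny=12, repeats_per_pixel=1, **far)
        scan10 = ScanConfig(nx=12, ny=12, repeats_per_pixel=10, **far)
        tom1 = assemble_tomogram(simulate_tomogram(phantom, optical_small, scan1, 3))
        tom10 = assemble_tomogram(simulate_tomogram(phantom, optical_small, scan10, 3))
        bg1 = tom1.volume[20:200].std()
        bg10 = tom10.volume[20:200].std()
        assert bg10 / bg1 == pytest.approx(0.316, abs=0.1)

    def test_sphere_phantom_ring_radius(self, optical_small):
        """En-face max-signal ring at the equatorial slice sits within two
        lateral pixels of the true sphere radius."""
        radius = 400.0
        phantom = SeedPhantom(
            center_um=(600.0, 600.0, 900.0),
            semi_axes_um=(radius, radius, radius),
            mean_thickness_um=50.0,
            thickness_sd_um=0.0,
        )
        optical = OpticalConfig(camera_pixels=512, focus_depth_um=900.0)
        scan = ScanConfig(nx=48, ny=48, x_extent_mm=1.2, y_extent_mm=1.2,
                          x_center_mm=0.6, y_center_mm=0.6)
        tom = assemble_tomogram(simulate_tomogram(phantom, optical, scan, 2))
        z_eq = int(round(900.0 / tom.dz_um))
        img = tom.volume[z_eq].astype(float)
        rows, cols = np.indices(img.shape)
        r_um = np.hypot(rows - 23.5, cols - 23.5) * tom.dx_um
        # max-signal radius from an azimuthally averaged radial profile
        edges = np.arange(0.0, 600.0, tom.dx_um)
        idx = np.digitize(r_um.ravel(), edges)
        prof = np.array(
            [img.ravel()[idx == i].mean() if (idx == i).any() else 0.0
             for i in range(1, len(edges))]
        )
        ring_radius_um = edges[int(np.argmax(prof))] + 0.5 * tom.dx_um
        assert abs(ring_radius_um - radius) <= 2 * tom.dx_um

    def test_tomogram_tiff_round_trip(self, tmp_path, optical_small):
        phantom = SeedPhantom(mean_thickness_um=50.0, thickness_sd_um=0.0)
        scan = ScanConfig(nx=4, ny=4, x_extent_mm=0.2, y_extent_mm=0.2)
        tom = assemble_tomogram(simulate_tomogram(phantom, optical_small, scan, 0))
        path = tmp_path / "vol.tiff"
        save_tomogram(path, tom)
        back = load_tomogram(path)
        np.testing.assert_array_equal(back.volume, tom.volume)
        assert back.dz_um == pytest.approx(tom.dz_um)
        assert back.meta["window"] == "hann"
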