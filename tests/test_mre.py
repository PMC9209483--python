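"""MRE inversion: unwrapping, temporal Fourier, radial profile, Bessel fit."""

import numpy as np
import pytest
from scipy import special

from adipomech import mre
from adipomech import synthetic as syn


def _acquisition(phase, f=800.0, pixel=0.15e-3, r_cyl=4e-3, xi=4e4):
    return mre.MREAcquisition(phase=phase, frequency=f, pixel_size=pixel,
                              cylinder_radius=r_cyl, encoding_efficiency=xi)


def _wave_image(field, mask, f=800.0):
    return mre.ComplexWaveImage(field=field, mask=mask, frequency=f)


class TestUnwrap:
    def test_no_jumps_is_identity_up_to_mean(self):
        rng = np.random.default_rng(0)
        phase = np.tile(rng.uniform(-1.0, 1.0, (64, 64)), (4, 1, 1))
        acq = _acquisition(phase)
        movie, flags = mre.unwrap_phase(acq)
        mask = acq.mask()
        for frame, orig in zip(movie, phase):
            np.testing.assert_allclose(frame[mask],
                                       orig[mask] - orig[mask].mean(),
                                       atol=1e-10)
        assert flags == ()

    def test_wrapped_linear_ramp_restored(self):
        """A 4π ramp across the field survives wrap → unwrap."""
        ny = nx = 64
        xx = np.linspace(0, 4 * np.pi, nx)
        ramp = np.tile(xx, (ny, 1))
        wrapped = np.angle(np.exp(1j * ramp))
        acq = _acquisition(np.tile(wrapped, (4, 1, 1)))
        movie, _ = mre.unwrap_phase(acq)
        mask = acq.mask()
        expected = ramp[mask] - ramp[mask].mean()
        np.testing.assert_allclose(movie[0][mask], expected, atol=1e-6)

    def test_checkerboard_noise_flagged_high_residue(self):
        rng = np.random.default_rng(1)
        noise = rng.uniform(-np.pi, np.pi, (4, 64, 64))
        acq = _acquisition(noise)
        assert mre.phase_residue_count(noise[0]) > 100
        with pytest.warns(UserWarning, match="residue"):
            _, flags = mre.unwrap_phase(acq)
        assert mre.FLAG_HIGH_RESIDUE in flags

    def test_empty_mask_raises(self):
        phase = np.zeros((4, 16, 16))
        acq = mre.MREAcquisition(phase=phase, frequency=800.0,
                                 pixel_size=0.15e-3, cylinder_radius=4e-3,
                                 center=(200.0, 200.0))
        with pytest.raises(ValueError, match="mask"):
            acq.mask()


class TestTemporalFourier:
    def test_exact_harmonic_real_amplitude(self):
        acq_shape, xi, A = (16, 16), 4e4, 2e-6
        j = np.arange(8)
        movie = np.array([np.full(acq_shape, xi * A * np.cos(2 * np.pi * jj / 8))
                          for jj in j])
        acq = _acquisition(np.zeros((8, *acq_shape)), r_cyl=2e-3)
        img = mre.temporal_fourier(movie, acq)
        m = acq.mask()
        np.testing.assert_allclose(img.field[m], A, rtol=1e-12)

    def test_phase_follows_negative_exponential_convention(self):
        """φ = ξA·cos(ωt + π/3) → |U| = A, arg U = −π/3 under u = Re[U e^{−iωt}]."""
        xi, A = 4e4, 2e-6
        j = np.arange(8)
        movie = np.array([np.full((16, 16),
                                  xi * A * np.cos(2 * np.pi * jj / 8 + np.pi / 3))
                          for jj in j])
        acq = _acquisition(np.zeros((8, 16, 16)), r_cyl=2e-3)
        img = mre.temporal_fourier(movie, acq)
        m = acq.mask()
        np.testing.assert_allclose(np.abs(img.field[m]), A, rtol=1e-12)
        np.testing.assert_allclose(np.angle(img.field[m]), -np.pi / 3,
                                   atol=1e-12)

    def test_static_field_gives_zero(self):
        movie = np.ones((8, 16, 16))
        acq = _acquisition(np.zeros((8, 16, 16)), r_cyl=2e-3)
        img = mre.temporal_fourier(movie, acq)
        np.testing.assert_allclose(np.abs(img.field), 0.0, atol=1e-15)


class TestRadialAverage:
    def test_symmetric_field_matches_generator(self):
        ny = nx = 64
        pixel, r_cyl = 0.15e-3, 4e-3
        cy = cx = (ny - 1) / 2
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = np.hypot(yy - cy, xx - cx) * pixel
        k = 1200.0 - 250.0j
        field = special.jv(0, k * r)
        mask = r <= r_cyl
        prof = mre.radial_average(_wave_image(field, mask), (cy, cx), pixel,
                                  r_cyl, n_bins=24)
        ok = np.isfinite(prof.u) & (prof.counts > 4)
        model = special.jv(0, k * prof.r[ok])
        np.testing.assert_allclose(prof.u[ok], model, rtol=0.15, atol=0.03)

    def test_constant_field_constant_profile(self):
        mask = np.ones((32, 32), bool)
        prof = mre.radial_average(_wave_image(np.full((32, 32), 2 + 1j), mask),
                                  (15.5, 15.5), 1e-4, 1.5e-3, n_bins=10)
        ok = np.isfinite(prof.u)
        np.testing.assert_allclose(prof.u[ok], 2 + 1j)

    def test_azimuthal_harmonic_cancels(self):
        ny = nx = 65
        yy, xx = np.mgrid[0:ny, 0:nx]
        theta = np.arctan2(yy - 32, xx - 32)
        field = np.cos(theta).astype(complex)
        mask = np.ones((ny, nx), bool)
        prof = mre.radial_average(_wave_image(field, mask), (32, 32), 1e-4,
                                  3e-3, n_bins=12)
        ok = np.isfinite(prof.u) & (prof.counts > 8)
        np.testing.assert_allclose(np.abs(prof.u[ok]), 0.0, atol=0.05)

    def test_center_outside_image_raises(self):
        mask = np.ones((16, 16), bool)
        with pytest.raises(ValueError, match="center"):
            mre.radial_average(_wave_image(np.zeros((16, 16), complex), mask),
                               (50, 50), 1e-4, 1e-3)


class TestCylinderFit:
    def test_noiseless_bessel_profile_recovery(self):
        k = 2000.0 - 150.0j
        r = np.linspace(0.05e-3, 4e-3, 32)
        u = 1e-5 * special.jv(0, k * r)
        prof = mre.RadialProfile(r=r, u=u, counts=np.full(32, 10),
                                 dispersion=np.zeros(32))
        fit = mre.fit_cylinder_wave(prof, 2 * np.pi * 1000.0)
        assert fit.k_real == pytest.approx(2000.0, rel=1e-6)
        assert fit.k_imag == pytest.approx(-150.0, rel=1e-6)

    def test_lossless_profile_gives_zero_kpp_and_infinite_a(self):
        k = 1500.0
        r = np.linspace(0.05e-3, 4e-3, 32)
        u = (2e-5 + 0j) * special.jv(0, k * r)
        prof = mre.RadialProfile(r=r, u=u, counts=np.full(32, 10),
                                 dispersion=np.zeros(32))
        fit = mre.fit_cylinder_wave(prof, 2 * np.pi * 800.0)
        assert fit.k_real == pytest.approx(1500.0, rel=1e-6)
        assert fit.k_imag == pytest.approx(0.0, abs=1e-3)

    def test_gauge_invariance_of_wavenumber(self):
        """A global complex factor changes U0 but not k*."""
        k = 1800.0 - 300.0j
        r = np.linspace(0.05e-3, 4e-3, 32)
        u = 1e-5 * special.jv(0, k * r)
        prof1 = mre.RadialProfile(r=r, u=u, counts=np.full(32, 10),
                                  dispersion=np.zeros(32))
        gauge = 3.7 * np.exp(1.1j)
        prof2 = mre.RadialProfile(r=r, u=gauge * u, counts=np.full(32, 10),
                                  dispersion=np.zeros(32))
        f1 = mre.fit_cylinder_wave(prof1, 2 * np.pi * 1000.0)
        f2 = mre.fit_cylinder_wave(prof2, 2 * np.pi * 1000.0)
        assert f2.k_real == pytest.approx(f1.k_real, rel=1e-8)
        assert f2.k_imag == pytest.approx(f1.k_imag, rel=1e-8)
        assert f2.amplitude == pytest.approx(gauge * f1.amplitude, rel=1e-6)

    def test_noisy_profile_monte_carlo_recovery(self):
        """5% complex noise, 32 bins: median k′ within 2%, k″ within 10%."""
        k = 2000.0 - 150.0j
        r = np.linspace(0.05e-3, 4e-3, 32)
        clean = 1e-5 * special.jv(0, k * r)
        scale = 0.05 * np.abs(clean).max()
        kps, kpps = [], []
        rng = np.random.default_rng(42)
        for _ in range(100):
            noisy = clean + scale * (rng.standard_normal(32)
                                     + 1j * rng.standard_normal(32))
            prof = mre.RadialProfile(r=r, u=noisy, counts=np.full(32, 10),
                                     dispersion=np.zeros(32))
            fit = mre.fit_cylinder_wave(prof, 2 * np.pi * 1000.0)
            kps.append(fit.k_real)
            kpps.append(fit.k_imag)
        assert np.median(kps) == pytest.approx(2000.0, rel=0.02)
        assert np.median(kpps) == pytest.approx(-150.0, rel=0.10)

    def test_all_zero_profile_raises(self):
        r = np.linspace(0.05e-3, 4e-3, 32)
        prof = mre.RadialProfile(r=r, u=np.zeros(32, complex),
                                 counts=np.full(32, 10),
                                 dispersion=np.zeros(32))
        with pytest.raises(ValueError, match="zero"):
            mre.fit_cylinder_wave(prof, 2 * np.pi * 800.0)

    def test_too_few_bins_raises(self):
        r = np.linspace(0.1e-3, 4e-3, 5)
        prof = mre.RadialProfile(r=r, u=np.ones(5, complex),
                                 counts=np.full(5, 10),
                                 dispersion=np.zeros(5))
        with pytest.raises(ValueError, match="8"):
            mre.fit_cylinder_wave(prof, 2 * np.pi * 800.0)


class TestConversions:
    def test_speed_and_penetration_oracle(self):
        """ω = 2π·1000, k = 2000 − 500i → c = π, a = 2 (direct formula)."""
        c, a = mre.speed_and_penetration(2000.0 - 500.0j, 2 * np.pi * 1000.0)
        assert c == pytest.approx(np.pi, rel=1e-12)
        assert a == pytest.approx(2.0, rel=1e-12)

    def test_lossless_gives_infinite_penetration(self):
        c, a = mre.speed_and_penetration(1500.0 + 0j, 2 * np.pi * 800.0)
        assert np.isinf(a)

    def test_positive_kpp_warns(self):
        with pytest.warns(UserWarning, match="amplification"):
            _, a = mre.speed_and_penetration(1500.0 + 100.0j, 2 * np.pi * 800.0)
        assert a < 0

    def test_frequency_homogeneity(self):
        k = 1800.0 - 250.0j
        c1, a1 = mre.speed_and_penetration(k, 2 * np.pi * 500.0)
        c2, a2 = mre.speed_and_penetration(k, 2 * np.pi * 1000.0)
        assert c2 == pytest.approx(2 * c1)
        assert a2 == pytest.approx(2 * a1)

    def test_modulus_from_ca_oracle(self):
        """c = 3.1416 m/s, a = 2 m/s, ρ = 1000 → G′ ≈ 8.196 kPa, G″ ≈ 4.371 kPa
        (frozen from exact complex arithmetic at 25-digit precision)."""
        g = mre.shear_modulus_from_ca(3.1416, 2.0, 1000.0)
        assert g.real == pytest.approx(8196.24253473497, rel=1e-10)
        assert g.imag == pytest.approx(4371.340936876, rel=1e-10)

    def test_elastic_limit_is_rho_c_squared(self):
        g = mre.shear_modulus_from_ca(3.0, np.inf, 1000.0)
        assert g == pytest.approx(9000.0 + 0j)

    def test_round_trip_identity_with_wavenumber(self):
        """G*(c(k), a(k)) = ρω²/k*² to machine precision."""
        rho, omega = 1000.0, 2 * np.pi * 800.0
        for k in (2000.0 - 150.0j, 800.0 - 400.0j, 1500.0 - 1e-7j):
            c, a = mre.speed_and_penetration(k, omega)
            g = mre.shear_modulus_from_ca(c, a, rho)
            expected = rho * omega**2 / k**2
            assert abs(g - expected) / abs(expected) < 1e-12

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            mre.shear_modulus_from_ca(-1.0, 2.0, 1000.0)
        with pytest.raises(ValueError):
            mre.shear_modulus_from_ca(3.0, 2.0, -5.0)
        with pytest.raises(ValueError):
            mre.speed_and_penetration(-100.0 + 0j, 2 * np.pi * 800.0)


class TestEndToEnd:
    def test_noiseless_movie_recovery_within_2pct(self):
        spec = syn.MRESpec(frequency=800.0, wave_speed=3.0,
                           penetration_rate=2.0)
        acq, truth = syn.gen_mre_movie(spec)
        fit = mre.invert_acquisition(acq)
        assert fit.g_storage == pytest.approx(truth["g_storage_Pa"], rel=0.02)
        assert fit.g_loss == pytest.approx(truth["g_loss_Pa"], rel=0.02)

    def test_power_law_medium_monotone_storage_over_sweep(self):
        """G′(f) of a power-law medium rises monotonically over the sweep."""
        freqs = (400.0, 600.0, 800.0, 1000.0, 1400.0)
        rho = 1000.0
        gps = []
        for f in freqs:
            g = 5000.0 * (1 + 0.3j) * (f / 400.0) ** 0.25
            omega = 2 * np.pi * f
            k = omega * np.sqrt(rho / g)
            if k.imag > 0:
                k = -k
            spec = syn.MRESpec(frequency=f, k=k)
            acq, _ = syn.gen_mre_movie(spec)
            gps.append(mre.invert_acquisition(acq).g_storage)
        assert np.all(np.diff(gps) > 0)

    def test_grid_refinement_stability(self):
        """Halving the radial bin width moves k′ by < 0.5%."""
        spec = syn.MRESpec(frequency=800.0, wave_speed=3.0,
                           penetration_rate=2.0)
        acq, _ = syn.gen_mre_movie(spec)
        k32 = mre.invert_acquisition(acq, n_bins=32).k_real
        k64 = mre.invert_acquisition(acq, n_bins=64).k_real
        assert abs(k64 - k32) / k32 < 0.005

    def test_table_over_frequencies(self, tmp_path):
        acqs = []
        for f in (600.0, 1000.0):
            spec = syn.MRESpec(frequency=f, wave_speed=3.0,
                               penetration_rate=2.0)
            acqs.append(syn.gen_mre_movie(spec)[0])
        table = mre.invert_to_table(acqs)
        np.testing.assert_allclose(table["f_Hz"], [600.0, 1000.0], rtol=1e-12)
        assert {"kp_1_per_m", "c_m_s", "Gp_Pa", "Gpp_Pa"} <= set(table.columns)

    def test_tiff_round_trip(self, tmp_path):
        spec = syn.MRESpec(frequency=800.0, wave_speed=3.0,
                           penetration_rate=2.0, phase_noise_sd=0.02, seed=3)
        p = syn.write_mre_movie(spec, tmp_path / "movie.tif")
        acq = mre.load_acquisition(p, p.with_suffix(".yaml"))
        fit = mre.invert_acquisition(acq)
        truth = syn.gen_mre_movie(spec)[1]
        assert fit.g_storage == pytest.approx(truth["g_storage_Pa"], rel=0.05)
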