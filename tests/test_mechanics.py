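import numpy as np
import pytest
from scipy import integrate

from memfluct.datatypes import FluctuationMovie, MechParams
from memfluct.mechanics import (DEFAULT_NUISANCE_CALIBRATION,
                                HeightCalibration, PSDEstimate,
                                StabilityLimits, TensionMap, Thresholds,
                                calibrate_intensity_to_height,
                                compute_sd_time, estimate_psd, fit_helfrich,
                                height_to_intensity, helfrich_psd,
                                intensity_to_height, map_pixelwise,
                                model_variance, select_fbr_regions,
                                sphere_cap_height)
from memfluct.synthetic import (simulate_fluctuation_movie,
                                simulate_height_series)

from test_synthetic import oracle_psd


class TestHelfrichPSD:
    def test_matches_adaptive_quadrature_oracle(self, tirf_params):
        freqs = [0.05, 0.5, 2.0, 9.7]
        model = helfrich_psd(np.array(freqs), tirf_params)
        for f, m in zip(freqs, model):
            assert m == pytest.approx(oracle_psd(f, tirf_params), rel=1e-6)

    def test_strictly_decreasing_in_f(self, tirf_params):
        f = np.linspace(0.01, 10, 200)
        psd = helfrich_psd(f, tirf_params)
        assert np.all(np.diff(psd) < 0)
        assert np.all(psd > 0)

    def test_decreasing_in_sigma(self, tirf_params):
        f = np.array([0.1, 1.0, 5.0])
        lo = helfrich_psd(f, tirf_params.replace(sigma=300.0))
        hi = helfrich_psd(f, tirf_params.replace(sigma=600.0))
        assert np.all(hi < lo)

    def test_decreasing_in_gamma(self, tirf_params):
        f = np.array([0.1, 1.0, 5.0])
        lo = helfrich_psd(f, tirf_params.replace(gamma=1e3))
        hi = helfrich_psd(f, tirf_params.replace(gamma=1e5))
        assert np.all(hi < lo)

    def test_rejects_nonpositive_freq(self, tirf_params):
        with pytest.raises(ValueError):
            helfrich_psd(np.array([0.0, 1.0]), tirf_params)

    def test_model_variance_consistent(self, tirf_params):
        # quadrature of the returned PSD equals the closed-form band integral
        val, _ = integrate.quad(
            lambda f: helfrich_psd(np.array([f]), tirf_params)[0],
            1e-6, 10.0, limit=200)
        assert model_variance(tirf_params, f_max=10.0) == pytest.approx(
            val, rel=1e-4)


class TestEstimatePSD:
    def test_parseval_for_tone(self):
        fs, n, a = 100.0, 4096, 3.0
        t = np.arange(n) / fs
        x = a * np.sin(2 * np.pi * 12.3 * t)
        psd = estimate_psd(x, fs, method="welch", nperseg=512)
        df = psd.freq[1] - psd.freq[0]
        assert np.sum(psd.power) * df == pytest.approx(a ** 2 / 2, rel=0.02)

    def test_parseval_white_noise(self, rng):
        fs, v = 50.0, 4.0
        x = rng.normal(0, np.sqrt(v), 2 ** 14)
        psd = estimate_psd(x, fs, method="welch", nperseg=256)
        df = psd.freq[1] - psd.freq[0]
        assert np.sum(psd.power) * df == pytest.approx(x.var(), rel=0.02)
        # flat level ~ v / (fs/2)
        assert psd.power.mean() == pytest.approx(v / (fs / 2), rel=0.05)

    def test_ar_matches_closed_form_ar2_spectrum(self, rng):
        phi1, phi2, v, fs = 0.6, -0.3, 1.0, 20.0
        n = 2 ** 15
        e = rng.normal(0, np.sqrt(v), n + 500)
        x = np.zeros(n + 500)
        for i in range(2, n + 500):
            x[i] = phi1 * x[i - 1] + phi2 * x[i - 2] + e[i]
        x = x[500:]
        psd = estimate_psd(x, fs, method="ar", ar_order=2)
        w = 2 * np.pi * psd.freq / fs
        denom = np.abs(1 - phi1 * np.exp(-1j * w)
                       - phi2 * np.exp(-2j * w)) ** 2
        truth = 2 * v / fs / denom
        mid = (psd.freq > 2.0) & (psd.freq < 8.0)
        assert np.all(np.abs(psd.power[mid] / truth[mid] - 1) < 0.10)

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            estimate_psd(np.zeros(10), 20.0, method="ar", ar_order=16)

    def test_invariants(self, tirf_params):
        m = simulate_height_series(tirf_params, 20.0, 1024, seed=0)
        for method in ("welch", "ar"):
            psd = estimate_psd(m.series(), 20.0, method=method)
            assert np.all(psd.power > 0)
            assert psd.freq[-1] <= 10.0 + 1e-9
            assert np.all(np.diff(psd.freq) > 0)


class TestFitHelfrich:
    def test_noiseless_recovery_all_params(self, tirf_params):
        freq = np.linspace(0.0781, 10, 128)
        psd = PSDEstimate(freq=freq, power=helfrich_psd(freq, tirf_params),
                          method="model", n_frames=2048, sampling_rate=20.0)
        fit = fit_helfrich(psd, fixed=dict(kappa=tirf_params.kappa,
                                           q_min=tirf_params.q_min,
                                           q_max=tirf_params.q_max))
        assert fit.converged
        assert fit.r_squared > 0.999
        assert fit.params.sigma == pytest.approx(tirf_params.sigma, rel=0.01)
        assert fit.params.gamma == pytest.approx(tirf_params.gamma, rel=0.01)
        assert fit.params.eta_eff == pytest.approx(tirf_params.eta_eff,
                                                   rel=0.01)
        assert fit.params.a_active == pytest.approx(tirf_params.a_active,
                                                    rel=0.01)

    def test_sigma_recovery_single_series(self, tirf_params):
        m = simulate_height_series(tirf_params.replace(sigma=500.0), 20.0,
                                   2048, seed=7)
        psd = estimate_psd(m.series(), 20.0, method="ar", ar_order=8)
        fit = fit_helfrich(psd,
                           fixed=dict(kappa=tirf_params.kappa,
                                      q_min=tirf_params.q_min,
                                      q_max=tirf_params.q_max),
                           fix=DEFAULT_NUISANCE_CALIBRATION)
        assert fit.params.sigma == pytest.approx(500.0, rel=0.20)

    def test_empty_frequency_range(self, tirf_params):
        freq = np.linspace(0.1, 1, 16)
        psd = PSDEstimate(freq=freq, power=np.ones(16), method="welch",
                          n_frames=256, sampling_rate=20.0)
        with pytest.raises(ValueError):
            fit_helfrich(psd, f_min=5.0)

    def test_bounds_respected(self, tirf_params):
        freq = np.linspace(0.1, 10, 64)
        psd = PSDEstimate(freq=freq, power=helfrich_psd(freq, tirf_params),
                          method="model", n_frames=2048, sampling_rate=20.0)
        bounds = {"sigma": (1000.0, 2000.0)}
        fit = fit_helfrich(psd, bounds=bounds)
        assert 1000.0 <= fit.params.sigma <= 2000.0


class TestSDTime:
    def test_constant_series_zero(self):
        assert compute_sd_time(np.ones(100)) == 0.0

    def test_iid_gaussian(self, rng):
        x = rng.normal(0, 5.0, 20000)
        assert compute_sd_time(x) == pytest.approx(5.0, rel=0.03)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_sd_time(np.ones((1, 2, 2)))

    def test_intensity_movie_rejected(self):
        m = FluctuationMovie(values=np.ones((4, 2, 2)), units="au",
                             pixel_size=65, frame_interval=0.05)
        with pytest.raises(ValueError):
            compute_sd_time(m)

    def test_sd_decreases_with_tension(self, tirf_params):
        sds = []
        for sigma in (300.0, 1300.0):
            m = simulate_height_series(tirf_params.replace(sigma=sigma),
                                       20.0, 2048, seed=21)
            sds.append(compute_sd_time(m.series()))
        assert sds[1] < sds[0]


class TestCalibration:
    @staticmethod
    def _bead_profile(slope=5.0, offset=1000.0, pixel_size=100.0,
                      radius_nm=30000.0, n=260):
        r = np.arange(n) * pixel_size
        h = radius_nm - np.sqrt(radius_nm ** 2 - r ** 2)
        return offset + slope * h

    def test_slope_recovered(self):
        profile = self._bead_profile(slope=5.0)
        cal = calibrate_intensity_to_height(profile, bead_diameter=60.0,
                                            pixel_size=100.0)
        assert cal.slope == pytest.approx(5.0, rel=0.01)

    def test_sphere_geometry(self):
        # exact sphere formula; r^2/2R approximation gives 66.67
        h = sphere_cap_height(2000.0, 30000.0)
        assert h == pytest.approx(66.67, abs=0.1)

    def test_bad_diameter(self):
        with pytest.raises(ValueError):
            calibrate_intensity_to_height(self._bead_profile(), -1.0, 100.0)

    def test_flat_profile_fails(self):
        with pytest.raises(ValueError):
            calibrate_intensity_to_height(np.full(200, 3.0),
                                          bead_diameter=60.0,
                                          pixel_size=100.0)


class TestIntensityHeightConversion:
    @staticmethod
    def _cal(slope=4.0):
        return HeightCalibration(slope=slope, valid_height_range=(0, 100),
                                 intensity_range=(900.0, 1500.0))

    def test_constant_movie_all_zero(self):
        m = FluctuationMovie(values=np.full((8, 2, 2), 1200.0), units="au",
                             pixel_size=65, frame_interval=0.05)
        h = intensity_to_height(m, self._cal())
        np.testing.assert_allclose(h.values, 0.0)
        assert h.units == "nm"

    def test_generator_roundtrip(self, tirf_params):
        truth = np.full((2, 2), 500.0)
        m = simulate_fluctuation_movie(truth, tirf_params, 65.0, 20.0, 256,
                                       seed=5)
        cal = self._cal()
        back = intensity_to_height(height_to_intensity(m, cal, 1200.0), cal)
        np.testing.assert_allclose(back.values, m.values, atol=1e-10)

    def test_slope_linearity(self):
        vals = 1200.0 + np.linspace(-8, 8, 16)[:, None, None] * np.ones((1, 2, 2))
        m = FluctuationMovie(values=vals, units="au", pixel_size=65,
                             frame_interval=0.05)
        h1 = intensity_to_height(m, self._cal(slope=2.0))
        h2 = intensity_to_height(m, self._cal(slope=4.0))
        np.testing.assert_allclose(h2.values, h1.values / 2.0)

    def test_height_mode_rejected(self):
        m = FluctuationMovie(values=np.zeros((4, 2, 2)), units="nm",
                             pixel_size=65, frame_interval=0.05)
        with pytest.raises(ValueError):
            intensity_to_height(m, self._cal())


class TestSelectFBR:
    @staticmethod
    def _movie(values):
        return FluctuationMovie(values=values, units="au", pixel_size=65,
                                frame_interval=0.05)

    def test_uniform_in_branch_full_tiling(self, rng):
        vals = 1200.0 + rng.normal(0, 1.0, (64, 8, 8))
        movie = self._movie(vals)
        limits = StabilityLimits(intensity_range=(1000.0, 1400.0),
                                 max_drift=5.0)
        origins = select_fbr_regions(movie, region_size=4,
                                     stability_limits=limits)
        assert sorted(origins) == [(0, 0), (0, 4), (4, 0), (4, 4)]

    def test_out_of_branch_half_excluded(self, rng):
        vals = 1200.0 + rng.normal(0, 1.0, (64, 8, 8))
        vals[:, :, :4] = 300.0   # left half below branch
        movie = self._movie(vals)
        limits = StabilityLimits(intensity_range=(1000.0, 1400.0))
        origins = select_fbr_regions(movie, 4, limits)
        assert sorted(origins) == [(0, 4), (4, 4)]

    def test_drift_excluded(self, rng):
        vals = 1200.0 + rng.normal(0, 1.0, (64, 4, 8))
        vals[:, :, 4:] += np.linspace(0, 50, 64)[:, None, None]
        movie = self._movie(vals)
        limits = StabilityLimits(intensity_range=(1000.0, 1400.0),
                                 max_drift=5.0)
        origins = select_fbr_regions(movie, 4, limits)
        assert origins == [(0, 0)]


class TestTensionMap:
    def test_threshold_idempotent(self, rng):
        sigma = rng.uniform(100, 6000, (8, 8))
        sd = rng.uniform(0, 20, (8, 8))
        r2 = rng.uniform(0.5, 1.0, (8, 8))
        tm = TensionMap.from_fields(sigma, sd, r2)
        tm2 = tm.apply_thresholds()
        np.testing.assert_array_equal(tm.valid_mask, tm2.valid_mask)
        tm3 = tm2.apply_thresholds()
        np.testing.assert_array_equal(tm2.valid_mask, tm3.valid_mask)

    def test_thresholds_applied(self):
        sigma = np.array([[100.0, 6000.0], [100.0, 100.0]])
        sd = np.array([[1.0, 1.0], [20.0, 1.0]])
        r2 = np.array([[0.95, 0.95], [0.95, 0.5]])
        tm = TensionMap.from_fields(sigma, sd, r2)
        np.testing.assert_array_equal(
            tm.valid_mask, [[True, False], [False, False]])
        assert np.isnan(tm.sigma_map[0, 1])


class TestMapPixelwise:
    def test_two_zone_ordering(self, tirf_params):
        truth = np.full((4, 6), 300.0)
        truth[:, 3:] = 1300.0
        movie = simulate_fluctuation_movie(truth, tirf_params, 65.0, 20.0,
                                           2048, seed=5)
        tm = map_pixelwise(movie)
        lo = np.nanmedian(tm.sigma_map[:, :3])
        hi = np.nanmedian(tm.sigma_map[:, 3:])
        assert hi > lo
        assert lo == pytest.approx(300.0, rel=0.35)
        assert hi == pytest.approx(1300.0, rel=0.35)

    def test_uniform_truth_centered(self, tirf_params):
        truth = np.full((4, 4), 500.0)
        movie = simulate_fluctuation_movie(truth, tirf_params, 65.0, 20.0,
                                           2048, seed=8)
        tm = map_pixelwise(movie)
        valid = tm.sigma_map[tm.valid_mask]
        assert valid.size >= 4
        assert np.median(valid) == pytest.approx(500.0, rel=0.20)

    def test_nonstationary_pixel_excluded(self, tirf_params):
        truth = np.full((2, 2), 500.0)
        movie = simulate_fluctuation_movie(truth, tirf_params, 65.0, 20.0,
                                           2048, seed=3)
        # inject a large step halfway through one pixel's series
        movie.values[1024:, 0, 0] += 60.0
        tm = map_pixelwise(movie)
        assert not tm.valid_mask[0, 0]
        assert tm.valid_mask[1, 1]

    def test_requires_height_units(self):
        m = FluctuationMovie(values=np.ones((4, 2, 2)), units="au",
                             pixel_size=65, frame_interval=0.05)
        with pytest.raises(ValueError):
            map_pixelwise(m)
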