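"""Depth-resolved metrics: percent change, epoch averaging, normalisation,
peak layer, laminar slope, FWHM, background fraction, surface detection."""

import numpy as np
import pytest

import lamline as L
from lamline.core import LaminarProfile, LineImage2D, LineScanSeries


def make_series(paradigm, data):
    return LineScanSeries(data, paradigm.tr_ms, 50.0)


class TestPercentChange:
    def test_constant_series_all_zero(self, paradigm):
        series = make_series(paradigm, np.full((4, paradigm.n_timepoints), 50.0))
        assert np.all(L.percent_change(series, paradigm) == 0.0)

    def test_s0_ignores_stimulus_window(self, paradigm):
        rng = np.random.default_rng(0)
        data = 100.0 + rng.standard_normal((4, paradigm.n_timepoints))
        series = make_series(paradigm, data)
        pct = L.percent_change(series, paradigm)
        # perturbing stimulation samples must not move the baseline S0
        box = L.build_boxcar(paradigm).astype(bool)
        data2 = data.copy()
        data2[:, box] += 25.0
        pct2 = L.percent_change(make_series(paradigm, data2), paradigm)
        assert pct2[:, ~box] == pytest.approx(pct[:, ~box], abs=1e-12)

    def test_pre_window_mean_is_zero(self, paradigm, l4_spec):
        l4_spec.noise_sd_profile = np.full(40, 2.0)
        series = L.simulate_series(l4_spec, paradigm)
        pct = L.percent_change(series, paradigm)
        pre = paradigm.pre_window_mask()
        assert pct[:, pre].mean(axis=1) == pytest.approx(np.zeros(40), abs=1e-10)

    def test_paradigm_must_tile_series(self, paradigm):
        series = make_series(paradigm, np.ones((2, 100)))
        with pytest.raises(ValueError, match="tile"):
            L.percent_change(series, paradigm)

    def test_commutes_with_epoch_average_when_noiseless(self, paradigm, l4_spec):
        series = L.simulate_series(l4_spec, paradigm)
        a = L.epoch_average(L.percent_change(series, paradigm), paradigm)
        # reverse order: epoch-average the raw series first, then percent
        # change against a single-epoch paradigm
        one = L.StimParadigm(
            pre_s=paradigm.pre_s, stim_s=paradigm.stim_s,
            post_s=paradigm.post_s, n_epochs=1, tr_ms=paradigm.tr_ms,
        )
        avg_raw = L.epoch_average(series.data, paradigm)
        b = L.percent_change(make_series(one, avg_raw), one)
        assert np.max(np.abs(a - b)) < 1e-9


class TestEpochAverage:
    def test_periodic_input_identity(self, paradigm):
        epoch = np.random.default_rng(1).standard_normal(paradigm.epoch_samples)
        data = np.tile(epoch, (3, paradigm.n_epochs))
        avg = L.epoch_average(data, paradigm)
        assert avg == pytest.approx(np.tile(epoch, (3, 1)), abs=1e-12)

    def test_noise_shrinks_by_sqrt_epochs(self, paradigm):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((40, paradigm.n_timepoints))
        avg = L.epoch_average(data, paradigm)
        assert avg.std() == pytest.approx(1.0 / np.sqrt(32), rel=0.15)

    def test_single_epoch_is_identity(self):
        p = L.StimParadigm(n_epochs=1)
        data = np.random.default_rng(3).standard_normal((2, p.n_timepoints))
        assert np.array_equal(L.epoch_average(data, p), data)


class TestNormalization:
    def test_normalize_map(self):
        m = np.random.default_rng(4).uniform(0.1, 9.0, (5, 7))
        out = L.normalize_map(m)
        assert out.max() == 1.0
        assert L.normalize_map(5.5 * m) == pytest.approx(out, rel=1e-12)
        assert np.all(L.normalize_map(np.full((3, 3), 2.0)) == 1.0)

    def test_mean_plus_sd_convention(self):
        d = np.array([0.1, 0.2, 0.3])
        mean = LaminarProfile(np.array([1.0, 2.0, 3.0]), d)
        sd = LaminarProfile(np.array([0.0, 0.0, 1.0]), d)
        out = L.normalize_profiles_meansd(mean, sd)
        assert out.values == pytest.approx([0.25, 0.5, 0.75], abs=1e-12)
        zero_sd = LaminarProfile(np.zeros(3), d)
        assert L.normalize_profiles_meansd(mean, zero_sd).values == pytest.approx(
            mean.values / mean.values.max(), abs=1e-12
        )
        assert out.values.max() <= 1.0


class TestPeakLayer:
    def test_l4_and_surface_peaks(self, paradigm, depth_grid, l4_spec):
        scheme = L.LayerScheme()
        series = L.simulate_series(l4_spec, paradigm)
        avg = L.epoch_average(L.percent_change(series, paradigm), paradigm)
        res = L.peak_layer(avg, scheme, depth_grid)
        assert res.layer == "L4"
        assert res.peak_pct == pytest.approx(10.0, abs=1e-6)

        surf = L.make_amplitude_profile("surface_peak", 30.0, depth_grid)
        spec = L.LaminarResponseSpec(amplitude_profile=surf.values, seed=0)
        series = L.simulate_series(spec, paradigm)
        avg = L.epoch_average(L.percent_change(series, paradigm), paradigm)
        assert L.peak_layer(avg, scheme, depth_grid).layer == "L1"

    def test_flat_profile_tie_breaks_shallow(self, depth_grid):
        avg = np.ones((40, 10))
        res = L.peak_layer(avg, L.LayerScheme(), depth_grid)
        assert res.depth_index == 0
        assert res.layer == "L1"

    def test_window_mean_statistic(self, depth_grid):
        avg = np.zeros((40, 200))
        avg[20, 50:90] = 2.0
        res = L.peak_layer(avg, L.LayerScheme(), depth_grid,
                           statistic="mean", window=slice(50, 90))
        assert res.depth_index == 20


class TestLaminarSlope:
    def test_flat_profile_zero(self, depth_grid):
        prof = LaminarProfile(np.ones(40), depth_grid)
        assert L.laminar_slope(prof, L.LayerScheme()) == 0.0

    def test_linear_profile_hand_value(self, depth_grid):
        # profile falling 1 -> 0 over 0-2 mm: slope between the L1 midpoint
        # (0.075 mm) and the L2/3 midpoint (0.425 mm) is -(0.425-0.075)/2
        prof = LaminarProfile(1.0 - depth_grid / 2.0, depth_grid)
        slope = L.laminar_slope(prof, L.LayerScheme())
        assert slope == pytest.approx(-(0.425 - 0.075) / 2.0, abs=1e-12)

    def test_increasing_profile_positive(self, depth_grid):
        prof = LaminarProfile(depth_grid ** 2, depth_grid)
        assert L.laminar_slope(prof, L.LayerScheme()) > 0


class TestFwhm:
    def test_gaussian_analytic_width(self):
        x = np.arange(0, 12.8, 0.05)
        sigma = 0.6366
        prof = np.exp(-((x - 6.4) ** 2) / (2 * sigma ** 2))
        fwhm = L.profile_fwhm(prof, 0.05)
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, abs=0.05)

    def test_rectangle_width(self):
        prof = np.zeros(100)
        prof[40:70] = 1.0
        assert L.profile_fwhm(prof, 0.1) == pytest.approx(3.0, abs=0.1)

    def test_bimodal_uses_global_peak_lobe(self):
        x = np.arange(200) * 0.1
        small = 0.6 * np.exp(-((x - 5.0) ** 2) / (2 * 0.5 ** 2))
        big = 1.0 * np.exp(-((x - 15.0) ** 2) / (2 * 1.0 ** 2))
        fwhm = L.profile_fwhm(small + big, 0.1)
        # width of the 1.0-sigma lobe, not of the whole support
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 1.0, abs=0.1)


class TestBackground:
    def make_image(self, inside=1.0, outside=0.05):
        data = np.full((8, 20), outside)
        mask = np.zeros((8, 20), dtype=bool)
        mask[:, 8:12] = True
        data[mask] = inside
        return LineImage2D(data, (6.4, 12.8), mask)

    def test_uniform_cases(self):
        assert L.background_fraction(self.make_image(outside=0.0)).fraction_pct == 0.0
        b = L.background_fraction(self.make_image(outside=0.05))
        assert b.fraction_pct == pytest.approx(5.0, abs=1e-12)
        assert b.s_roi == 1.0 and b.n_bkg == pytest.approx(0.05)

    def test_mask_complement_reciprocal(self):
        img = self.make_image(outside=0.05)
        f = L.background_fraction(img).fraction_pct
        swapped = LineImage2D(img.data, img.fov_mm, ~img.roi_mask)
        assert L.background_fraction(swapped).fraction_pct == pytest.approx(
            1e4 / f, rel=1e-12
        )

    def test_scale_invariance(self):
        img = self.make_image()
        scaled = LineImage2D(3.0 * img.data, img.fov_mm, img.roi_mask)
        assert L.background_fraction(scaled).fraction_pct == pytest.approx(
            L.background_fraction(img).fraction_pct, rel=1e-12
        )


class TestSurfaceDetection:
    def test_step_profile(self, depth_grid):
        y = np.zeros(40)
        y[7:] = 100.0
        idx, thr = L.detect_cortical_surface(LaminarProfile(y, depth_grid))
        assert idx == 7
        assert thr == pytest.approx(50.0)

    def test_all_above_threshold(self, depth_grid):
        idx, _ = L.detect_cortical_surface(LaminarProfile(np.full(40, 5.0), depth_grid))
        assert idx == 0

    def test_ramp_matches_direct_scan(self, depth_grid):
        y = np.linspace(0, 100, 40)
        prof = LaminarProfile(y, depth_grid)
        idx, thr = L.detect_cortical_surface(prof)
        # oracle: first bin at or above half the 95th percentile
        expect = int(np.nonzero(y >= 0.5 * np.percentile(y, 95))[0][0])
        assert idx == expect


def test_metrics_invariant_to_positive_scaling(paradigm, l4_spec):
    l4_spec.noise_sd_profile = np.full(40, 1.0)
    series = L.simulate_series(l4_spec, paradigm)
    scaled = series.copy_with(4.2 * series.data)
    pct_a = L.percent_change(series, paradigm)
    pct_b = L.percent_change(scaled, paradigm)
    assert pct_b == pytest.approx(pct_a, abs=1e-9)
    assert L.compute_tsnr(scaled).values == pytest.approx(
        L.compute_tsnr(series).values, rel=1e-12
    )
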