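"""Processing-chain stages: outlier removal, calibration, baselines,
averaging, normalization, and full-chain truth recovery."""

import numpy as np
import pytest

from duvdecon import SyntheticConfig, generate_target
from duvdecon.preprocess import (PreprocessConfig, RamanPreprocessor,
                                 average_replicates, correct_laser_intensity,
                                 crop_fingerprint, normalize_to_guanine,
                                 recalibrate_shift, remove_cosmic_rays,
                                 run_pipeline, subtract_atmospheric,
                                 subtract_linear_baseline)
from duvdecon.spectra import RamanSpectrum, SpectrumError, SpectrumSet
from duvdecon.standards import pseudo_voigt_line


def smooth_set(n_reps=25, seed=0, sigma=0.05):
    axis = np.arange(800.0, 1801.0, 2.0)
    truth = pseudo_voigt_line(axis, 1300.0, 25.0)
    rng = np.random.default_rng(seed)
    mat = truth + rng.normal(0.0, sigma, size=(n_reps, len(axis)))
    return SpectrumSet.from_matrix(axis, mat), truth, sigma


class TestCosmicRays:
    def test_injected_spike_removed_others_untouched(self):
        s, truth, sigma = smooth_set()
        mat = s.to_matrix().copy()
        mat[7, 200] += 50.0 * sigma
        spiked = s.with_matrix(mat)
        cleaned, flagged = remove_cosmic_rays(spiked, zmax=5.0)
        assert (7, 200) in flagged
        out = cleaned.to_matrix()
        # replaced value back inside the local noise band
        assert abs(out[7, 200] - truth[200]) < 5.0 * sigma
        # every unflagged cell bit-identical
        mask = np.ones_like(mat, dtype=bool)
        for r, c in flagged:
            mask[r, c] = False
        np.testing.assert_array_equal(out[mask], mat[mask])

    def test_spike_free_set_is_noop(self):
        axis = np.arange(800.0, 900.0, 2.0)
        mat = np.tile(np.linspace(1.0, 2.0, len(axis)), (5, 1))
        s = SpectrumSet.from_matrix(axis, mat)
        cleaned, flagged = remove_cosmic_rays(s)
        assert flagged == []
        np.testing.assert_array_equal(cleaned.to_matrix(), mat)

    def test_requires_three_replicates(self):
        axis = np.arange(800.0, 900.0, 2.0)
        s = SpectrumSet.from_matrix(axis, np.ones((2, len(axis))))
        with pytest.raises(SpectrumError, match="insufficient replicates"):
            remove_cosmic_rays(s)

    def test_boundary_channel_replaced_one_sided(self):
        s, truth, sigma = smooth_set()
        mat = s.to_matrix().copy()
        mat[0, 0] += 80.0 * sigma
        cleaned, flagged = remove_cosmic_rays(s.with_matrix(mat))
        assert (0, 0) in flagged
        assert cleaned.to_matrix()[0, 0] == pytest.approx(mat[0, 1])


class TestLaserCorrection:
    def test_divides_by_factor(self):
        s = RamanSpectrum([800.0, 802.0], [10.0, 10.0])
        out = correct_laser_intensity(s, 2.0)
        np.testing.assert_array_equal(out.intensity, [5.0, 5.0])
        assert out.meta["laser_correction"] == 2.0

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_nonpositive_factor_rejected(self, factor):
        s = RamanSpectrum([800.0, 802.0], [10.0, 10.0])
        with pytest.raises(SpectrumError, match="invalid correction factor"):
            correct_laser_intensity(s, factor)


class TestRecalibration:
    def _spectrum_with_line(self, center, full_axis):
        y = 0.5 * pseudo_voigt_line(full_axis, center, 12.0)
        return RamanSpectrum(full_axis, y)

    def test_offset_line_shifted_home(self, full_axis):
        s = self._spectrum_with_line(2318.0, full_axis)
        out, delta = recalibrate_shift(s, reference=2330.0)
        assert delta == pytest.approx(12.0, abs=1.0)
        apex = out.shift[np.argmax(out.intensity)]
        assert abs(apex - 2330.0) <= 1.0  # within half a channel + refinement

    def test_already_calibrated_is_near_identity(self, full_axis):
        s = self._spectrum_with_line(2330.0, full_axis)
        _, delta = recalibrate_shift(s)
        assert abs(delta) < 1.0

    def test_cropped_spectrum_lacks_n2_region(self, fingerprint_axis):
        s = RamanSpectrum(fingerprint_axis, np.ones(len(fingerprint_axis)))
        with pytest.raises(SpectrumError, match="N2 region absent"):
            recalibrate_shift(s)

    def test_flat_window_has_no_peak(self, full_axis):
        s = RamanSpectrum(full_axis, np.ones(len(full_axis)))
        with pytest.raises(SpectrumError, match="N2 peak not found"):
            recalibrate_shift(s)


class TestAtmosphericSubtraction:
    def test_isolated_line_removed(self, full_axis):
        line = 0.3 * pseudo_voigt_line(full_axis, 1550.0, 12.0)
        s = RamanSpectrum(full_axis, line + 1.0)
        out, info = subtract_atmospheric(s, positions=(1550.0,))
        assert info[0]["status"] == "subtracted"
        assert info[0]["height"] == pytest.approx(0.3, rel=0.05)
        m = out.window_mask(1510.0, 1590.0)
        resid_area = np.trapezoid(np.abs(out.intensity[m] - 1.0),
                                  out.shift[m])
        line_area = np.trapezoid(line[m], full_axis[m])
        assert resid_area < 0.05 * line_area

    def test_no_feature_gives_zero_amplitude(self, full_axis):
        s = RamanSpectrum(full_axis, np.full(len(full_axis), 2.0))
        out, info = subtract_atmospheric(s, positions=(1550.0,))
        assert info[0]["height"] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(out.intensity, s.intensity, atol=1e-9)

    def test_both_lines_removed_independently(self, full_axis):
        n2 = 0.5 * pseudo_voigt_line(full_axis, 2330.0, 12.0)
        o2 = 0.2 * pseudo_voigt_line(full_axis, 1550.0, 12.0)
        s = RamanSpectrum(full_axis, n2 + o2 + 1.0)
        out, info = subtract_atmospheric(s, positions=(2330.0, 1550.0))
        heights = {i["position"]: i["height"] for i in info}
        assert heights[2330.0] == pytest.approx(0.5, rel=0.05)
        assert heights[1550.0] == pytest.approx(0.2, rel=0.05)
        np.testing.assert_allclose(out.intensity, 1.0, atol=0.02)

    def test_uncovered_window_warns_and_flags(self, fingerprint_axis):
        s = RamanSpectrum(fingerprint_axis, np.ones(len(fingerprint_axis)))
        with pytest.warns(UserWarning, match="not covered"):
            out, info = subtract_atmospheric(s, positions=(2330.0,))
        assert info[0]["status"] == "window_absent"
        assert out.meta["atmospheric_flag"] == "window_absent"


class TestCropAndBaseline:
    def test_crop_closed_interval(self, full_axis):
        s = RamanSpectrum(full_axis, np.ones(len(full_axis)))
        out = crop_fingerprint(s, 800.0, 1800.0)
        assert out.shift[0] == 800.0 and out.shift[-1] == 1800.0

    def test_crop_wider_than_axis_is_identity(self, ramp_spectrum):
        out = crop_fingerprint(ramp_spectrum, 0.0, 5000.0)
        np.testing.assert_array_equal(out.shift, ramp_spectrum.shift)

    def test_empty_crop_rejected(self, ramp_spectrum):
        with pytest.raises(SpectrumError, match="empty crop"):
            crop_fingerprint(ramp_spectrum, 1900.0, 2000.0)

    def test_pure_line_annihilated(self, ramp_spectrum):
        out, (slope, intercept) = subtract_linear_baseline(ramp_spectrum)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(7.0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)

    def test_peak_on_line_preserved_vs_ols_oracle(self, fingerprint_axis):
        peak = pseudo_voigt_line(fingerprint_axis, 1300.0, 25.0)
        y = peak + 0.01 * fingerprint_axis + 3.0
        s = RamanSpectrum(fingerprint_axis, y)
        out, _ = subtract_linear_baseline(s)
        # oracle: closed-form OLS normal equations on the constructed input
        X = np.column_stack([np.ones_like(fingerprint_axis),
                             fingerprint_axis])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out.intensity, y - X @ beta, atol=1e-10)
        apex = np.argmax(out.intensity)
        assert out.intensity[apex] == pytest.approx(1.0, rel=0.05)

    def test_idempotent(self, fingerprint_axis):
        y = pseudo_voigt_line(fingerprint_axis, 1300.0, 25.0) + 0.3
        once, _ = subtract_linear_baseline(
            RamanSpectrum(fingerprint_axis, y))
        twice, _ = subtract_linear_baseline(once)
        np.testing.assert_allclose(twice.intensity, once.intensity,
                                   rtol=1e-10, atol=1e-12)

    def test_degenerate_baseline_rejected(self):
        s = RamanSpectrum([800.0, 801.0], [1.0, 2.0])
        with pytest.raises(SpectrumError, match="degenerate baseline"):
            subtract_linear_baseline(s)


class TestAveraging:
    def test_identical_replicates(self):
        axis = np.arange(800.0, 900.0, 2.0)
        s = SpectrumSet.from_matrix(axis, np.tile(np.ones(len(axis)), (4, 1)))
        mean, sd = average_replicates(s)
        np.testing.assert_array_equal(mean.intensity, 1.0)
        np.testing.assert_array_equal(sd, 0.0)

    def test_sample_sd_estimator(self):
        axis = np.arange(800.0, 900.0, 2.0)
        mat = np.vstack([np.zeros(len(axis)), 2.0 * np.ones(len(axis))])
        mean, sd = average_replicates(SpectrumSet.from_matrix(axis, mat))
        np.testing.assert_array_equal(mean.intensity, 1.0)
        np.testing.assert_allclose(sd, np.sqrt(2.0))

    def test_noise_shrinks_like_sqrt_n(self):
        deviations = []
        for n in (4, 64):
            devs = []
            for seed in range(10):
                s, truth, sigma = smooth_set(n_reps=n, seed=seed, sigma=0.1)
                mean, _ = average_replicates(s)
                devs.append(np.std(mean.intensity - truth))
            deviations.append(np.mean(devs))
        assert deviations[0] / deviations[1] == pytest.approx(4.0, rel=0.25)


class TestNormalization:
    def test_window_apex_scaled_to_one(self, fingerprint_axis):
        y = 50.0 * pseudo_voigt_line(fingerprint_axis, 1460.0, 25.0)
        out, factor = normalize_to_guanine(RamanSpectrum(fingerprint_axis, y))
        assert factor == pytest.approx(50.0)
        m = out.window_mask(1440.0, 1480.0)
        assert np.max(out.intensity[m]) == pytest.approx(1.0)

    def test_idempotent(self, fingerprint_axis):
        y = 3.0 * pseudo_voigt_line(fingerprint_axis, 1460.0, 25.0)
        once, _ = normalize_to_guanine(RamanSpectrum(fingerprint_axis, y))
        twice, factor = normalize_to_guanine(once)
        assert factor == pytest.approx(1.0)
        np.testing.assert_allclose(twice.intensity, once.intensity)

    def test_window_mean_statistic(self, fingerprint_axis):
        y = 2.0 * np.ones(len(fingerprint_axis))
        out, factor = normalize_to_guanine(
            RamanSpectrum(fingerprint_axis, y), statistic="mean")
        assert factor == pytest.approx(2.0)

    def test_zero_spectrum_rejected(self, fingerprint_axis):
        s = RamanSpectrum(fingerprint_axis, np.zeros(len(fingerprint_axis)))
        with pytest.raises(SpectrumError, match="cannot normalize"):
            normalize_to_guanine(s)


class TestFullPipeline:
    @pytest.mark.parametrize("seed", range(10))
    def test_truth_recovery_within_noise_band(self, seed):
        """Pipeline output matches the generator's noise-free truth to within
        3x the injected per-replicate noise sd, per channel, across seeds."""
        config = SyntheticConfig.cell_like(seed=seed)
        spectrum_set, record = generate_target(config)
        result = run_pipeline(spectrum_set)
        truth = crop_fingerprint(record.truth)
        truth, _ = subtract_linear_baseline(truth)
        truth, norm = normalize_to_guanine(truth)
        interp = np.interp(result.spectrum.shift, truth.shift,
                           truth.intensity)
        err = np.abs(result.spectrum.intensity - interp)
        assert np.max(err) < 3.0 * record.noise_sigma_abs / norm

    def test_near_identity_on_clean_cropped_input(self, fingerprint_axis):
        y = pseudo_voigt_line(fingerprint_axis, 1460.0, 25.0)
        y, _ = subtract_linear_baseline(RamanSpectrum(fingerprint_axis, y))
        y, _ = normalize_to_guanine(y)
        s = SpectrumSet.from_matrix(fingerprint_axis,
                                    np.tile(y.intensity, (3, 1)))
        config = PreprocessConfig(recalibrate=False,
                                  subtract_atmospheric_lines=False)
        result = run_pipeline(s, config)
        np.testing.assert_allclose(result.spectrum.intensity, y.intensity,
                                   atol=1e-6)

    def test_missing_n2_region_fails_recalibration(self, fingerprint_axis):
        s = SpectrumSet.from_matrix(
            fingerprint_axis,
            np.tile(pseudo_voigt_line(fingerprint_axis, 1460.0, 25.0),
                    (3, 1)))
        with pytest.raises(SpectrumError, match="N2 region absent"):
            run_pipeline(s, PreprocessConfig())

    def test_report_logs_stage_effects(self, cell_fixture):
        spectrum_set, _, record = cell_fixture(seed=4)
        result = run_pipeline(spectrum_set)
        rep = result.report
        assert rep["recalibration_shift_cm1"] == pytest.approx(
            -record.axis_offset_cm1, abs=0.5)
        assert rep["normalization_factor"] > 0
        assert {i["position"] for i in rep["atmospheric"]} == {2330.0, 1550.0}


class TestSklearnWrapper:
    def test_transformer_matches_run_pipeline(self, cell_fixture):
        spectrum_set, _, _ = cell_fixture(seed=2)
        est = RamanPreprocessor(wavenumbers=spectrum_set.axis)
        out = est.fit_transform(spectrum_set.to_matrix())
        result = run_pipeline(spectrum_set)
        np.testing.assert_allclose(out[0], result.spectrum.intensity)
        assert est.report_["cosmic_rays_replaced"] == \
            result.report["cosmic_rays_replaced"]

    def test_get_params_round_trip(self):
        est = RamanPreprocessor(cosmic_ray_zmax=4.0)
        params = est.get_params()
        assert params["cosmic_ray_zmax"] == 4.0
        est2 = RamanPreprocessor(**params)
        assert est2.get_params() == params
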