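"""Hemoglobin compensation: references, deltas, linear law, correction."""

import math

import numpy as np
import pytest

from bilicomp.calibration import CalibrationCurve, fit_calibration
from bilicomp.compensation import (
    CompensationModel,
    ReferenceSet,
    compute_deltas,
    compute_references,
    correct_reflectance,
    estimate_bilirubin,
    estimate_panel,
    fit_compensation,
)
from bilicomp.evaluation import pooled_rmse
from bilicomp.exceptions import (
    DegenerateFitError,
    DomainError,
    InvalidCorrectionError,
    MissingReferenceError,
)
from bilicomp.optical import (
    Measurement,
    calibration_panel_spec,
    default_params,
    simulate_panel,
    default_panel_spec,
)
from bilicomp.pipeline import run_pipeline


def _dp(sample_id, x, y):
    from bilicomp.compensation import DeltaPoint

    return DeltaPoint(sample_id=sample_id, delta_r590=x, delta_r465=y, n_tests_averaged=1)


REFS = ReferenceSet(r465_ref_by_level={5.0: 100.0}, r590_ref=98.2, hb_ref_level=0.06)


class TestReferences:
    def test_constant_r590_gives_that_reference(self):
        ms = [
            Measurement("B1H1", 5.0, 0.06, r, 100.0, 98.2) for r in (1, 2)
        ] + [Measurement("B1H2", 5.0, 0.5, 1, 90.0, 85.0)]
        refs = compute_references(ms)
        assert refs.r590_ref == pytest.approx(98.2)
        assert refs.hb_ref_level == 0.06

    def test_per_level_reference_is_replicate_mean(self):
        ms = [
            Measurement("B1H1", 5.0, 0.06, 1, 100.0, 98.0),
            Measurement("B1H1", 5.0, 0.06, 2, 102.0, 98.4),
        ]
        refs = compute_references(ms)
        assert refs.r465_ref_by_level[5.0] == pytest.approx(101.0)
        assert refs.r590_ref == pytest.approx(98.2)

    def test_noiseless_panel_r590_ref_matches_forward_model(self, noiseless_panel, noiseless_params):
        refs = compute_references(noiseless_panel)
        expected = noiseless_params.n590 * math.exp(-noiseless_params.k_hb_590 * 0.06)
        assert refs.r590_ref == pytest.approx(expected, rel=1e-12)
        assert refs.r590_ref == pytest.approx(98.216, abs=1e-3)

    def test_missing_reference_level_is_explicit_error(self, noiseless_panel):
        without_b3_refs = [
            m for m in noiseless_panel
            if not (m.bilirubin_nominal == 14.47 and m.hemoglobin_nominal == 0.06)
        ]
        with pytest.raises(MissingReferenceError, match="14.47"):
            compute_references(without_b3_refs)


class TestDeltas:
    def test_direct_substitution(self):
        ms = [Measurement("B1H2", 5.0, 0.5, 1, 95.0, 88.2)]
        (d,) = compute_deltas(ms, REFS)
        assert d.delta_r590 == pytest.approx(10.0)
        assert d.delta_r465 == pytest.approx(5.0)

    def test_reference_group_deltas_are_zero_noise_free(self, noiseless_panel):
        refs = compute_references(noiseless_panel)
        deltas = compute_deltas(noiseless_panel, refs)
        for d in deltas:
            if d.sample_id.endswith("H1"):
                assert d.delta_r590 == pytest.approx(0.0, abs=1e-12)
                assert d.delta_r465 == pytest.approx(0.0, abs=1e-12)

    def test_one_point_per_sample_on_replicate_means(self, noisy_panel):
        refs = compute_references(noisy_panel)
        deltas = compute_deltas(noisy_panel, refs)
        assert len(deltas) == 25
        assert all(d.n_tests_averaged == 5 for d in deltas)

    def test_noiseless_b1h5_delta_matches_closed_form(self, noiseless_panel, noiseless_params):
        refs = compute_references(noiseless_panel)
        deltas = {d.sample_id: d for d in compute_deltas(noiseless_panel, refs)}
        p = noiseless_params
        expected = p.n590 * (math.exp(-p.k_hb_590 * 0.06) - math.exp(-p.k_hb_590 * 0.99))
        assert deltas["B1H5"].delta_r590 == pytest.approx(expected, rel=1e-12)
        assert deltas["B1H5"].delta_r590 == pytest.approx(23.912, abs=1e-3)

    def test_unknown_level_is_error(self):
        ms = [Measurement("X1", 7.7, 0.5, 1, 95.0, 88.2)]
        with pytest.raises(MissingReferenceError):
            compute_deltas(ms, REFS)


class TestFitCompensation:
    def test_exact_line_recovered(self):
        deltas = [_dp(f"S{i}", x, 2.0 * x + 1.0) for i, x in enumerate([0.0, 1.0, 2.5, 4.0])]
        model = fit_compensation(deltas, REFS)
        assert model.slope == pytest.approx(2.0, abs=1e-12)
        assert model.intercept == pytest.approx(1.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.r590_ref == REFS.r590_ref

    def test_hand_computed_least_squares(self):
        # points (0,0), (1,1), (2,3): slope 1.5, intercept −1/6
        deltas = [_dp("a", 0, 0), _dp("b", 1, 1), _dp("c", 2, 3)]
        model = fit_compensation(deltas, REFS)
        assert model.slope == pytest.approx(1.5, abs=1e-12)
        assert model.intercept == pytest.approx(-1.0 / 6.0, abs=1e-12)

    def test_agrees_with_closed_form_simple_regression(self, noisy_panel):
        refs = compute_references(noisy_panel)
        deltas = compute_deltas(noisy_panel, refs)
        model = fit_compensation(deltas, refs)
        x = np.array([d.delta_r590 for d in deltas])
        y = np.array([d.delta_r465 for d in deltas])
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert model.slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert model.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), abs=1e-12)
        # and with numpy's independent polynomial fit
        np_slope, np_intercept = np.polyfit(x, y, 1)
        assert model.slope == pytest.approx(np_slope, abs=1e-9)
        assert model.intercept == pytest.approx(np_intercept, abs=1e-9)

    def test_additive_mode_forces_slope_gamma_intercept_zero(self, additive_panel, additive_params):
        refs = compute_references(additive_panel)
        deltas = compute_deltas(additive_panel, refs)
        model = fit_compensation(deltas, refs)
        assert model.slope == pytest.approx(additive_params.additive_gamma, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        deltas = [_dp("a", 1.0, 0.0), _dp("b", 1.0, 2.0)]
        with pytest.raises(DegenerateFitError):
            fit_compensation(deltas, REFS)


class TestCorrection:
    MODEL = CompensationModel(slope=0.5, intercept=0.0, r_squared=0.9, n_points=25,
                              r590_ref=98.2)

    def test_zero_interference_identity(self):
        assert correct_reflectance(self.MODEL, 70.0, 98.2) == pytest.approx(70.0)

    def test_direct_substitution(self):
        assert correct_reflectance(self.MODEL, 70.0, 88.2) == pytest.approx(75.0)

    def test_nonpositive_corrected_is_flagged_error(self):
        model = CompensationModel(slope=-10.0, intercept=0.0, r_squared=0.5,
                                  n_points=25, r590_ref=98.2)
        with pytest.raises(InvalidCorrectionError):
            correct_reflectance(model, 5.0, 88.2)

    def test_additive_panel_correction_restores_reference_reflectance(
        self, additive_panel
    ):
        """Exact-linearity oracle: every corrected r465 equals the reference
        group's r465 for its bilirubin level."""
        refs = compute_references(additive_panel)
        deltas = compute_deltas(additive_panel, refs)
        model = fit_compensation(deltas, refs)
        for m in additive_panel:
            corrected = correct_reflectance(model, m.r465, m.r590)
            assert corrected == pytest.approx(
                refs.r465_ref_by_level[m.bilirubin_nominal], abs=1e-9
            )


class TestEstimate:
    def test_reference_group_recovered_exactly_noise_free(self, noiseless_panel, additive_panel):
        """Noise-free reference-group tests invert to their nominal value:
        uncompensated on the multiplicative panel (calibration data are
        exactly exponential), and both ways on the additive panel (where the
        fitted intercept is 0, so the correction is the identity there)."""
        ref_ms = [m for m in noiseless_panel if m.hemoglobin_nominal == 0.06]
        curve = fit_calibration(ref_ms)
        for m in ref_ms:
            est = estimate_bilirubin(curve, None, m, compensate=False)
            assert est.estimate_mgdl == pytest.approx(m.bilirubin_nominal, abs=1e-6)

        add_refs_hb = min(m.hemoglobin_nominal for m in additive_panel)
        add_ref_ms = [m for m in additive_panel if m.hemoglobin_nominal == add_refs_hb]
        curve_a = fit_calibration(add_ref_ms)
        refs = compute_references(additive_panel)
        model = fit_compensation(compute_deltas(additive_panel, refs), refs)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        for m in add_ref_ms:
            for compensate, mdl in ((False, None), (True, model)):
                est = estimate_bilirubin(curve_a, mdl, m, compensate)
                assert est.estimate_mgdl == pytest.approx(m.bilirubin_nominal, abs=1e-6)

    def test_additive_noiseless_panel_exact_recovery(self, additive_panel):
        """Full pipeline on exactly-linear interference recovers every nominal
        concentration to ≤ 1e−6 mg/dL."""
        hb_ref = min(m.hemoglobin_nominal for m in additive_panel)
        ref_ms = [m for m in additive_panel if m.hemoglobin_nominal == hb_ref]
        curve = fit_calibration(ref_ms)
        refs = compute_references(additive_panel)
        model = fit_compensation(compute_deltas(additive_panel, refs), refs)
        estimates = estimate_panel(curve, model, additive_panel, compensate=True)
        assert len(estimates) == 125
        for e in estimates:
            assert e.estimate_mgdl == pytest.approx(e.bilirubin_nominal, abs=1e-6)

    def test_uncompensated_interference_shift_matches_closed_form(
        self, noiseless_panel, noiseless_params
    ):
        """Without compensation the apparent concentration shifts by
        (k_hb_465/k_bil_465)·Δc_hb = 9·(0.99−0.06) = 8.37 mg/dL at B1H5."""
        ref_ms = [m for m in noiseless_panel if m.hemoglobin_nominal == 0.06]
        curve = fit_calibration(ref_ms)
        (b1h5,) = [m for m in noiseless_panel if m.sample_id == "B1H5" and m.replicate == 1]
        est = estimate_bilirubin(curve, None, b1h5, compensate=False)
        assert est.estimate_mgdl == pytest.approx(4.96 + 9 * (0.99 - 0.06), abs=1e-6)
        assert est.estimate_mgdl == pytest.approx(13.33, abs=1e-2)

    def test_compensate_without_model_rejected(self, noiseless_panel):
        curve = CalibrationCurve(a=120, b=0.02, r_squared=1.0, n_points=10)
        with pytest.raises(DomainError):
            estimate_bilirubin(curve, None, noiseless_panel[0], compensate=True)

    def test_negative_estimate_flagged_not_clamped(self):
        curve = CalibrationCurve(a=120, b=0.02, r_squared=1.0, n_points=10)
        m = Measurement("B1H1", 0.0, 0.06, 1, 125.0, 98.2)
        est = estimate_bilirubin(curve, None, m, compensate=False)
        assert est.estimate_mgdl < 0
        assert "negative_estimate" in est.flags

    def test_invalid_correction_yields_nan_with_flag(self):
        curve = CalibrationCurve(a=120, b=0.02, r_squared=1.0, n_points=10)
        model = CompensationModel(slope=-10.0, intercept=0.0, r_squared=0.5,
                                  n_points=25, r590_ref=98.2)
        m = Measurement("B1H1", 5.0, 0.5, 1, 5.0, 88.2)
        est = estimate_bilirubin(curve, model, m, compensate=True)
        assert math.isnan(est.estimate_mgdl)
        assert est.flags == ("invalid_correction",)


class TestCompensationHelps:
    def test_compensated_rmse_lower_on_every_seed(self):
        """On the default multiplicative panel, compensation reduces pooled
        RMSE for every one of 20 seeds."""
        for seed in range(20):
            result = run_pipeline(seed)
            assert result.report.pooled_rmse_comp < result.report.pooled_rmse_noncomp, (
                f"seed {seed}: compensation did not reduce pooled RMSE"
            )
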