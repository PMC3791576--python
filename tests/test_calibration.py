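import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromval.calibration import (
    CalibrationFit,
    ConcentrationEstimate,
    fit_calibration,
    fit_record,
    invert_calibration,
    qualify_loq,
    relative_calibration_uncertainty,
    slope_confidence_interval,
)
from chromval.synth import (
    DEFAULT_INTERCEPT,
    DEFAULT_SLOPE,
    ResponseModel,
    generate_calibration_tables,
)

LEVELS = [0.5, 1.0, 5.0, 10.0, 20.0, 50.0]

# Hand-evaluated oracle for the fixed 3-point toy fit (exact-fraction
# arithmetic, then the inverse-prediction formula evaluated by hand):
#   x = {1, 2, 3}, y = {2.1, 3.9, 6.1}
#   m = 2.0, b = 1/30, s_r = sqrt(2/75), x0(y0=4, N=1) = 119/60
TOY_SLOPE = 2.0
TOY_INTERCEPT = 1.0 / 30.0
TOY_SR = 0.16329931618554522
TOY_X0 = 1.9833333333333334
TOY_SX0 = 0.0942858144940946


def pooled_default_data(seed=42, curves=5):
    model = ResponseModel(seed=seed)
    tables = generate_calibration_tables(model, LEVELS, curves=curves)
    x = np.tile(LEVELS, curves)
    y = np.concatenate([t.iloc[0].to_numpy() for t in tables])
    ids = np.repeat(np.arange(curves), len(LEVELS))
    return x, y, ids


class TestFit:
    def test_noise_free_line_is_exact(self, noise_free_model):
        (table,) = generate_calibration_tables(noise_free_model, LEVELS, curves=1)
        fit = fit_calibration(LEVELS, table.iloc[0].to_numpy())
        assert fit.slope == pytest.approx(DEFAULT_SLOPE, rel=1e-12)
        assert fit.intercept == pytest.approx(DEFAULT_INTERCEPT, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_toy_fit_matches_hand_oracle(self, toy_fit):
        assert toy_fit.slope == pytest.approx(TOY_SLOPE, rel=1e-12)
        assert toy_fit.intercept == pytest.approx(TOY_INTERCEPT, rel=1e-9)
        assert toy_fit.residual_sd == pytest.approx(TOY_SR, rel=1e-12)
        assert toy_fit.n == 3
        assert toy_fit.sxx == pytest.approx(2.0)

    def test_too_few_distinct_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_calibration([1.0, 1.0, 2.0, 2.0], [1.0, 1.1, 2.0, 2.1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            fit_calibration([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_pooled_default_r_squared(self):
        x, y, ids = pooled_default_data()
        fit = fit_calibration(x, y, curve_ids=ids)
        assert fit.r_squared >= 0.999
        assert fit.n == 30

    def test_per_curve_slopes(self):
        x, y, ids = pooled_default_data()
        fit = fit_calibration(x, y, curve_ids=ids)
        assert len(fit.per_curve_slopes) == 5
        # per-curve slope scatter lands in the RSD band implied by the noise model
        slope_rsd = 100 * np.std(fit.per_curve_slopes, ddof=1) / np.mean(fit.per_curve_slopes)
        assert 0.3 < slope_rsd < 3.5

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            fit_calibration([1.0, 1.0, 2.0, 3.0], [1.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])

    def test_fit_record_keys(self, toy_fit):
        record = fit_record(toy_fit)
        assert set(record) == {
            "slope", "intercept", "r_squared", "residual_sd", "n", "x_bar", "sxx",
        }


class TestInversePrediction:
    def test_hand_oracle_x0_and_sx0(self, toy_fit):
        est = invert_calibration(toy_fit, [4.0])
        assert est.x0 == pytest.approx(TOY_X0, rel=1e-9)
        assert est.N == 1
        assert est.s_x0 == pytest.approx(TOY_SX0, rel=1e-9)

    def test_zero_residual_gives_zero_sx0(self, noise_free_model):
        (table,) = generate_calibration_tables(noise_free_model, LEVELS, curves=1)
        fit = fit_calibration(LEVELS, table.iloc[0].to_numpy())
        est = invert_calibration(fit, [fit.predict(7.0)])
        assert est.s_x0 == pytest.approx(0.0, abs=1e-9)

    def test_exact_inversion_of_noise_free_fit(self, noise_free_model):
        (table,) = generate_calibration_tables(noise_free_model, LEVELS, curves=1)
        fit = fit_calibration(LEVELS, table.iloc[0].to_numpy())
        for target in (0.7, 9.3, 42.0):
            est = invert_calibration(fit, [fit.predict(target)])
            assert est.x0 == pytest.approx(target, rel=1e-10)

    def test_centered_unknown_drops_centering_term(self, toy_fit):
        est = invert_calibration(toy_fit, [toy_fit.y_bar])
        expected = (toy_fit.residual_sd / toy_fit.slope) * math.sqrt(1.0 + 1.0 / 3.0)
        assert est.s_x0 == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n_rep", [1, 2, 5, 50])
    def test_sx0_non_increasing_in_replicates(self, toy_fit, n_rep):
        est1 = invert_calibration(toy_fit, [4.0])
        est_n = invert_calibration(toy_fit, [4.0] * n_rep)
        assert est_n.s_x0 <= est1.s_x0 + 1e-15

    def test_sx0_limit_as_n_grows(self, toy_fit):
        est = invert_calibration(toy_fit, [4.0] * 100_000)
        limit = (toy_fit.residual_sd / toy_fit.slope) * math.sqrt(
            1.0 / 3.0
            + (4.0 - toy_fit.y_bar) ** 2 / (toy_fit.slope**2 * toy_fit.sxx)
        )
        assert est.s_x0 == pytest.approx(limit, rel=1e-4)

    def test_empty_unknowns_rejected(self, toy_fit):
        with pytest.raises(ValueError, match="non-empty"):
            invert_calibration(toy_fit, [])


class TestRelativeCalibrationUncertainty:
    def test_zero_sx0(self):
        est = ConcentrationEstimate(x0=9.3, y0_bar=1.0, N=1, s_x0=0.0)
        assert relative_calibration_uncertainty(est) == 0.0

    def test_table_consistent_division(self):
        est = ConcentrationEstimate(x0=9.30, y0_bar=1.0, N=1, s_x0=0.24)
        assert relative_calibration_uncertainty(est) == pytest.approx(2.58, abs=0.005)

    def test_scale_invariance(self):
        a = ConcentrationEstimate(9.3, 1.0, 1, 0.24)
        b = ConcentrationEstimate(18.6, 1.0, 1, 0.48)
        assert relative_calibration_uncertainty(a) == pytest.approx(
            relative_calibration_uncertainty(b)
        )

    def test_nonpositive_x0_rejected(self):
        est = ConcentrationEstimate(x0=-1.0, y0_bar=0.0, N=1, s_x0=0.1)
        with pytest.raises(ValueError, match="x0"):
            relative_calibration_uncertainty(est)


class TestSlopeConfidenceInterval:
    def test_classical_contains_true_slope_for_clean_data(self):
        x, y, ids = pooled_default_data(seed=3)
        fit = fit_calibration(x, y, curve_ids=ids)
        lo, hi = slope_confidence_interval(fit, method="between_curves")
        assert lo < DEFAULT_SLOPE < hi

    def test_between_curves_coverage_sane(self):
        hits = 0
        reps = 50
        for seed in range(reps):
            x, y, ids = pooled_default_data(seed=seed)
            fit = fit_calibration(x, y, curve_ids=ids)
            lo, hi = slope_confidence_interval(fit, method="between_curves")
            hits += lo <= DEFAULT_SLOPE <= hi
        assert hits / reps >= 0.8

    def test_unknown_method_rejected(self, toy_fit):
        with pytest.raises(ValueError, match="method"):
            slope_confidence_interval(toy_fit, method="bogus")

    def test_hc3_wider_than_classical_under_heteroscedasticity(self):
        x, y, ids = pooled_default_data(seed=5)
        fit = fit_calibration(x, y, curve_ids=ids)
        c_lo, c_hi = slope_confidence_interval(fit, method="classical")
        r_lo, r_hi = slope_confidence_interval(fit, method="hc3")
        assert (r_hi - r_lo) > (c_hi - c_lo)


class TestLoqRule:
    def test_reported_loq_level_passes(self):
        result = qualify_loq(96.67, 0.91, 28000.0, 500.0)
        assert result.passed and result.reasons == []

    def test_accuracy_violation(self):
        result = qualify_loq(94.9, 0.91, 28000.0, 500.0)
        assert not result.passed
        assert any("accuracy" in r for r in result.reasons)

    def test_rsd_exactly_five_fails(self):
        result = qualify_loq(100.0, 5.0, 28000.0, 500.0)
        assert not result.passed
        assert any("RSD" in r for r in result.reasons)

    def test_blank_ratio_violation(self):
        result = qualify_loq(100.0, 1.0, 4000.0, 500.0)
        assert not result.passed
        assert any("blank" in r for r in result.reasons)

    def test_all_violations_listed(self):
        result = qualify_loq(90.0, 6.0, 100.0, 500.0)
        assert len(result.reasons) == 3


@given(
    slope=st.floats(0.5, 1e5),
    intercept=st.floats(-1e4, 1e4),
    target=st.floats(0.1, 100.0),
)
def test_inverse_prediction_is_exact_for_noise_free_lines(slope, intercept, target):
    x = np.array([0.5, 1.0, 5.0, 10.0, 20.0, 50.0])
    y = slope * x + intercept
    fit = fit_calibration(x, y)
    est = invert_calibration(fit, [slope * target + intercept])
    assert est.x0 == pytest.approx(target, rel=1e-6, abs=1e-9)
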