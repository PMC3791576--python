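import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromval.synth import (
    DEFAULT_STRESS_CONDITIONS,
    DegradationSpec,
    generate_stress_table,
)
from chromval.validation import (
    PeakPurityRecord,
    RecoveryExperiment,
    ReplicateSeries,
    RobustnessCriteria,
    RobustnessRow,
    accuracy_pct,
    compare_f_factor,
    evaluate_robustness,
    f_factor,
    recovery_summary,
    rsd,
    summarize_stress,
    truncate_pct,
)


class TestRsd:
    def test_constant_series_is_zero(self):
        assert rsd([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value(self):
        assert rsd([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="two values"):
            rsd([1.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            rsd([-1.0, 1.0])

    @given(
        scale=st.floats(1e-3, 1e3),
        values=st.lists(st.floats(1.0, 100.0), min_size=2, max_size=10),
    )
    def test_scale_invariance(self, scale, values):
        assert rsd(np.array(values) * scale) == pytest.approx(rsd(values), rel=1e-6, abs=1e-9)


class TestAccuracy:
    def test_identity(self):
        assert accuracy_pct(7.0, 7.0) == 100.0

    def test_table_first_row(self):
        assert truncate_pct(accuracy_pct(11.91, 12.00)) == 99.25

    def test_table_third_row_truncating_display(self):
        value = accuracy_pct(18.30, 18.00)
        assert value == pytest.approx(101.6667, abs=1e-4)
        assert truncate_pct(value) == 101.66  # not 101.67

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError, match="nominal"):
            accuracy_pct(1.0, 0.0)

    @given(x=st.floats(0.1, 1e4))
    def test_identity_property(self, x):
        assert accuracy_pct(x, x) == pytest.approx(100.0)


class TestTruncation:
    @pytest.mark.parametrize(
        "value,expected",
        [(101.66666, 101.66), (100.4960, 100.49), (99.25, 99.25), (100.579, 100.57)],
    )
    def test_truncates_toward_zero(self, value, expected):
        assert truncate_pct(value) == expected


class TestRecovery:
    def test_grand_mean_matches_reported_value(self):
        experiments = [
            RecoveryExperiment(12.00, [11.91]),
            RecoveryExperiment(14.00, [14.08]),
            RecoveryExperiment(18.00, [18.30]),
        ]
        summary = recovery_summary(experiments)
        assert truncate_pct(summary.mean_recovery_pct) == 100.49

    def test_single_exact_experiment_has_absent_rsd(self):
        summary = recovery_summary([RecoveryExperiment(10.0, [10.0])])
        assert summary.mean_recovery_pct == pytest.approx(100.0)
        assert summary.recovery_rsd is None  # absent, not zero

    def test_symmetric_pairs_average_to_100(self):
        for d in (0.5, 1.0, 3.7):
            experiments = [
                RecoveryExperiment(100.0, [100.0 - d]),
                RecoveryExperiment(100.0, [100.0 + d]),
            ]
            summary = recovery_summary(experiments)
            assert summary.mean_recovery_pct == pytest.approx(100.0, abs=1e-12)

    def test_per_level_sd(self):
        exp = RecoveryExperiment(12.0, [11.9, 12.0, 12.1])
        sd = exp.recovery_sd
        assert sd == pytest.approx(100.0 / 12.0 * np.std([11.9, 12.0, 12.1], ddof=1))

    def test_global_pooling_uses_all_individuals(self):
        experiments = [
            RecoveryExperiment(12.0, [11.9, 12.1]),
            RecoveryExperiment(14.0, [13.9, 14.1]),
        ]
        summary = recovery_summary(experiments)
        assert summary.n_individual == 4
        assert summary.recovery_rsd is not None

    def test_per_level_pooling_flag(self):
        experiments = [
            RecoveryExperiment(12.0, [11.9, 12.1]),
            RecoveryExperiment(14.0, [13.9, 14.1]),
        ]
        g = recovery_summary(experiments, pooling="global").recovery_rsd
        p = recovery_summary(experiments, pooling="per_level").recovery_rsd
        assert g is not None and p is not None and g != p

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            recovery_summary([])


class TestFFactor:
    def test_equal_areas(self):
        assert f_factor(100.0, 100.0) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="area_260"):
            f_factor(100.0, 0.0)

    def test_stressed_factor_consistent_with_reference(self):
        assert compare_f_factor(3.52, 3.55)

    def test_inconsistent_outside_tolerance(self):
        assert not compare_f_factor(3.40, 3.55)

    def test_purity_record_computes_ratio(self):
        record = PeakPurityRecord(area_240=355.0, area_260=100.0)
        assert record.f_factor == pytest.approx(3.55)


class TestStressSummary:
    def make_series(self, label, values):
        return ReplicateSeries(label=label, level=100.0, values=np.asarray(values))

    def test_unstressed_equals_100(self):
        s = summarize_stress(self.make_series("control", [100.0, 100.0]), 100.0, 0)
        assert s.recovered_pct_mean == pytest.approx(100.0)
        assert s.impurity_count == 0

    def test_acidic_simulation_near_target(self):
        spec = DEFAULT_STRESS_CONDITIONS[1]
        table = generate_stress_table(spec, 100.0, replicates=50, seed=9)
        s = summarize_stress(
            self.make_series("acidic", table["parent"].to_numpy()), 100.0, 1
        )
        # 50 replicates at ~2% RSD: mean within ~4 standard errors
        assert s.recovered_pct_mean == pytest.approx(16.67, abs=0.2)
        assert s.impurity_count == 1

    def test_neutral_heat_simulation_near_target(self):
        spec = DEFAULT_STRESS_CONDITIONS[2]
        table = generate_stress_table(spec, 100.0, replicates=50, seed=10)
        s = summarize_stress(
            self.make_series("neutral-heat", table["parent"].to_numpy()), 100.0, 1
        )
        assert s.recovered_pct_mean == pytest.approx(84.57, abs=0.5)

    def test_undegraded_run_property(self):
        spec = DegradationSpec("control", 0.0, 12.0, replicate_rsd=0.0)
        table = generate_stress_table(spec, 100.0, replicates=3, seed=0)
        s = summarize_stress(
            self.make_series("control", table["parent"].to_numpy()), 100.0, 0
        )
        assert s.recovered_pct_mean == pytest.approx(100.0, rel=1e-12)

    def test_bad_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            summarize_stress(self.make_series("x", [1.0]), 0.0, 0)


def nominal_row(factor, level, **overrides):
    values = dict(assay_pct=100.0, resolution=9.6, plates=11800.0, tailing=1.1)
    values.update(overrides)
    return RobustnessRow(factor=factor, level=level, **values)


class TestRobustness:
    def test_all_nominal_passes(self):
        grid = [nominal_row(f, lv) for f in ("flow", "temp", "pH") for lv in "abc"]
        report = evaluate_robustness(grid)
        assert report.passed
        assert all(f.assay_rsd == 0.0 for f in report.factors)

    def test_low_resolution_fails_resolution_criterion(self):
        grid = [nominal_row("flow", "a"), nominal_row("flow", "b", resolution=8.5)]
        report = evaluate_robustness(grid)
        assert not report.passed
        (flow,) = report.factors
        assert not flow.resolution_ok
        assert flow.assay_rsd_ok and flow.plates_ok and flow.tailing_ok

    def test_assay_rsd_criterion(self):
        grid = [
            nominal_row("flow", "a", assay_pct=97.0),
            nominal_row("flow", "b", assay_pct=103.0),
        ]
        report = evaluate_robustness(grid)
        assert not report.factors[0].assay_rsd_ok

    def test_mixed_factor_row_rejected(self):
        with pytest.raises(ValueError, match="one factor"):
            nominal_row("flow+pH", "a")

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="two levels"):
            evaluate_robustness([nominal_row("flow", "a")])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_robustness([])

    def test_custom_criteria(self):
        grid = [nominal_row("flow", "a", plates=5000.0), nominal_row("flow", "b", plates=5100.0)]
        relaxed = RobustnessCriteria(plates_min=4000.0)
        assert evaluate_robustness(grid, relaxed).passed
        assert not evaluate_robustness(grid).passed
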