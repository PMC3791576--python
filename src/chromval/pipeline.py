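"""End-to-end run: generate -> integrate -> calibrate -> validate -> budget.

Every stochastic stage draws from its own child of the run seed (spawned
in a fixed order from ``numpy.random.SeedSequence``), so a stage can be
regenerated in isolation and two runs with the same configuration are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from chromval import calibration as cal
from chromval import chromatograms as chrom
from chromval import synth
from chromval import uncertainty as unc
from chromval import validation as val
from chromval.config import RunConfig, validate_config

__all__ = ["ConfigValidationError", "PipelineRun", "run_full_validation"]

log = logging.getLogger("chromval.pipeline")

_STAGES = (
    "calibration",
    "precision",
    "accuracy",
    "recovery",
    "sample",
    "stress",
    "chromatogram",
    "robustness",
)


class ConfigValidationError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "invalid run configuration:\n" + "\n".join(f"- {v}" for v in violations)
        )


def _stage_seeds(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    rngs = {}
    for name, child in zip(_STAGES, children):
        log.info("stage %-12s seed lineage %s", name, child)
        rngs[name] = np.random.default_rng(child)
    return rngs


@dataclass
class PipelineRun:
    """Everything a full validation run produced, plus the file bundle."""

    config: RunConfig
    fit: cal.CalibrationFit
    results: dict
    calibration_tables: list[pd.DataFrame]
    trace: chrom.Chromatogram
    peaks: list[chrom.Peak]
    budget: unc.UncertaintyBudget

    @property
    def passed(self) -> bool:
        return self.results["criteria"]["passed"]


def _degradation_spec(cond) -> synth.DegradationSpec:
    if cond.rate_constant_per_h is not None:
        k = cond.rate_constant_per_h
    else:
        k = synth.rate_from_remaining(cond.remaining_pct, cond.duration_h)
    return synth.DegradationSpec(
        condition_label=cond.label,
        rate_constant=k,
        duration=cond.duration_h,
        impurity_channels=cond.impurity_channels,
        replicate_rsd=cond.replicate_rsd_pct,
    )


def run_full_validation(config: RunConfig, out_dir: str | Path | None = None) -> PipelineRun:
    """Run the whole pipeline and (optionally) write the report bundle.

    Raises :class:`ConfigValidationError` before writing anything when
    the configuration is invalid. The bundle contains the calibration
    tables, the fit record, a validation summary, a stress summary, the
    uncertainty budget, the synthetic chromatogram with its peak table,
    and a machine-readable ``results.json``.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigValidationError(violations)
    rngs = _stage_seeds(config.seed)
    model = synth.ResponseModel(
        true_slope=config.slope,
        true_intercept=config.intercept,
        noise_rsd_by_level=dict(config.noise_rsd_by_level),
        seed=config.seed,
    )

    # --- calibration -------------------------------------------------------
    rng = rngs["calibration"]
    tables = []
    for _ in range(config.calibration_curves):
        tables.append(
            pd.DataFrame(
                {
                    lv: synth.generate_replicate_areas(
                        model, lv, config.replicates_per_point, rng
                    )
                    for lv in config.calibration_levels
                }
            )
        )
    xs, ys, ids = [], [], []
    for i, table in enumerate(tables):
        for lv in table.columns:
            for area in table[lv]:
                xs.append(float(lv))
                ys.append(float(area))
                ids.append(i)
    fit = cal.fit_calibration(xs, ys, curve_ids=ids)
    per_curve_rsd = (
        val.rsd(fit.per_curve_slopes) if len(fit.per_curve_slopes) >= 2 else None
    )

    def to_conc(areas: np.ndarray) -> np.ndarray:
        return (np.asarray(areas) - fit.intercept) / fit.slope

    # --- precision ---------------------------------------------------------
    rng = rngs["precision"]
    precision_rows = []
    for lv in config.precision_levels:
        intraday = synth.generate_replicate_areas(model, lv, config.intraday_n, rng)
        interday = synth.generate_replicate_areas(model, lv, config.interday_n, rng)
        precision_rows.append(
            {
                "level": lv,
                "intraday_rsd_pct": val.rsd(intraday),
                "interday_rsd_pct": val.rsd(interday),
            }
        )

    # --- accuracy on spiked placebo ---------------------------------------
    rng = rngs["accuracy"]
    accuracy_rows = []
    loq_inputs = None
    for lv in config.accuracy_levels:
        areas = synth.generate_replicate_areas(model, lv, config.accuracy_n, rng)
        concs = to_conc(areas)
        row = {
            "level": lv,
            "accuracy_pct": val.accuracy_pct(float(concs.mean()), lv),
            "accuracy_rsd_pct": val.rsd(concs),
        }
        accuracy_rows.append(row)
        if lv == config.loq_level:
            loq_inputs = (row["accuracy_pct"], row["accuracy_rsd_pct"], float(areas.mean()))
    if loq_inputs is None:
        areas = synth.generate_replicate_areas(
            model, config.loq_level, config.accuracy_n, rng
        )
        concs = to_conc(areas)
        loq_inputs = (
            val.accuracy_pct(float(concs.mean()), config.loq_level),
            val.rsd(concs),
            float(areas.mean()),
        )
    loq = cal.qualify_loq(*loq_inputs, blank_response=config.blank_mean_area)

    # --- recovery on spiked gel -------------------------------------------
    rng = rngs["recovery"]
    experiments = []
    for target in config.recovery_targets:
        areas = synth.generate_replicate_areas(model, target, config.recovery_n, rng)
        experiments.append(
            val.RecoveryExperiment(
                target_concentration=target, measured_concentrations=to_conc(areas)
            )
        )
    recovery = val.recovery_summary(experiments)
    u_acc = (
        unc.u_accuracy(recovery.recovery_rsd, recovery.n_individual)
        if recovery.recovery_rsd is not None
        else 0.0
    )

    # --- sample assay: calibration + precision components ------------------
    rng = rngs["sample"]
    sample_areas = synth.generate_replicate_areas(
        model, config.sample_concentration, config.sample_replicates, rng
    )
    estimate = cal.invert_calibration(fit, sample_areas)
    u_cal = cal.relative_calibration_uncertainty(estimate)
    sample_series = val.ReplicateSeries(
        label="sample", level=config.sample_concentration, values=to_conc(sample_areas)
    )
    u_prec = unc.u_precision(sample_series)

    # --- stress ------------------------------------------------------------
    rng = rngs["stress"]
    stress_results = []
    for cond in config.stress_conditions:
        spec = _degradation_spec(cond)
        table = synth.generate_stress_table(
            spec,
            config.stress_initial_concentration,
            config.stress_replicates,
            seed=int(rng.integers(2**31 - 1)),
        )
        series = val.ReplicateSeries(
            label=cond.label,
            level=config.stress_initial_concentration,
            values=table["parent"].to_numpy(),
        )
        stress_results.append(
            val.summarize_stress(
                series,
                control_mean_area=config.stress_initial_concentration,
                impurity_peak_count=spec.impurity_channels,
            )
        )

    # --- chromatogram + system suitability ---------------------------------
    peak_specs = [
        synth.PeakSpec(
            retention_time=p.retention_time,
            area=p.area,
            plate_count=p.plate_count,
            tailing_factor=p.tailing_factor,
            model=p.model,
        )
        for p in config.peaks
    ]
    trace = synth.synthesize_chromatogram(
        peak_specs,
        duration=config.chromatogram_duration_min,
        sampling_interval=config.sampling_interval_min,
        baseline_noise_sd=config.baseline_noise_sd,
        seed=int(rngs["chromatogram"].integers(2**31 - 1)),
    )
    peaks = chrom.detect_and_integrate(trace)
    suitability: dict[str, float | None] = {
        "plates": None,
        "tailing": None,
        "resolution": None,
    }
    if peaks:
        main_peak = peaks[-1]
        suitability["plates"] = chrom.theoretical_plates(main_peak)
        suitability["tailing"] = chrom.tailing_factor(main_peak)
        if len(peaks) >= 2:
            suitability["resolution"] = chrom.resolution(peaks[-2], peaks[-1])

    # --- robustness (injected metric shifts, no physics) -------------------
    rng = rngs["robustness"]
    nominal = config.robustness
    grid = []
    for factor in ("flow_rate", "column_temperature", "mobile_phase_pH"):
        for level in ("low", "nominal", "high"):
            shift = 1.0 + rng.normal(0.0, nominal.perturbation_rsd_pct / 100.0, 4)
            grid.append(
                val.RobustnessRow(
                    factor=factor,
                    level=level,
                    assay_pct=nominal.assay_pct * shift[0],
                    resolution=nominal.resolution * shift[1],
                    plates=nominal.plates * shift[2],
                    tailing=nominal.tailing * shift[3],
                )
            )
    robustness = val.evaluate_robustness(grid)

    # --- budget -------------------------------------------------------------
    spec = unc.StandardSpec(
        certified_purity_pct=config.standard_purity_pct,
        preparation_uncertainty_pct=config.preparation_uncertainty_pct,
    )
    u_std = unc.u_standard(unc.u_stock(spec), config.preparation_uncertainty_pct)
    budget = unc.expanded_uncertainty(
        u_std,
        u_cal,
        u_prec,
        u_acc,
        coverage_factor=config.coverage_factor,
        concentration=config.sample_concentration,
    )

    # --- pass/fail criteria -------------------------------------------------
    criterion_levels = set(config.precision_criterion_levels)
    precision_ok = all(
        row["intraday_rsd_pct"] < 2.0 and row["interday_rsd_pct"] < 2.0
        for row in precision_rows
        if row["level"] in criterion_levels
    )
    criteria = {
        "precision_rsd_below_2pct": precision_ok,
        "loq_qualified": loq.passed,
        "robustness_passed": robustness.passed,
    }
    criteria["passed"] = all(criteria.values())

    results = {
        "seed": config.seed,
        "calibration": {
            **cal.fit_record(fit),
            "per_curve_slopes": fit.per_curve_slopes,
            "slope_rsd_pct": per_curve_rsd,
        },
        "precision": precision_rows,
        "accuracy": accuracy_rows,
        "loq": {"passed": loq.passed, "reasons": loq.reasons},
        "recovery": {
            "levels": [
                {
                    "target": lv.target_concentration,
                    "calculated_mean": lv.calculated_mean,
                    "recovery_pct": lv.recovery_pct,
                    "recovery_sd": lv.recovery_sd,
                    "n": lv.n,
                }
                for lv in recovery.levels
            ],
            "mean_recovery_pct": recovery.mean_recovery_pct,
            "recovery_rsd_pct": recovery.recovery_rsd,
            "n_individual": recovery.n_individual,
        },
        "sample": {
            "x0": estimate.x0,
            "s_x0": estimate.s_x0,
            "N": estimate.N,
        },
        "stress": [
            {
                "condition": s.condition_label,
                "recovered_pct_mean": s.recovered_pct_mean,
                "recovered_pct_rsd": s.recovered_pct_rsd,
                "impurity_count": s.impurity_count,
            }
            for s in stress_results
        ],
        "suitability": suitability,
        "robustness": {
            "passed": robustness.passed,
            "factors": [
                {
                    "factor": f.factor,
                    "assay_rsd_pct": f.assay_rsd,
                    "passed": f.passed,
                }
                for f in robustness.factors
            ],
        },
        "budget": {
            "u_standard_pct": budget.u_standard,
            "u_calibration_pct": budget.u_calibration,
            "u_precision_pct": budget.u_precision,
            "u_accuracy_pct": budget.u_accuracy,
            "coverage_factor": budget.coverage_factor,
            "concentration_ug_per_ml": budget.concentration,
            "u_expanded_pct": budget.expanded_relative,
            "u_expanded_ug_per_ml": budget.expanded_absolute,
            "dominant_component": unc.dominant_component(budget),
        },
        "criteria": criteria,
    }

    run = PipelineRun(
        config=config,
        fit=fit,
        results=results,
        calibration_tables=tables,
        trace=trace,
        peaks=peaks,
        budget=budget,
    )
    if out_dir is not None:
        _write_bundle(run, Path(out_dir))
    return run


def _write_bundle(run: PipelineRun, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, table in enumerate(run.calibration_tables, start=1):
        synth.write_area_table(table, out_dir / f"calibration_curve_{i}.csv")
    pd.DataFrame([cal.fit_record(run.fit)]).to_csv(
        out_dir / "calibration_fit.csv", index=False
    )

    res = run.results
    summary = pd.DataFrame(res["precision"]).merge(
        pd.DataFrame(res["accuracy"]), on="level", how="outer"
    )
    recovery_frame = pd.DataFrame(res["recovery"]["levels"])
    summary = pd.concat([summary, recovery_frame], axis=1)
    summary.to_csv(out_dir / "validation_summary.csv", index=False)

    pd.DataFrame(res["stress"]).to_csv(out_dir / "stress_summary.csv", index=False)
    (out_dir / "budget.csv").write_text(unc.budget_report(run.budget))
    chrom.write_chromatogram(run.trace, out_dir / "chromatogram.csv")
    chrom.write_peak_table(run.peaks, out_dir / "peaks.csv")
    (out_dir / "results.json").write_text(
        json.dumps(res, indent=2, sort_keys=True) + "\n"
    )
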