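"""Run configuration for the end-to-end validation pipeline.

The configuration is a pydantic model loadable from YAML or JSON.
Rule violations are collected as data by :func:`validate_config` rather
than raised, so a caller can report every problem at once.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PeakSettings",
    "StressConditionConfig",
    "RobustnessNominal",
    "RunConfig",
    "default_config",
    "load_config",
    "validate_config",
]


class PeakSettings(BaseModel):
    retention_time: float
    area: float
    plate_count: float
    tailing_factor: float = 1.0
    model: str = "gaussian"


class StressConditionConfig(BaseModel):
    """One stress condition; give either remaining_pct or rate_constant_per_h."""

    label: str
    duration_h: float
    remaining_pct: float | None = None
    rate_constant_per_h: float | None = None
    impurity_channels: int = 1
    replicate_rsd_pct: float = 1.0


class RobustnessNominal(BaseModel):
    """Nominal suitability metrics the robustness grid perturbs.

    Robustness perturbations are injected as direct relative shifts on
    these metrics; no physics of flow/temperature/pH is modelled.
    """

    assay_pct: float = 100.0
    resolution: float = 9.6
    plates: float = 11800.0
    tailing: float = 1.10
    perturbation_rsd_pct: float = 0.3


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int | None = None
    out_dir: str | None = None

    # detector response
    slope: float = 44446.17
    intercept: float = 5597.38
    noise_rsd_by_level: dict[float, float] = Field(
        default_factory=lambda: {0.5: 0.96, 5.0: 1.34, 10.0: 0.78, 50.0: 1.46}
    )

    # calibration design
    calibration_levels: list[float] = Field(
        default_factory=lambda: [0.5, 1.0, 5.0, 10.0, 20.0, 50.0]
    )
    calibration_curves: int = 5
    replicates_per_point: int = 1

    # precision / accuracy / recovery designs
    precision_levels: list[float] = Field(default_factory=lambda: [0.5, 5.0, 10.0, 50.0])
    intraday_n: int = 5
    interday_n: int = 5
    precision_criterion_levels: list[float] = Field(
        default_factory=lambda: [5.0, 10.0, 50.0]
    )
    accuracy_levels: list[float] = Field(default_factory=lambda: [0.5, 5.0, 10.0, 50.0])
    accuracy_n: int = 3
    recovery_targets: list[float] = Field(default_factory=lambda: [12.0, 14.0, 18.0])
    recovery_n: int = 3
    loq_level: float = 0.5
    blank_mean_area: float = 500.0

    # stress design
    stress_conditions: list[StressConditionConfig] = Field(
        default_factory=lambda: [
            StressConditionConfig(
                label="photolytic", duration_h=4.0, remaining_pct=48.86,
                replicate_rsd_pct=1.48,
            ),
            StressConditionConfig(
                label="acidic", duration_h=12.0, remaining_pct=16.67,
                replicate_rsd_pct=1.95,
            ),
            StressConditionConfig(
                label="neutral-heat", duration_h=12.0, remaining_pct=84.57,
                replicate_rsd_pct=0.86,
            ),
            StressConditionConfig(
                label="oxidative", duration_h=4.0, remaining_pct=89.01,
                replicate_rsd_pct=1.74,
            ),
            StressConditionConfig(
                label="basic", duration_h=12.0, remaining_pct=10.47,
                impurity_channels=2, replicate_rsd_pct=2.10,
            ),
        ]
    )
    stress_initial_concentration: float = 100.0
    stress_replicates: int = 3

    # chromatogram
    peaks: list[PeakSettings] = Field(
        default_factory=lambda: [
            PeakSettings(retention_time=4.2, area=4.0e5, plate_count=30000.0),
            PeakSettings(
                retention_time=5.8, area=4.5e5, plate_count=11511.0,
                tailing_factor=1.1, model="emg",
            ),
        ]
    )
    chromatogram_duration_min: float = 8.0
    sampling_interval_min: float = 0.002
    baseline_noise_sd: float = 0.0

    # uncertainty budget
    standard_purity_pct: float = 99.50
    preparation_uncertainty_pct: float | None = None
    coverage_factor: float = 2.0
    sample_concentration: float = 9.30
    sample_replicates: int = 5

    robustness: RobustnessNominal = Field(default_factory=RobustnessNominal)


def default_config(seed: int | None = None) -> RunConfig:
    return RunConfig(seed=seed)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {path} is not a mapping")
    return RunConfig(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every rule violation in the configuration.

    Returns an empty list iff the configuration is runnable; each
    violation names the offending field or stress condition.
    """
    v: list[str] = []
    if config.seed is None:
        v.append("seed: a seed is mandatory")
    if not config.calibration_levels:
        v.append("calibration_levels: must be non-empty")
    if any(lv <= 0 for lv in config.calibration_levels):
        v.append("calibration_levels: all levels must be positive")
    if len(set(config.calibration_levels)) < 3:
        v.append("calibration_levels: need at least 3 distinct levels")
    if config.calibration_curves < 1:
        v.append("calibration_curves: must be >= 1")
    if config.replicates_per_point < 1:
        v.append("replicates_per_point: must be >= 1")
    if config.slope <= 0:
        v.append("slope: must be positive")
    for lv, noise in config.noise_rsd_by_level.items():
        if noise < 0:
            v.append(f"noise_rsd_by_level[{lv}]: RSD must be >= 0")
    if not config.precision_levels:
        v.append("precision_levels: must be non-empty")
    if config.intraday_n < 2 or config.interday_n < 2:
        v.append("intraday_n/interday_n: precision needs >= 2 replicates")
    if not config.accuracy_levels:
        v.append("accuracy_levels: must be non-empty")
    if config.accuracy_n < 2:
        v.append("accuracy_n: needs >= 2 replicates")
    if not config.recovery_targets:
        v.append("recovery_targets: must be non-empty")
    if config.recovery_n < 1:
        v.append("recovery_n: must be >= 1")
    if config.blank_mean_area < 0:
        v.append("blank_mean_area: must be >= 0")
    if not config.stress_conditions:
        v.append("stress_conditions: must be non-empty")
    for cond in config.stress_conditions:
        prefix = f"stress_conditions[{cond.label}]"
        if cond.duration_h < 0:
            v.append(f"{prefix}: duration must be >= 0")
        if cond.remaining_pct is None and cond.rate_constant_per_h is None:
            v.append(f"{prefix}: give remaining_pct or rate_constant_per_h")
        if cond.remaining_pct is not None and not 0 < cond.remaining_pct <= 100:
            v.append(f"{prefix}: remaining_pct must lie in (0, 100]")
        if cond.rate_constant_per_h is not None and cond.rate_constant_per_h < 0:
            v.append(f"{prefix}: rate_constant must be >= 0")
        if cond.impurity_channels not in (1, 2):
            v.append(f"{prefix}: impurity_channels must be 1 or 2")
        if cond.replicate_rsd_pct < 0:
            v.append(f"{prefix}: replicate_rsd_pct must be >= 0")
    if config.stress_initial_concentration <= 0:
        v.append("stress_initial_concentration: must be positive")
    if config.stress_replicates < 1:
        v.append("stress_replicates: must be >= 1")
    if not config.peaks:
        v.append("peaks: must be non-empty")
    if config.sampling_interval_min <= 0:
        v.append("sampling_interval_min: must be positive")
    if not 0 < config.standard_purity_pct <= 100:
        v.append("standard_purity_pct: must lie in (0, 100]")
    if config.coverage_factor <= 0:
        v.append("coverage_factor: must be positive")
    if config.sample_concentration <= 0:
        v.append("sample_concentration: must be positive")
    if config.sample_replicates < 2:
        v.append("sample_replicates: needs >= 2 replicates")
    return v
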