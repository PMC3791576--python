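"""ICH-style validation statistics: precision RSDs, accuracy, spiked
recovery, the two-wavelength F-factor purity check, stress-test
summaries and robustness evaluation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ReplicateSeries",
    "RecoveryExperiment",
    "RecoverySummary",
    "LevelRecovery",
    "PeakPurityRecord",
    "StressResult",
    "RobustnessRow",
    "RobustnessCriteria",
    "FactorResult",
    "RobustnessReport",
    "rsd",
    "accuracy_pct",
    "truncate_pct",
    "recovery_summary",
    "f_factor",
    "compare_f_factor",
    "summarize_stress",
    "evaluate_robustness",
]


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, ``100 * sample SD / mean`` (%).

    Sample SD uses the n-1 denominator. Needs at least two values and a
    nonzero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD is undefined for a zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def accuracy_pct(measured_mean: float, nominal: float) -> float:
    """Measured mean as a percentage of the nominal concentration."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return 100.0 * measured_mean / nominal


def truncate_pct(value: float, decimals: int = 2) -> float:
    """Truncate a percentage toward zero at `decimals` places.

    Display convention for reported recoveries (e.g. 101.666.. prints
    as 101.66, not 101.67). Internal arithmetic stays at full precision;
    only displayed values go through this.
    """
    scale = 10.0**decimals
    return math.trunc(value * scale) / scale


@dataclass
class ReplicateSeries:
    """Labelled replicate measurements at one nominal level."""

    label: str
    level: float | None
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("values must be non-empty")
        if self.level is not None and self.level <= 0:
            raise ValueError("nominal level must be positive when given")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class RecoveryExperiment:
    """Spiked-sample experiment at one target concentration."""

    target_concentration: float
    measured_concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.measured_concentrations = np.asarray(
            self.measured_concentrations, dtype=float
        )
        if self.target_concentration <= 0:
            raise ValueError("target_concentration must be positive")
        if self.measured_concentrations.size == 0:
            raise ValueError("measured_concentrations must be non-empty")

    @property
    def individual_recoveries(self) -> np.ndarray:
        return 100.0 * self.measured_concentrations / self.target_concentration

    @property
    def recovery_pct(self) -> float:
        return accuracy_pct(
            float(self.measured_concentrations.mean()), self.target_concentration
        )

    @property
    def recovery_sd(self) -> float | None:
        """SD of the individual percent recoveries; None below 2 replicates."""
        if self.measured_concentrations.size < 2:
            return None
        return float(self.individual_recoveries.std(ddof=1))


@dataclass(frozen=True)
class LevelRecovery:
    target_concentration: float
    calculated_mean: float
    recovery_pct: float
    recovery_sd: float | None
    n: int


@dataclass(frozen=True)
class RecoverySummary:
    levels: tuple[LevelRecovery, ...]
    mean_recovery_pct: float
    recovery_rsd: float | None  # s(eta), % — None when undefined
    n_individual: int


def recovery_summary(
    experiments: Sequence[RecoveryExperiment], pooling: str = "global"
) -> RecoverySummary:
    """Summarize spiked recoveries across levels.

    The grand mean averages the per-level recoveries. ``recovery_rsd``
    (s(eta)) is by default the RSD of all individual recoveries pooled
    globally; with ``pooling="per_level"`` it is the mean of the
    within-level recovery RSDs. It is reported as absent (None), never
    zero, when fewer than two recoveries are available.
    """
    if not experiments:
        raise ValueError("need at least one recovery experiment")
    if pooling not in ("global", "per_level"):
        raise ValueError(f"unknown pooling: {pooling!r}")

    levels = tuple(
        LevelRecovery(
            target_concentration=e.target_concentration,
            calculated_mean=float(e.measured_concentrations.mean()),
            recovery_pct=e.recovery_pct,
            recovery_sd=e.recovery_sd,
            n=int(e.measured_concentrations.size),
        )
        for e in experiments
    )
    mean_recovery = float(np.mean([lv.recovery_pct for lv in levels]))

    all_recoveries = np.concatenate([e.individual_recoveries for e in experiments])
    s_eta: float | None
    if pooling == "global":
        s_eta = rsd(all_recoveries) if all_recoveries.size >= 2 else None
    else:
        per_level = [
            rsd(e.individual_recoveries)
            for e in experiments
            if e.individual_recoveries.size >= 2
        ]
        s_eta = float(np.mean(per_level)) if per_level else None

    return RecoverySummary(
        levels=levels,
        mean_recovery_pct=mean_recovery,
        recovery_rsd=s_eta,
        n_individual=int(all_recoveries.size),
    )


# ---------------------------------------------------------------------------
# peak purity (two-wavelength F factor)


def f_factor(area_240: float, area_260: float) -> float:
    """Ratio of the peak areas at 240 nm and 260 nm."""
    if area_260 <= 0:
        raise ValueError("area_260 must be positive")
    if area_240 <= 0:
        raise ValueError("area_240 must be positive")
    return area_240 / area_260


def compare_f_factor(
    observed: float, reference: float, tolerance: float = 0.05
) -> bool:
    """True when an observed F factor agrees with the reference within tolerance."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return abs(observed - reference) <= tolerance


@dataclass(frozen=True)
class PeakPurityRecord:
    area_240: float
    area_260: float
    f_factor: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_factor", f_factor(self.area_240, self.area_260))


# ---------------------------------------------------------------------------
# stress summaries


@dataclass(frozen=True)
class StressResult:
    condition_label: str
    recovered_pct_mean: float
    recovered_pct_rsd: float | None
    impurity_count: int

    def __post_init__(self) -> None:
        if self.recovered_pct_mean < 0:
            raise ValueError("recovered_pct_mean must be >= 0")
        if self.impurity_count < 0:
            raise ValueError("impurity_count must be >= 0")


def summarize_stress(
    parent_areas: ReplicateSeries,
    control_mean_area: float,
    impurity_peak_count: int,
) -> StressResult:
    """Percent of parent remaining relative to an unstressed control.

    The RSD is that of the per-replicate recovered fractions (equal to
    the RSD of the raw areas); it is None with a single replicate.
    """
    if control_mean_area <= 0:
        raise ValueError("control_mean_area must be positive")
    recovered = 100.0 * parent_areas.values / control_mean_area
    return StressResult(
        condition_label=parent_areas.label,
        recovered_pct_mean=float(recovered.mean()),
        recovered_pct_rsd=rsd(recovered) if recovered.size >= 2 else None,
        impurity_count=impurity_peak_count,
    )


# ---------------------------------------------------------------------------
# robustness


@dataclass(frozen=True)
class RobustnessRow:
    """One chromatographic run under a single deliberately varied factor."""

    factor: str
    level: str
    assay_pct: float
    resolution: float
    plates: float
    tailing: float

    def __post_init__(self) -> None:
        if not self.factor or any(sep in self.factor for sep in (",", "+")):
            raise ValueError(
                f"each row must vary exactly one factor, got {self.factor!r}"
            )


@dataclass(frozen=True)
class RobustnessCriteria:
    assay_rsd_max: float = 2.0
    resolution_min: float = 9.0
    plates_min: float = 11500.0
    tailing_max: float = 1.2


@dataclass(frozen=True)
class FactorResult:
    factor: str
    assay_rsd: float
    assay_rsd_ok: bool
    resolution_ok: bool
    plates_ok: bool
    tailing_ok: bool

    @property
    def passed(self) -> bool:
        return (
            self.assay_rsd_ok and self.resolution_ok and self.plates_ok and self.tailing_ok
        )


@dataclass(frozen=True)
class RobustnessReport:
    factors: tuple[FactorResult, ...]
    criteria: RobustnessCriteria

    @property
    def passed(self) -> bool:
        return all(f.passed for f in self.factors)


def evaluate_robustness(
    grid: Sequence[RobustnessRow], criteria: RobustnessCriteria | None = None
) -> RobustnessReport:
    """Evaluate a robustness grid against per-metric acceptance criteria.

    Per factor: RSD of the assay percentages across its levels must stay
    below ``assay_rsd_max``; every row must additionally satisfy the
    resolution, plate-count and tailing bounds.
    """
    if not grid:
        raise ValueError("robustness grid must be non-empty")
    criteria = criteria or RobustnessCriteria()

    by_factor: dict[str, list[RobustnessRow]] = {}
    for row in grid:
        by_factor.setdefault(row.factor, []).append(row)

    results = []
    for factor, rows in by_factor.items():
        if len(rows) < 2:
            raise ValueError(f"factor {factor!r} needs at least two levels")
        assay_rsd = rsd([r.assay_pct for r in rows])
        results.append(
            FactorResult(
                factor=factor,
                assay_rsd=assay_rsd,
                assay_rsd_ok=assay_rsd < criteria.assay_rsd_max,
                resolution_ok=all(r.resolution > criteria.resolution_min for r in rows),
                plates_ok=all(r.plates > criteria.plates_min for r in rows),
                tailing_ok=all(r.tailing < criteria.tailing_max for r in rows),
            )
        )
    return RobustnessReport(factors=tuple(results), criteria=criteria)
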