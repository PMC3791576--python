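"""Four-component measurement-uncertainty budget (ISO-GUM style).

All components are carried on the relative (%) scale. The expanded
relative uncertainty is the coverage factor times the quadratic
combination of the standard, calibration, precision and accuracy
components; the absolute value applies that percentage to the sample
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from chromval.validation import ReplicateSeries, rsd

__all__ = [
    "StandardSpec",
    "UncertaintyBudget",
    "u_stock",
    "u_standard",
    "u_precision",
    "u_accuracy",
    "expanded_uncertainty",
    "dominant_component",
    "budget_report",
    "parse_budget_report",
]

_COMPONENT_NAMES = ("standard", "calibration", "precision", "accuracy")


@dataclass(frozen=True)
class StandardSpec:
    """Certified reference standard: purity (%) and optional preparation term."""

    certified_purity_pct: float
    preparation_uncertainty_pct: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.certified_purity_pct <= 100:
            raise ValueError("certified purity must lie in (0, 100]")
        if (
            self.preparation_uncertainty_pct is not None
            and self.preparation_uncertainty_pct < 0
        ):
            raise ValueError("preparation uncertainty must be >= 0 when present")


def u_stock(spec: StandardSpec) -> float:
    """Stock-standard uncertainty from the certified purity.

    Rectangular distribution over the purity tolerance:
    ``(100 - P) / sqrt(3)`` on the % scale.
    """
    return (100.0 - spec.certified_purity_pct) / math.sqrt(3.0)


def u_standard(u_stock_pct: float, u_preparation_pct: float | None = None) -> float:
    """Quadratic addition of the stock and preparation terms.

    With independent standard preparations at each level the preparation
    term is absent and the stock value passes through unchanged.
    """
    if u_stock_pct < 0:
        raise ValueError("u_stock must be >= 0")
    if u_preparation_pct is None:
        return u_stock_pct
    if u_preparation_pct < 0:
        raise ValueError("u_preparation must be >= 0")
    return math.hypot(u_stock_pct, u_preparation_pct)


def u_precision(series: ReplicateSeries) -> float:
    """Precision component: RSD of the replicates divided by sqrt(n) (%)."""
    if series.n < 2:
        raise ValueError("precision needs at least two replicates")
    return rsd(series.values) / math.sqrt(series.n)


def u_accuracy(recovery_rsd_pct: float, n: int) -> float:
    """Accuracy component: recovery RSD s(eta) divided by sqrt(n) (%)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if recovery_rsd_pct < 0:
        raise ValueError("recovery RSD must be >= 0")
    return recovery_rsd_pct / math.sqrt(n)


@dataclass(frozen=True)
class UncertaintyBudget:
    """Assembled budget; construct through :func:`expanded_uncertainty`."""

    u_standard: float
    u_calibration: float
    u_precision: float
    u_accuracy: float
    coverage_factor: float
    concentration: float
    expanded_relative: float
    expanded_absolute: float

    @property
    def components(self) -> dict[str, float]:
        return {
            "standard": self.u_standard,
            "calibration": self.u_calibration,
            "precision": self.u_precision,
            "accuracy": self.u_accuracy,
        }


def expanded_uncertainty(
    u_standard_pct: float,
    u_calibration_pct: float,
    u_precision_pct: float,
    u_accuracy_pct: float,
    coverage_factor: float = 2.0,
    concentration: float = 1.0,
) -> UncertaintyBudget:
    """Combine the four relative components into the expanded uncertainty.

    ``expanded_relative = k * sqrt(sum of squared components)`` (%),
    ``expanded_absolute = expanded_relative * concentration / 100``.
    """
    components = (u_standard_pct, u_calibration_pct, u_precision_pct, u_accuracy_pct)
    for name, value in zip(_COMPONENT_NAMES, components):
        if value < 0:
            raise ValueError(f"u_{name} must be >= 0")
    if coverage_factor <= 0:
        raise ValueError("coverage factor must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    combined = math.sqrt(sum(c * c for c in components))
    expanded_relative = coverage_factor * combined
    return UncertaintyBudget(
        u_standard=u_standard_pct,
        u_calibration=u_calibration_pct,
        u_precision=u_precision_pct,
        u_accuracy=u_accuracy_pct,
        coverage_factor=coverage_factor,
        concentration=concentration,
        expanded_relative=expanded_relative,
        expanded_absolute=expanded_relative * concentration / 100.0,
    )


def dominant_component(budget: UncertaintyBudget) -> str:
    """Name of the largest relative component."""
    return max(budget.components, key=budget.components.get)


_REPORT_ROWS = (
    ("u_standard_pct", lambda b: b.u_standard),
    ("u_calibration_pct", lambda b: b.u_calibration),
    ("u_precision_pct", lambda b: b.u_precision),
    ("u_accuracy_pct", lambda b: b.u_accuracy),
    ("u_expanded_pct", lambda b: b.expanded_relative),
    ("u_expanded_ug_per_ml", lambda b: b.expanded_absolute),
    ("concentration_ug_per_ml", lambda b: b.concentration),
    ("coverage_factor", lambda b: b.coverage_factor),
)


def budget_report(budget: UncertaintyBudget) -> str:
    """Delimited budget table, values displayed at 2 decimals.

    Rows in reporting order: the four components, expanded %, expanded
    ug/mL, concentration, then the coverage factor.
    """
    lines = ["quantity,value"]
    for name, getter in _REPORT_ROWS:
        lines.append(f"{name},{getter(budget):.2f}")
    return "\n".join(lines) + "\n"


def parse_budget_report(text: str) -> UncertaintyBudget:
    """Rebuild a budget from a report; inverse of `budget_report` at
    display precision (the expanded values are recomputed from the
    rounded components)."""
    values: dict[str, float] = {}
    for line in text.strip().splitlines()[1:]:
        name, _, raw = line.partition(",")
        values[name.strip()] = float(raw)
    try:
        return expanded_uncertainty(
            values["u_standard_pct"],
            values["u_calibration_pct"],
            values["u_precision_pct"],
            values["u_accuracy_pct"],
            coverage_factor=values["coverage_factor"],
            concentration=values["concentration_ug_per_ml"],
        )
    except KeyError as exc:  # pragma: no cover - malformed input
        raise ValueError(f"budget report is missing row {exc}") from exc
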