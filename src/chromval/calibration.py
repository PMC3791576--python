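"""Linear calibration: OLS fit, inverse prediction and its standard
deviation, relative calibration uncertainty, and the LOQ rule.

The inverse-prediction standard deviation is

    s_x0 = (s_r / m) * sqrt(1/N + 1/n + (y0_bar - y_bar)^2 / (m^2 Sxx))

with ``s_r`` the residual SD of the fit on ``n - 2`` degrees of
freedom, ``N`` the number of replicate unknown responses and ``Sxx``
the centred sum of squares of the standard concentrations. ``n`` counts
every point entering the pooled fit (30 when five 6-point curves are
pooled), not the number of distinct levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationFit",
    "ConcentrationEstimate",
    "LoqAssessment",
    "fit_calibration",
    "invert_calibration",
    "relative_calibration_uncertainty",
    "slope_confidence_interval",
    "qualify_loq",
    "fit_record",
]


@dataclass
class CalibrationFit:
    """OLS calibration line plus the design quantities inverse prediction needs."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    x_bar: float
    y_bar: float
    sxx: float
    per_curve_slopes: list[float] | None = None
    # raw data retained for robust/bootstrap standard errors
    x: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a calibration fit needs n >= 3 points")
        if self.sxx <= 0:
            raise ValueError("sxx must be positive")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse-predicted concentration with its standard deviation."""

    x0: float
    y0_bar: float
    N: int
    s_x0: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.s_x0 < 0:
            raise ValueError("s_x0 must be >= 0")
        if not math.isfinite(self.x0):
            raise ValueError("x0 must be finite")


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    curve_ids: Sequence[int] | None = None,
) -> CalibrationFit:
    """Ordinary least-squares line through (level, response) pairs.

    When ``curve_ids`` labels each point with its calibration curve, the
    per-curve slopes are fitted separately as well (for between-curve
    precision of the slope).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and responses must be equal-length 1-D sequences")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentration levels")

    n = x.size
    x_bar = float(x.mean())
    y_bar = float(y.mean())
    sxx = float(((x - x_bar) ** 2).sum())
    if sxx <= 0:
        raise ValueError("zero concentration spread")
    slope = float(((x - x_bar) * (y - y_bar)).sum() / sxx)
    intercept = y_bar - slope * x_bar
    residuals = y - slope * x - intercept
    sse = float((residuals**2).sum())
    sst = float(((y - y_bar) ** 2).sum())
    r_squared = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - sse / sst))
    residual_sd = math.sqrt(max(sse, 0.0) / (n - 2))

    per_curve_slopes = None
    if curve_ids is not None:
        ids = np.asarray(curve_ids)
        if ids.shape != x.shape:
            raise ValueError("curve_ids must match levels in length")
        per_curve_slopes = []
        for cid in pd_unique(ids):
            mask = ids == cid
            xs, ys = x[mask], y[mask]
            if np.unique(xs).size < 2:
                raise ValueError(f"curve {cid!r} has no concentration spread")
            sxx_c = float(((xs - xs.mean()) ** 2).sum())
            per_curve_slopes.append(
                float(((xs - xs.mean()) * (ys - ys.mean())).sum() / sxx_c)
            )

    return CalibrationFit(
        slope=slope,
        intercept=float(intercept),
        r_squared=r_squared,
        residual_sd=residual_sd,
        n=n,
        x_bar=x_bar,
        y_bar=y_bar,
        sxx=sxx,
        per_curve_slopes=per_curve_slopes,
        x=x,
        y=y,
    )


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def slope_confidence_interval(
    fit: CalibrationFit, level: float = 0.95, method: str = "classical"
) -> tuple[float, float]:
    """Confidence interval for the slope.

    ``method``:

    * ``"classical"`` -- homoscedastic OLS t-interval,
      ``slope +/- t * s_r / sqrt(Sxx)``.
    * ``"hc3"`` -- same centre with an HC3 heteroscedasticity-robust
      standard error; appropriate when replicate noise scales with the
      response, which makes the classical interval undercover.
    * ``"between_curves"`` -- t-interval from the independent per-curve
      slopes (requires >= 2 fitted curves); exact under any per-level
      noise because the curve slopes are i.i.d.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    if method == "classical":
        se = fit.residual_sd / math.sqrt(fit.sxx)
        tq = stats.t.ppf(1 - alpha / 2, fit.n - 2)
        return fit.slope - tq * se, fit.slope + tq * se
    if method == "hc3":
        if fit.x is None or fit.y is None:
            raise ValueError("fit does not carry raw data for robust errors")
        e = fit.y - fit.slope * fit.x - fit.intercept
        h = 1.0 / fit.n + (fit.x - fit.x_bar) ** 2 / fit.sxx
        c = (fit.x - fit.x_bar) / fit.sxx
        se = math.sqrt(float((c**2 * e**2 / (1.0 - h) ** 2).sum()))
        tq = stats.t.ppf(1 - alpha / 2, fit.n - 2)
        return fit.slope - tq * se, fit.slope + tq * se
    if method == "between_curves":
        if not fit.per_curve_slopes or len(fit.per_curve_slopes) < 2:
            raise ValueError("between_curves needs >= 2 per-curve slopes")
        slopes = np.asarray(fit.per_curve_slopes)
        k = slopes.size
        se = slopes.std(ddof=1) / math.sqrt(k)
        tq = stats.t.ppf(1 - alpha / 2, k - 1)
        centre = float(slopes.mean())
        return centre - tq * se, centre + tq * se
    raise ValueError(f"unknown method: {method!r}")


def invert_calibration(
    fit: CalibrationFit, unknown_responses: Sequence[float]
) -> ConcentrationEstimate:
    """Inverse prediction of the unknown concentration with its SD."""
    y0 = np.asarray(unknown_responses, dtype=float)
    if y0.size == 0:
        raise ValueError("unknown_responses must be non-empty")
    if fit.slope == 0:
        raise ValueError("cannot invert a calibration with zero slope")
    y0_bar = float(y0.mean())
    big_n = int(y0.size)
    x0 = (y0_bar - fit.intercept) / fit.slope
    s_x0 = (fit.residual_sd / abs(fit.slope)) * math.sqrt(
        1.0 / big_n
        + 1.0 / fit.n
        + (y0_bar - fit.y_bar) ** 2 / (fit.slope**2 * fit.sxx)
    )
    return ConcentrationEstimate(x0=float(x0), y0_bar=y0_bar, N=big_n, s_x0=float(s_x0))


def relative_calibration_uncertainty(estimate: ConcentrationEstimate) -> float:
    """Relative calibration uncertainty, ``100 * s_x0 / x0`` (%)."""
    if estimate.x0 <= 0:
        raise ValueError("x0 must be positive for a relative uncertainty")
    return 100.0 * estimate.s_x0 / estimate.x0


@dataclass(frozen=True)
class LoqAssessment:
    passed: bool
    reasons: list[str]


def qualify_loq(
    level_accuracy_pct: float,
    level_rsd_pct: float,
    level_mean_response: float,
    blank_response: float,
) -> LoqAssessment:
    """Apply the LOQ rule: RSD < 5%, accuracy within +/-5%, response >= 10x blank.

    The RSD bound is strict; the accuracy band is inclusive. Every
    violated criterion is listed in ``reasons``.
    """
    if blank_response < 0:
        raise ValueError("blank_response must be >= 0")
    reasons = []
    if not level_rsd_pct < 5.0:
        reasons.append(f"RSD {level_rsd_pct:.2f}% is not lower than 5%")
    if abs(level_accuracy_pct - 100.0) > 5.0:
        reasons.append(f"accuracy {level_accuracy_pct:.2f}% is outside 100 +/- 5%")
    if level_mean_response < 10.0 * blank_response:
        reasons.append(
            f"mean response {level_mean_response:.4g} is below 10x the blank "
            f"({blank_response:.4g})"
        )
    return LoqAssessment(passed=not reasons, reasons=reasons)


def fit_record(fit: CalibrationFit) -> dict[str, float]:
    """Flat key-value summary of a fit (for the delimited fit record)."""
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "residual_sd": fit.residual_sd,
        "n": float(fit.n),
        "x_bar": fit.x_bar,
        "sxx": fit.sxx,
    }
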