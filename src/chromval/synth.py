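"""Seeded synthetic-data generators standing in for the instrument.

Everything downstream consumes tables or traces produced here: replicate
peak-area tables from a linear detector-response model with per-level
relative noise, stressed-sample tables from first-order degradation
kinetics, and raw chromatogram traces built from Gaussian or
exponentially-modified-Gaussian (EMG) peak shapes.

All randomness flows through ``numpy.random.default_rng`` seeded from
explicit integers, so identical parameters and seed reproduce identical
output byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import exponnorm, norm

from chromval.chromatograms import Chromatogram

__all__ = [
    "DEFAULT_SLOPE",
    "DEFAULT_INTERCEPT",
    "DEFAULT_NOISE_RSD",
    "DEFAULT_STRESS_CONDITIONS",
    "ResponseModel",
    "DegradationSpec",
    "PeakSpec",
    "generate_calibration_tables",
    "generate_replicate_areas",
    "generate_stress_table",
    "synthesize_chromatogram",
    "rate_from_remaining",
    "emg_tailing",
    "emg_tau_for_tailing",
    "write_area_table",
    "read_area_table",
]

# Default detector response: area = 44446.17 x + 5597.38 (x in ug/mL),
# with replicate RSDs in the ~0.8-1.5% band typical of the target assay.
DEFAULT_SLOPE = 44446.17
DEFAULT_INTERCEPT = 5597.38
DEFAULT_NOISE_RSD: dict[float, float] = {0.5: 0.96, 5.0: 1.34, 10.0: 0.78, 50.0: 1.46}


@dataclass(frozen=True)
class ResponseModel:
    """Linear detector response with per-level relative replicate noise.

    ``noise_rsd_by_level`` maps concentration (ug/mL) to the relative
    standard deviation (%) of replicate areas at that level; levels not
    present fall back to the nearest mapped level. An empty map means a
    noise-free detector.
    """

    true_slope: float = DEFAULT_SLOPE
    true_intercept: float = DEFAULT_INTERCEPT
    noise_rsd_by_level: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_RSD)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")
        for level, rsd in self.noise_rsd_by_level.items():
            if rsd < 0:
                raise ValueError(f"noise RSD at level {level} must be >= 0")

    def mean_area(self, level: float) -> float:
        return self.true_slope * level + self.true_intercept

    def rsd_for(self, level: float) -> float:
        """RSD (%) at `level`, nearest mapped level if absent; 0 if unmapped."""
        if not self.noise_rsd_by_level:
            return 0.0
        if level in self.noise_rsd_by_level:
            return float(self.noise_rsd_by_level[level])
        nearest = min(self.noise_rsd_by_level, key=lambda lv: abs(lv - level))
        return float(self.noise_rsd_by_level[nearest])


def _noisy_areas(
    rng: np.random.Generator, mean: float, rsd_pct: float, size: int
) -> np.ndarray:
    """Normal draws with SD = RSD * mean, truncated at zero."""
    if rsd_pct == 0:
        return np.full(size, mean)
    draws = rng.normal(mean, rsd_pct / 100.0 * mean, size)
    return np.clip(draws, 0.0, None)


def generate_replicate_areas(
    model: ResponseModel, level: float, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate areas at one concentration level, drawn from `rng`."""
    if level <= 0:
        raise ValueError(f"non-positive concentration level: {level!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    return _noisy_areas(rng, model.mean_area(level), model.rsd_for(level), replicates)


def generate_calibration_tables(
    model: ResponseModel,
    levels: Sequence[float],
    curves: int,
    replicates_per_point: int = 1,
) -> list[pd.DataFrame]:
    """Generate one replicate-area table per calibration curve.

    Each table has one column per concentration level (header = level)
    and ``replicates_per_point`` rows. Deterministic under a fixed
    ``model.seed``.
    """
    levels = [float(lv) for lv in levels]
    if not levels:
        raise ValueError("levels must be non-empty")
    for lv in levels:
        if lv <= 0:
            raise ValueError(f"non-positive concentration level: {lv!r}")
    if curves < 1:
        raise ValueError("curves must be >= 1")
    if replicates_per_point < 1:
        raise ValueError("replicates_per_point must be >= 1")

    rng = np.random.default_rng(model.seed)
    tables = []
    for _ in range(curves):
        data = {
            lv: generate_replicate_areas(model, lv, replicates_per_point, rng)
            for lv in levels
        }
        tables.append(pd.DataFrame(data))
    return tables


# ---------------------------------------------------------------------------
# forced degradation


@dataclass(frozen=True)
class DegradationSpec:
    """First-order stress condition for the parent compound.

    The parent decays as ``exp(-rate_constant * duration)``; the lost
    fraction is split across ``impurity_channels`` impurity peaks.
    """

    condition_label: str
    rate_constant: float  # per hour
    duration: float  # hours
    impurity_channels: int = 1
    replicate_rsd: float = 0.0  # % multiplicative replicate scatter

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.impurity_channels not in (1, 2):
            raise ValueError("impurity_channels must be 1 or 2")
        if self.replicate_rsd < 0:
            raise ValueError("replicate_rsd must be >= 0")

    @property
    def remaining_fraction(self) -> float:
        return math.exp(-self.rate_constant * self.duration)


def rate_from_remaining(remaining_pct: float, duration: float) -> float:
    """First-order rate constant hitting `remaining_pct` after `duration` h."""
    if not 0 < remaining_pct <= 100:
        raise ValueError("remaining_pct must lie in (0, 100]")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return -math.log(remaining_pct / 100.0) / duration


def _stress_spec(label, remaining_pct, rsd, duration, channels) -> DegradationSpec:
    return DegradationSpec(
        condition_label=label,
        rate_constant=rate_from_remaining(remaining_pct, duration),
        duration=duration,
        impurity_channels=channels,
        replicate_rsd=rsd,
    )


#: Default stress panel: (label, target remaining %, replicate RSD %, h, channels).
DEFAULT_STRESS_CONDITIONS: tuple[DegradationSpec, ...] = (
    _stress_spec("photolytic", 48.86, 1.48, 4.0, 1),
    _stress_spec("acidic", 16.67, 1.95, 12.0, 1),
    _stress_spec("neutral-heat", 84.57, 0.86, 12.0, 1),
    _stress_spec("oxidative", 89.01, 1.74, 4.0, 1),
    _stress_spec("basic", 10.47, 2.10, 12.0, 2),
)


def generate_stress_table(
    spec: DegradationSpec,
    initial_concentration: float,
    replicates: int,
    seed: int,
    impurity_weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Replicate parent + impurity amounts after a stress run.

    Columns: ``parent`` and ``impurity_1`` (and ``impurity_2`` for a
    two-channel condition); one row per replicate. With zero
    ``replicate_rsd`` the rows mass-balance exactly:
    parent + sum(impurities) = initial_concentration.
    """
    if initial_concentration <= 0:
        raise ValueError("initial_concentration must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if impurity_weights is None:
        impurity_weights = [1.0 / spec.impurity_channels] * spec.impurity_channels
    if len(impurity_weights) != spec.impurity_channels:
        raise ValueError("impurity_weights length must equal impurity_channels")
    if any(w < 0 for w in impurity_weights) or not math.isclose(
        sum(impurity_weights), 1.0, rel_tol=1e-12
    ):
        raise ValueError("impurity_weights must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    remaining = spec.remaining_fraction
    lost = 1.0 - remaining
    parent_mean = initial_concentration * remaining
    impurity_means = [initial_concentration * lost * w for w in impurity_weights]

    data: dict[str, np.ndarray] = {
        "parent": _noisy_areas(rng, parent_mean, spec.replicate_rsd, replicates)
    }
    for j, mu in enumerate(impurity_means, start=1):
        if mu == 0:
            data[f"impurity_{j}"] = np.zeros(replicates)
        else:
            data[f"impurity_{j}"] = _noisy_areas(rng, mu, spec.replicate_rsd, replicates)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# chromatogram synthesis


@dataclass(frozen=True)
class PeakSpec:
    """Target shape for one synthesized peak.

    ``model`` is ``"gaussian"`` (tailing_factor must be 1) or ``"emg"``
    (exponentially modified Gaussian, tailing_factor >= 1). The Gaussian
    sigma is taken from the half-height plate relation,
    ``sigma = retention_time / sqrt(plate_count)``.
    """

    retention_time: float  # minutes
    area: float
    plate_count: float
    tailing_factor: float = 1.0
    model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention_time must be positive")
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.plate_count <= 0:
            raise ValueError("plate_count must be positive")
        if self.model not in ("gaussian", "emg"):
            raise ValueError(f"unknown peak model: {self.model!r}")
        if self.model == "gaussian" and self.tailing_factor != 1.0:
            raise ValueError("a pure-Gaussian peak has tailing_factor 1")
        if self.model == "emg" and self.tailing_factor < 1.0:
            raise ValueError("an EMG peak needs tailing_factor >= 1")

    @property
    def sigma(self) -> float:
        return self.retention_time / math.sqrt(self.plate_count)


def _emg_grid(sigma: float, tau: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(-8 * sigma, 8 * sigma + 10 * tau, 40001)
    return t, exponnorm.pdf(t, tau / sigma, loc=0.0, scale=sigma)


def emg_tailing(sigma: float, tau: float) -> float:
    """USP tailing factor of the EMG(sigma, tau) shape, measured numerically."""
    if tau <= 0:
        return 1.0
    t, y = _emg_grid(sigma, tau)
    i = int(y.argmax())
    level = 0.05 * y[i]
    li = int(np.where(y[: i + 1] < level)[0][-1])
    t_left = t[li] + (level - y[li]) / (y[li + 1] - y[li]) * (t[li + 1] - t[li])
    ri = i + int(np.where(y[i:] < level)[0][0])
    t_right = t[ri - 1] + (y[ri - 1] - level) / (y[ri - 1] - y[ri]) * (t[ri] - t[ri - 1])
    return float((t_right - t_left) / (2.0 * (t[i] - t_left)))


def emg_tau_for_tailing(sigma: float, tailing: float) -> float:
    """Exponential time constant giving a target USP tailing factor.

    Solved by 1-D root finding on tau/sigma; tailing 1 maps to tau 0.
    """
    if tailing < 1.0:
        raise ValueError("tailing factor must be >= 1")
    if tailing < 1.0 + 1e-9:
        return 0.0
    ratio = brentq(lambda r: emg_tailing(sigma, r * sigma) - tailing, 1e-4, 20.0)
    return float(ratio * sigma)


def _emg_mode_offset(sigma: float, tau: float) -> float:
    """Apex position of EMG(sigma, tau) relative to its Gaussian centre."""
    t, y = _emg_grid(sigma, tau)
    i = int(y.argmax())
    # parabolic refinement of the grid argmax
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    delta = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    return float(t[i] + delta * (t[i + 1] - t[i]))


def synthesize_chromatogram(
    peaks: Sequence[PeakSpec],
    duration: float,
    sampling_interval: float = 0.002,
    baseline_noise_sd: float = 0.0,
    seed: int = 0,
) -> Chromatogram:
    """Sum of peak shapes plus optional Gaussian baseline noise.

    Each peak's numerically integrated area matches its spec within 0.5%
    on a noise-free trace at the default 0.002 min sampling interval.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if baseline_noise_sd < 0:
        raise ValueError("baseline_noise_sd must be >= 0")
    for p in peaks:
        if not 0 <= p.retention_time <= duration:
            raise ValueError(
                f"retention_time {p.retention_time} outside [0, {duration}]"
            )

    times = np.arange(0.0, duration + sampling_interval / 2, sampling_interval)
    trace = np.zeros_like(times)
    for p in sorted(peaks, key=lambda q: q.retention_time):
        tau = emg_tau_for_tailing(p.sigma, p.tailing_factor) if p.model == "emg" else 0.0
        if tau == 0.0:
            trace += p.area * norm.pdf(times, p.retention_time, p.sigma)
        else:
            mu = p.retention_time - _emg_mode_offset(p.sigma, tau)
            trace += p.area * exponnorm.pdf(times, tau / p.sigma, loc=mu, scale=p.sigma)
    if baseline_noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, baseline_noise_sd, times.size)
    return Chromatogram(times, trace)


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_area_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a replicate-area table; header row = concentration levels."""
    if table.isna().any().any():
        raise ValueError("area tables must not contain missing values")
    table.to_csv(path, index=False)


def read_area_table(path: str | Path) -> pd.DataFrame:
    """Read a replicate-area table, restoring float column labels."""
    table = pd.read_csv(path)
    if table.isna().any().any():
        raise ValueError("area tables must not contain missing values")
    table.columns = [float(c) for c in table.columns]
    return table
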