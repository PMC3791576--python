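"""Peak detection, integration and USP system-suitability metrics.

A chromatogram is a strictly increasing time axis plus a same-length
intensity trace. Peaks are integrated above a flat baseline (5th
percentile of the trace) between baseline crossings, with widths read
off by linear interpolation at 50% and 5% of the apex height. The
suitability metrics follow the USP conventions: half-height plate count
``5.54 (tR / W50)^2``, 5%-height tailing ``W05 / (2 f05)`` and
half-height resolution ``1.18 (tR2 - tR1) / (W50_1 + W50_2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Chromatogram",
    "Peak",
    "detect_and_integrate",
    "theoretical_plates",
    "tailing_factor",
    "resolution",
    "read_chromatogram",
    "write_chromatogram",
    "peaks_to_frame",
    "write_peak_table",
]

#: Fraction of the intensity distribution taken as the flat baseline.
BASELINE_PERCENTILE = 5.0


@dataclass
class Chromatogram:
    """Time-intensity trace with a strictly increasing time axis (minutes)."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a chromatogram needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Peak:
    """Integrated peak with the width measurements the metrics need.

    ``width_half`` / ``width_5pct`` are full widths at 50% / 5% of the
    apex height; ``leading_5pct`` is the apex-to-leading-edge distance
    at 5% height. All times in minutes.
    """

    retention_time: float
    area: float
    height: float
    width_half: float
    width_5pct: float
    leading_5pct: float

    def __post_init__(self) -> None:
        if not 0 < self.width_half < self.width_5pct:
            raise ValueError("require 0 < width_half < width_5pct")
        if not 0 < self.leading_5pct < self.width_5pct:
            raise ValueError("require 0 < leading_5pct < width_5pct")
        if self.retention_time <= 0 or self.area <= 0 or self.height <= 0:
            raise ValueError("retention_time, area and height must be positive")


def _parabolic_apex(t: np.ndarray, s: np.ndarray, i: int) -> tuple[float, float]:
    """Refine the apex position/height through the 3-point parabola at i."""
    if i == 0 or i == len(s) - 1:
        return float(t[i]), float(s[i])
    y0, y1, y2 = s[i - 1], s[i], s[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the sample apex
        return float(t[i]), float(s[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = 0.5 * (t[i + 1] - t[i - 1])
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(t[i] + delta * dt), float(height)


def _cross_left(t: np.ndarray, s: np.ndarray, i: int, lo: int, level: float) -> float:
    """Time where the signal crosses `level` walking left from apex i."""
    for k in range(i, lo, -1):
        if s[k - 1] < level <= s[k]:
            frac = (level - s[k - 1]) / (s[k] - s[k - 1])
            return float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return float(t[lo])


def _cross_right(t: np.ndarray, s: np.ndarray, i: int, hi: int, level: float) -> float:
    for k in range(i, hi):
        if s[k + 1] < level <= s[k]:
            frac = (s[k] - level) / (s[k] - s[k + 1])
            return float(t[k] + frac * (t[k + 1] - t[k]))
    return float(t[hi])


def detect_and_integrate(
    trace: Chromatogram, min_height_fraction: float = 0.05
) -> list[Peak]:
    """Detect peaks above a relative threshold and integrate each one.

    Parameters
    ----------
    trace:
        Chromatogram to process.
    min_height_fraction:
        Fraction (in ``(0, 1)``) of the tallest baseline-corrected
        sample a local maximum must reach to count as a peak.

    Returns
    -------
    list of Peak, in retention-time order. A trace with nothing above
    the threshold yields an empty list.
    """
    if not 0 < min_height_fraction < 1:
        raise ValueError("min_height_fraction must lie in (0, 1)")
    t = trace.times
    baseline = float(np.percentile(trace.intensities, BASELINE_PERCENTILE))
    s = trace.intensities - baseline
    smax = float(s.max())
    if smax <= 0:
        return []
    apexes, _ = find_peaks(s, height=min_height_fraction * smax)
    if apexes.size == 0:
        return []

    peaks: list[Peak] = []
    for j, i in enumerate(apexes):
        # bounds: nearest baseline crossing, or valley towards a neighbour
        lo_lim = 0 if j == 0 else int(apexes[j - 1] + np.argmin(s[apexes[j - 1] : i + 1]))
        hi_lim = len(s) - 1 if j == len(apexes) - 1 else int(i + np.argmin(s[i : apexes[j + 1] + 1]))
        lo = lo_lim
        for k in range(i, lo_lim, -1):
            if s[k] <= 0:
                lo = k
                break
        hi = hi_lim
        for k in range(i, hi_lim):
            if s[k] <= 0:
                hi = k
                break
        apex_t, apex_h = _parabolic_apex(t, s, int(i))
        l50 = _cross_left(t, s, int(i), lo, 0.5 * apex_h)
        r50 = _cross_right(t, s, int(i), hi, 0.5 * apex_h)
        l05 = _cross_left(t, s, int(i), lo, 0.05 * apex_h)
        r05 = _cross_right(t, s, int(i), hi, 0.05 * apex_h)
        area = float(np.trapezoid(s[lo : hi + 1], t[lo : hi + 1]))
        peaks.append(
            Peak(
                retention_time=apex_t,
                area=area,
                height=apex_h,
                width_half=r50 - l50,
                width_5pct=r05 - l05,
                leading_5pct=apex_t - l05,
            )
        )
    peaks.sort(key=lambda p: p.retention_time)
    return peaks


def theoretical_plates(peak: Peak) -> float:
    """USP half-height plate count, ``5.54 (tR / W50)^2``."""
    return 5.54 * (peak.retention_time / peak.width_half) ** 2


def tailing_factor(peak: Peak) -> float:
    """USP tailing factor at 5% height, ``W05 / (2 f05)``."""
    return peak.width_5pct / (2.0 * peak.leading_5pct)


def resolution(earlier: Peak, later: Peak) -> float:
    """Half-height resolution ``1.18 (tR2 - tR1) / (W50_1 + W50_2)``.

    Arguments must be in elution order; co-eluting peaks (equal
    retention times) give 0.
    """
    if later.retention_time < earlier.retention_time:
        raise ValueError(
            "peaks passed out of elution order: "
            f"{earlier.retention_time:.4g} min must elute before "
            f"{later.retention_time:.4g} min"
        )
    return (
        1.18
        * (later.retention_time - earlier.retention_time)
        / (earlier.width_half + later.width_half)
    )


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_chromatogram(trace: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.times, "intensity": trace.intensities}).to_csv(
        path, index=False
    )


def read_chromatogram(path: str | Path) -> Chromatogram:
    df = pd.read_csv(path)
    return Chromatogram(df["time_min"].to_numpy(), df["intensity"].to_numpy())


_PEAK_COLUMNS = [
    "retention_time",
    "area",
    "height",
    "width_half",
    "width_5pct",
    "leading_5pct",
]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(p, c) for c in _PEAK_COLUMNS] for p in peaks], columns=_PEAK_COLUMNS
    )


def write_peak_table(peaks: list[Peak], path: str | Path) -> None:
    peaks_to_frame(peaks).to_csv(path, index=False)
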