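"""Turbidimetric tubulin-polymerization curve metrics.

Tubulin assembly is followed by absorbance at 350 nm; polymer mass is
proportional to turbidity. A polymerization time course is summarized by
its baseline, plateau (extent of polymerization), lag time (nucleation)
and maximal assembly rate. None of these have a universal definition, so
the conventions used here are explicit and configurable:

* baseline = mean of the first 5% of points;
* plateau = mean of the last 10% of points;
* lag time = first time the smoothed signal exceeds baseline + 10% of
  the amplitude (plateau − baseline); undefined when the amplitude does
  not exceed three times the baseline noise SD;
* vmax = maximum finite-difference slope of the smoothed signal.

Smoothing is a centered moving average (default window 5 samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TurbidityCurve",
    "PolymMetrics",
    "PolymComparison",
    "curve_metrics",
    "compare_curves",
]


@dataclass
class TurbidityCurve:
    """An A350 time course: strictly increasing time (s), absorbance, label."""

    time: np.ndarray
    a350: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.a350 = np.asarray(self.a350, dtype=float)
        if self.time.shape != self.a350.shape or self.time.ndim != 1:
            raise ValueError("time and a350 must be equal-length 1-D arrays")
        if len(self.time) < 10:
            raise ValueError("a turbidity curve needs at least 10 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class PolymMetrics:
    """Summary metrics of one polymerization curve (lag NaN when undefined)."""

    lag_time: float
    plateau: float
    vmax: float
    baseline: float
    noise_sd: float
    condition: str = ""

    @property
    def amplitude(self) -> float:
        return self.plateau - self.baseline


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    return (pd.Series(y).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def curve_metrics(curve: TurbidityCurve, smooth_window: int = 5,
                  baseline_frac: float = 0.05, plateau_frac: float = 0.10,
                  lag_frac: float = 0.10) -> PolymMetrics:
    """Compute baseline, plateau, lag time and maximal rate of a turbidity curve."""
    t, y = curve.time, curve.a350
    n = len(t)
    n_base = max(1, int(math.ceil(baseline_frac * n)))
    n_plat = max(1, int(math.ceil(plateau_frac * n)))
    baseline = float(y[:n_base].mean())
    plateau = float(y[-n_plat:].mean())
    noise_sd = float(y[:n_base].std(ddof=1)) if n_base >= 2 else 0.0

    smoothed = _smooth(y, smooth_window)
    slopes = np.diff(smoothed) / np.diff(t)
    vmax = float(max(slopes.max(), 0.0))

    amplitude = plateau - baseline
    if amplitude <= 3.0 * noise_sd:
        lag = math.nan
    else:
        above = smoothed > baseline + lag_frac * amplitude
        idx = np.argmax(above)
        lag = float(t[idx]) if above.any() else math.nan
    return PolymMetrics(lag_time=lag, plateau=plateau, vmax=vmax,
                        baseline=baseline, noise_sd=noise_sd,
                        condition=curve.condition)


@dataclass
class PolymComparison:
    """Treated-vs-control fold changes of polymerization metrics.

    ``plateau_ratio`` compares amplitudes (plateau − baseline), i.e. the
    extent of polymerization independent of any baseline offset;
    ``lag_diff`` = treated − control lag (s, NaN if either undefined);
    ``vmax_ratio`` = treated/control maximal rate.
    """

    plateau_ratio: float
    lag_diff: float
    vmax_ratio: float


def compare_curves(control: PolymMetrics, treated: PolymMetrics) -> PolymComparison:
    """Fold-change report between two sets of curve metrics."""
    plateau_ratio = (treated.amplitude / control.amplitude
                     if control.amplitude != 0 else math.nan)
    lag_diff = (treated.lag_time - control.lag_time
                if math.isfinite(treated.lag_time) and math.isfinite(control.lag_time)
                else math.nan)
    vmax_ratio = treated.vmax / control.vmax if control.vmax != 0 else math.nan
    return PolymComparison(plateau_ratio=plateau_ratio, lag_diff=lag_diff,
                           vmax_ratio=vmax_ratio)
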