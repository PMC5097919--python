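"""Incremental-test VO2max determination and game HR / lactate summaries.

The treadmill protocol starts at 10 km/h and adds 1 km/h every 3 min until
exhaustion.  Breath-by-breath gas exchange is smoothed (moving average over
breaths) and interpolated to 1 value per second.  VO2max is the highest
VO2 average over the final 30 s of an exercise stage, accepted when at
least two of three criteria hold: (1) VO2 stabilization across the final
two stages (range < 2.1 mL·kg⁻¹·min⁻¹); (2) respiratory exchange ratio
> 1.1; (3) heart rate above 90% of the age-predicted maximum.  vVO2max is
the lowest stage speed whose final-30-s VO2 reaches VO2max within a small
tolerance — it is the sprint threshold for the time-motion analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BreathSeries",
    "VO2maxResult",
    "PhysioSummary",
    "resample_breaths",
    "vo2max",
    "lactate_summary",
    "hr_summary",
]


@dataclass
class BreathSeries:
    """Breath-by-breath gas exchange during the incremental test."""

    t: np.ndarray            # s, irregular
    vo2: np.ndarray          # mL/kg/min
    vco2: np.ndarray         # same basis
    hr: np.ndarray           # bpm
    stage_speed: np.ndarray  # km/h of the stage each breath belongs to

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.stage_speed = np.asarray(self.stage_speed, dtype=float)
        n = len(self.t)
        if any(len(a) != n for a in (self.vo2, self.vco2, self.hr, self.stage_speed)):
            raise ValueError("all series must have equal length")
        if n < 2:
            raise ValueError("need at least 2 breaths")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class VO2maxResult:
    vo2max: float                    # mL/kg/min
    vvo2max: float                   # km/h
    criteria: dict                   # {"plateau","rer","hr"} -> bool | None
    met_count: int
    accepted: bool
    stage_means: dict                # speed km/h -> final-30-s VO2 mean


@dataclass
class PhysioSummary:
    scope: str
    peak: float
    mean: float


def resample_breaths(series: BreathSeries, smooth_breaths: int = 5) -> pd.DataFrame:
    """Smooth breath-by-breath data and interpolate to a 1-s grid.

    A centred moving average over ``smooth_breaths`` breaths is applied to
    vo2, vco2 and hr, then each is linearly interpolated onto an integer-
    second grid spanning the test.  Stage speed is carried by nearest-breath
    lookup (it is piecewise constant, not smooth).
    """
    if smooth_breaths < 1:
        raise ValueError("smooth_breaths must be >= 1")
    df = pd.DataFrame(
        {"t": series.t, "vo2": series.vo2, "vco2": series.vco2, "hr": series.hr}
    )
    sm = df[["vo2", "vco2", "hr"]].rolling(smooth_breaths, center=True, min_periods=1).mean()
    grid = np.arange(np.ceil(series.t[0]), np.floor(series.t[-1]) + 1.0)
    out = {"t": grid}
    for col in ("vo2", "vco2", "hr"):
        out[col] = np.interp(grid, series.t, sm[col].to_numpy())
    idx = np.searchsorted(series.t, grid, side="right") - 1
    out["stage_speed"] = series.stage_speed[np.clip(idx, 0, len(series.t) - 1)]
    return pd.DataFrame(out)


def _final_window_means(series1hz: pd.DataFrame, window_s: float = 30.0) -> dict:
    """Final-``window_s`` VO2 mean for each stage with enough data."""
    means: dict[float, float] = {}
    for speed, g in series1hz.groupby("stage_speed", sort=True):
        if len(g) < window_s:
            continue
        t_end = g["t"].iloc[-1]
        w = g[g["t"] > t_end - window_s]
        means[float(speed)] = float(w["vo2"].mean())
    return means


def vo2max(
    series1hz: pd.DataFrame,
    age_years: float,
    plateau_range: float = 2.1,
    rer_threshold: float = 1.1,
    hr_frac: float = 0.9,
    hrmax_intercept: float = 220.0,
    hrmax_slope: float = 1.0,
    vvo2max_tol: float = 1.0,
) -> VO2maxResult:
    """VO2max, vVO2max and the acceptance criteria from a 1-Hz series.

    Predicted maximal HR defaults to 220 − age.  The plateau criterion is
    undefined (None) with fewer than two completed stages.
    """
    means = _final_window_means(series1hz)
    if not means:
        raise ValueError("no stage completed a final 30-s window")
    speeds = sorted(means)
    vmax = max(means.values())
    if len(speeds) >= 2:
        plateau = abs(means[speeds[-1]] - means[speeds[-2]]) < plateau_range
    else:
        plateau = None
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = series1hz["vco2"].to_numpy() / series1hz["vo2"].to_numpy()
    rer_flag = bool(np.nanmax(rer) > rer_threshold)
    hr_pred = hrmax_intercept - hrmax_slope * age_years
    hr_flag = bool(series1hz["hr"].max() > hr_frac * hr_pred)
    criteria = {"plateau": plateau, "rer": rer_flag, "hr": hr_flag}
    met = sum(1 for v in criteria.values() if v)
    vvo2 = next(s for s in speeds if means[s] >= vmax - vvo2max_tol)
    return VO2maxResult(
        vo2max=vmax, vvo2max=vvo2, criteria=criteria,
        met_count=met, accepted=met >= 2, stage_means=means,
    )


def lactate_summary(samples, scope: str = "half") -> PhysioSummary:
    """Peak (max) and mean blood lactate over the scope's period samples."""
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("no lactate samples in scope")
    return PhysioSummary(scope=scope, peak=float(arr.max()), mean=float(arr.mean()))


def hr_summary(hr_bpm, scope: str = "half") -> PhysioSummary:
    """Peak (max) and mean heart rate over the in-scope beats."""
    arr = np.asarray(list(hr_bpm), dtype=float)
    if arr.size == 0:
        raise ValueError("no heart-rate samples in scope")
    return PhysioSummary(scope=scope, peak=float(arr.max()), mean=float(arr.mean()))
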