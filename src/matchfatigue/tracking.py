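"""Time-motion analysis of 2-D player tracks.

Court coordinates from automatic video tracking (nominally 30 Hz) are
low-pass filtered with a zero-phase 3rd-order Butterworth at 0.4 Hz, and the
running-performance variables are computed per 10-min game period and
aggregated to halves and match: distance covered (DC, m), distance covered
per minute (DC_MIN, m·min⁻¹), number of sprints (S_N — excursions of speed
above the player's vVO2max, the lowest speed at which VO2max was reached)
and total sprint time (S_T, s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PlayerTrack",
    "RunningSummary",
    "SprintBout",
    "filter_track",
    "compute_speed",
    "distance_covered",
    "distance_per_minute",
    "detect_sprints",
    "summarize",
]

PERIODS = ("P1", "P2", "P3", "P4")
HALVES = {"H1": ("P1", "P2"), "H2": ("P3", "P4")}


@dataclass
class PlayerTrack:
    """2-D positions of one player over time, labelled by game period."""

    player_id: str
    t: np.ndarray          # s, strictly increasing
    x: np.ndarray          # m
    y: np.ndarray          # m
    period: np.ndarray     # per-sample labels, P1..P4

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.period = np.asarray(self.period)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.period)):
            raise ValueError("t, x, y, period must have equal length")
        if len(self.t) < 2:
            raise ValueError("track needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("missing coordinates are not allowed")

    def select(self, period_label: str) -> "PlayerTrack":
        m = self.period == period_label
        if m.sum() < 2:
            raise ValueError(f"period {period_label!r} has fewer than 2 samples")
        return PlayerTrack(self.player_id, self.t[m], self.x[m], self.y[m], self.period[m])

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"player_id": self.player_id, "t": self.t, "x": self.x,
             "y": self.y, "period": self.period}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PlayerTrack":
        pid = str(df["player_id"].iloc[0])
        return cls(pid, df["t"].to_numpy(), df["x"].to_numpy(),
                   df["y"].to_numpy(), df["period"].to_numpy())


@dataclass
class SprintBout:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RunningSummary:
    player_id: str
    scope: str                 # P1..P4 | H1 | H2 | match
    DC: float                  # m
    DC_MIN: float              # m per min
    S_N: int
    S_T: float                 # s
    bouts: list = field(default_factory=list)


def _uniform_grid(track: PlayerTrack, jitter_tol: float = 0.01) -> PlayerTrack:
    """Resample onto a uniform grid if timestamp jitter exceeds tolerance."""
    dt = np.diff(track.t)
    dt_med = np.median(dt)
    if np.max(np.abs(dt - dt_med)) <= jitter_tol * dt_med:
        return track
    tg = np.arange(track.t[0], track.t[-1] + dt_med / 2, dt_med)
    xg = np.interp(tg, track.t, track.x)
    yg = np.interp(tg, track.t, track.y)
    pg = np.full(tg.shape, track.period[0])
    return PlayerTrack(track.player_id, tg, xg, yg, pg)


def filter_track(track: PlayerTrack, order: int = 3, cutoff_hz: float = 0.4) -> PlayerTrack:
    """Zero-phase Butterworth low-pass of x and y (forward-backward).

    The filter is applied independently per period so that rest intervals
    never leak across period boundaries.  Reflective (odd) padding of at
    least three filter lengths handles the endpoints.
    """
    out_x = np.empty_like(track.x)
    out_y = np.empty_like(track.y)
    for p in np.unique(track.period):
        m = track.period == p
        sub = _uniform_grid(track.select(str(p)))
        fs = sub.sample_rate
        if cutoff_hz >= fs / 2:
            raise ValueError("cutoff must be below Nyquist")
        sos = signal.butter(order, cutoff_hz, fs=fs, output="sos")
        # transient length scales with fs/cutoff; pad 3 filter lengths
        padlen = int(3 * fs / cutoff_hz)
        if len(sub.t) <= padlen:
            raise ValueError("track segment shorter than filter padding")
        xf = signal.sosfiltfilt(sos, sub.x, padtype="odd", padlen=padlen)
        yf = signal.sosfiltfilt(sos, sub.y, padtype="odd", padlen=padlen)
        # map back to the original timestamps if a resample happened
        out_x[m] = np.interp(track.t[m], sub.t, xf)
        out_y[m] = np.interp(track.t[m], sub.t, yf)
    return PlayerTrack(track.player_id, track.t, out_x, out_y, track.period)


def compute_speed(track: PlayerTrack) -> np.ndarray:
    """Speed (m·s⁻¹) from central finite differences of the positions.

    One-sided differences at the segment ends; computed per period.
    """
    if len(track.t) < 2:
        raise ValueError("need at least 2 samples")
    speed = np.empty_like(track.x)
    for p in np.unique(track.period):
        m = track.period == p
        t, x, y = track.t[m], track.x[m], track.y[m]
        vx = np.gradient(x, t)
        vy = np.gradient(y, t)
        speed[m] = np.hypot(vx, vy)
    return speed


def distance_covered(track: PlayerTrack, window: tuple[float, float] | None = None) -> float:
    """Path length (m): sum of Euclidean steps inside the half-open window."""
    if window is None:
        m = np.ones(len(track.t), dtype=bool)
    else:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("empty window")
        m = (track.t >= t0) & (track.t < t1)
    if m.sum() < 2:
        return 0.0
    dx = np.diff(track.x[m])
    dy = np.diff(track.y[m])
    return float(np.sum(np.hypot(dx, dy)))


def distance_per_minute(dc_m: float, effective_minutes: float) -> float:
    if effective_minutes <= 0:
        raise ValueError("effective minutes must be positive")
    return dc_m / effective_minutes


def detect_sprints(
    t: np.ndarray,
    speed: np.ndarray,
    threshold: float,
    min_duration_s: float = 0.0,
) -> list[SprintBout]:
    """Maximal contiguous runs of samples with speed strictly above threshold.

    Bout duration is the sample count times the sampling interval, so an
    isolated single sample above threshold still contributes one sample's
    worth of time.  Bouts shorter than ``min_duration_s`` are dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold
    if not above.any():
        return []
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    flags = above.astype(np.int8)
    starts = np.flatnonzero(np.diff(np.r_[0, flags]) == 1)
    ends = np.flatnonzero(np.diff(np.r_[flags, 0]) == -1)
    bouts = []
    for i0, i1 in zip(starts, ends):
        dur = (i1 - i0 + 1) * dt
        if dur >= min_duration_s and dur > 0:
            bouts.append(SprintBout(start_s=float(t[i0]), end_s=float(t[i0]) + dur))
    return bouts


def _scope_summary(
    track_f: PlayerTrack,
    scope: str,
    labels: tuple[str, ...],
    threshold: float,
    scheduled_minutes: float | None,
    min_sprint_s: float,
) -> RunningSummary:
    dc = 0.0
    minutes = 0.0
    bouts: list[SprintBout] = []
    for p in labels:
        m = track_f.period == p
        if not m.any():
            raise ValueError(f"missing period label {p}")
        sub = track_f.select(p)
        dc += distance_covered(sub)
        sp = compute_speed(sub)
        bouts.extend(detect_sprints(sub.t, sp, threshold, min_sprint_s))
        if scheduled_minutes is None:
            minutes += (sub.t[-1] - sub.t[0]) / 60.0
        else:
            minutes += scheduled_minutes
    s_t = sum(b.duration_s for b in bouts)
    return RunningSummary(
        player_id=track_f.player_id, scope=scope, DC=dc,
        DC_MIN=distance_per_minute(dc, minutes), S_N=len(bouts), S_T=s_t,
        bouts=bouts,
    )


def summarize(
    track: PlayerTrack,
    vvo2max_ms: float,
    scheduled_period_minutes: float | None = 10.0,
    min_sprint_s: float = 0.0,
    prefiltered: bool = False,
) -> list[RunningSummary]:
    """Per-period, per-half and match running summaries.

    ``scheduled_period_minutes`` sets the DC_MIN denominator per period
    (the game's nominal 10-min periods); pass ``None`` to use the analyzed
    effective time span of each period instead.
    """
    tf = track if prefiltered else filter_track(track)
    present = [p for p in PERIODS if (tf.period == p).any()]
    if not present:
        raise ValueError("no recognised period labels present")
    out = [
        _scope_summary(tf, p, (p,), vvo2max_ms, scheduled_period_minutes, min_sprint_s)
        for p in present
    ]
    for half, plabels in HALVES.items():
        labels = tuple(p for p in plabels if p in present)
        if labels:
            out.append(_scope_summary(tf, half, labels, vvo2max_ms,
                                      scheduled_period_minutes, min_sprint_s))
    out.append(_scope_summary(tf, "match", tuple(present), vvo2max_ms,
                              scheduled_period_minutes, min_sprint_s))
    return out
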