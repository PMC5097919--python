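"""Synthetic match-fatigue signals with known ground truth.

Every raw input the pipeline consumes can be generated here with the truth
recorded alongside, so each estimator has a closed-loop parameter-recovery
test:

* player tracks — piecewise-constant-speed locomotion bouts along a smoothly
  turning heading, with a configurable 2nd-half speed decrement and Gaussian
  positional digitization noise;
* ball kicks — drag-free projectile flight (z quadratic under gravity, x
  and y linear) sampled at 240 Hz with digitization noise;
* MVC force traces — ramp/plateau voluntary force plus doublet twitches
  modelled as a peak-normalized difference of exponentials; the
  superimposed twitch is constructed as TC × (1 − VA/100) so the true
  voluntary activation is recoverable exactly;
* EMG — band-limited Gaussian noise scaled to a target RMS plus one
  biphasic M-wave at a marked time;
* breath-by-breath gas exchange — staged incremental-test series with a
  controllable terminal plateau;
* paired cohorts — before/after tables with configured true mean change and
  SD of changes, for end-to-end statistics tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .kicks import BallTrajectory
from .neuro import EMGTrace, ForceTrace
from .physio import BreathSeries
from .tracking import PlayerTrack

__all__ = [
    "Bout",
    "TrackSimConfig",
    "KickSimConfig",
    "MvcSimConfig",
    "EmgSimConfig",
    "BreathSimConfig",
    "TrackTruth",
    "KickTruth",
    "MvcTruth",
    "EmgTruth",
    "BreathTruth",
    "gen_player_track",
    "gen_kick",
    "gen_mvc_trace",
    "gen_emg_trace",
    "gen_breath_series",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# player tracks

@dataclass
class Bout:
    """One locomotion state: speed (m/s), duration (s), selection weight."""

    speed: float
    duration: float
    weight: float = 1.0


def default_bouts() -> list[Bout]:
    """Futsal-like intermittent locomotion mix.

    Weights are tuned to a mean speed near 103 m/min and roughly one sprint
    every ~24 s of play (about 50 sprints per 20-min half), the scale of
    elite simulated-game time-motion data.
    """
    return [
        Bout(0.3, 4.0, 0.22),   # standing / shuffling
        Bout(0.8, 4.0, 0.25),   # walking
        Bout(1.8, 5.0, 0.23),   # jogging
        Bout(3.0, 4.0, 0.13),   # running
        Bout(5.0, 2.5, 0.17),   # sprinting
    ]


@dataclass
class TrackSimConfig:
    duration_s: float = 2400.0           # total play: 4 x 10-min periods
    sample_rate: float = 30.0
    bout_speeds: list = field(default_factory=default_bouts)
    transition_scheme: str = "markov"    # "markov" | "cycle"
    half2_decrement: float = 0.066       # fraction removed from 2nd-half speeds
    noise_sd: float = 0.05               # m positional jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration_s and sample_rate must be positive")
        if not (0.0 <= self.half2_decrement < 1.0):
            raise ValueError("half2_decrement must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.bout_speeds:
            raise ValueError("bout_speeds must be non-empty")


@dataclass
class TrackTruth:
    distance_m: float
    distance_by_period: dict
    speed: np.ndarray                    # true per-sample speed, m/s
    sprint_intervals: dict = field(default_factory=dict)

    def sprints_above(self, threshold: float, t: np.ndarray) -> list:
        """Contiguous intervals where the true speed exceeds threshold."""
        above = self.speed > threshold
        flags = above.astype(np.int8)
        starts = np.flatnonzero(np.diff(np.r_[0, flags]) == 1)
        ends = np.flatnonzero(np.diff(np.r_[flags, 0]) == -1)
        return [(float(t[i0]), float(t[i1])) for i0, i1 in zip(starts, ends)]


def _speed_schedule(cfg: TrackSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sample true speed from the bout schedule, with 2nd-half decrement."""
    n = int(round(cfg.duration_s * cfg.sample_rate))
    dt = 1.0 / cfg.sample_rate
    speeds = np.empty(n)
    weights = np.array([b.weight for b in cfg.bout_speeds], dtype=float)
    weights /= weights.sum()
    i = 0
    k = 0
    while i < n:
        if cfg.transition_scheme == "markov":
            b = cfg.bout_speeds[rng.choice(len(cfg.bout_speeds), p=weights)]
        elif cfg.transition_scheme == "cycle":
            b = cfg.bout_speeds[k % len(cfg.bout_speeds)]
            k += 1
        else:
            raise ValueError(f"unknown transition_scheme {cfg.transition_scheme!r}")
        m = max(1, int(round(b.duration / dt)))
        speeds[i:i + m] = b.speed
        i += m
    half2 = np.arange(n) >= n // 2
    speeds[half2] *= 1.0 - cfg.half2_decrement
    return speeds


def gen_player_track(
    cfg: TrackSimConfig, player_id: str = "p1"
) -> tuple[PlayerTrack, TrackTruth]:
    """Simulate one player's noisy 2-D track plus its ground truth.

    The heading turns smoothly (two slow sinusoids, ≤ 0.05 Hz) so the true
    path has no spectral content above the tracking filter's pass band; the
    true path length is exactly the integral of the scheduled speed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate))
    dt = 1.0 / cfg.sample_rate
    t = np.arange(n) * dt
    speed = _speed_schedule(cfg, rng)
    theta = (
        rng.uniform(0, 2 * math.pi)
        + 2.2 * np.sin(2 * math.pi * 0.031 * t + rng.uniform(0, 2 * math.pi))
        + 1.4 * np.sin(2 * math.pi * 0.013 * t + rng.uniform(0, 2 * math.pi))
    )
    step = speed * dt
    x = np.concatenate([[0.0], np.cumsum(step[:-1] * np.cos(theta[:-1]))]) + 20.0
    y = np.concatenate([[0.0], np.cumsum(step[:-1] * np.sin(theta[:-1]))]) + 10.0
    xn = x + rng.normal(0, cfg.noise_sd, n)
    yn = y + rng.normal(0, cfg.noise_sd, n)
    q = n // 4
    period = np.empty(n, dtype=object)
    for i, lab in enumerate(("P1", "P2", "P3", "P4")):
        period[i * q: (i + 1) * q if i < 3 else n] = lab
    track = PlayerTrack(player_id, t, xn, yn, period)
    dist_steps = step.copy()
    dist_steps[-1] = 0.0  # last sample opens no step
    by_period = {
        lab: float(np.sum(dist_steps[period == lab])) for lab in ("P1", "P2", "P3", "P4")
    }
    truth = TrackTruth(
        distance_m=float(np.sum(dist_steps)),
        distance_by_period=by_period,
        speed=speed,
    )
    return track, truth


# ---------------------------------------------------------------------------
# ball kicks

@dataclass
class KickSimConfig:
    v0: tuple[float, float, float] = (2.0, 28.0, 3.0)   # m/s (x, y, z)
    p0: tuple[float, float, float] = (0.0, 0.0, 0.11)   # m (ball on floor)
    sample_rate: float = 240.0
    n_frames: int = 12                                  # >= 10 airborne frames
    noise_sd: float = 0.002                             # m digitization noise
    gravity: float = 9.81
    goal_plane_y: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.sample_rate <= 0 or self.gravity <= 0:
            raise ValueError("sample_rate and gravity must be positive")


@dataclass
class KickTruth:
    speed_ms: float
    speed_kmh: float
    v0: tuple[float, float, float]
    crossing: tuple[float, float]        # (x, z) at the goal plane, noise-free
    t_crossing: float


def gen_kick(cfg: KickSimConfig, kick_id: str = "k1") -> tuple[BallTrajectory, KickTruth]:
    """Drag-free projectile flight sampled after a contact frame.

    Frame 0 is the contact frame (the release position); the following
    ``n_frames`` frames are airborne.  i.i.d. Gaussian noise is added per
    coordinate.  The goal-plane crossing is computed analytically from the
    noise-free flight.
    """
    rng = np.random.default_rng(cfg.seed)
    vx, vy, vz = cfg.v0
    px, py, pz = cfg.p0
    g = cfg.gravity
    t = np.arange(cfg.n_frames + 1) / cfg.sample_rate
    x = px + vx * t
    y = py + vy * t
    z = pz + vz * t - 0.5 * g * t ** 2
    xn = x + rng.normal(0, cfg.noise_sd, len(t))
    yn = y + rng.normal(0, cfg.noise_sd, len(t))
    zn = z + rng.normal(0, cfg.noise_sd, len(t))
    traj = BallTrajectory(kick_id, t, xn, yn, zn, contact_index=0)
    speed = math.sqrt(vx * vx + vy * vy + vz * vz)
    if vy > 0:
        t_star = (cfg.goal_plane_y - py) / vy
        crossing = (px + vx * t_star, pz + vz * t_star - 0.5 * g * t_star ** 2)
    else:
        t_star = math.nan
        crossing = (math.nan, math.nan)
    truth = KickTruth(
        speed_ms=speed, speed_kmh=3.6 * speed, v0=cfg.v0,
        crossing=crossing, t_crossing=t_star,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# MVC force traces

@dataclass
class MvcSimConfig:
    mvc_force: float = 840.2            # N, true plateau level
    va_true: float = 85.9               # percent, (0, 100]
    tc_amp: float = 288.6               # N, control-doublet amplitude
    twitch_tau_rise: float = 0.015      # s
    twitch_tau_decay: float = 0.08      # s
    ramp_s: float = 1.0
    stim_relaxed_t: float = 2.0         # voluntary force is zero here
    stim_super_t: float = 7.0           # 3 s into the 5-s MVC (2-3 s window)
    mvc_start_t: float = 4.0
    mvc_hold_s: float = 5.0
    duration_s: float = 12.0
    noise_sd: float = 2.0               # N
    sample_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.va_true <= 100.0):
            raise ValueError("va_true must be in (0, 100]")
        if not (0 <= self.stim_relaxed_t <= self.duration_s
                and 0 <= self.stim_super_t <= self.duration_s):
            raise ValueError("stimulation times must lie inside the trace")
        if self.stim_relaxed_t >= self.mvc_start_t:
            raise ValueError("relaxed doublet must precede the MVC")


@dataclass
class MvcTruth:
    F_PEAK: float
    TC: float
    TS: float
    VA: float
    force_at_stim: float


def _twitch(t_rel: np.ndarray, amp: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials twitch, peak-normalized to ``amp``."""
    t_peak = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    w = np.where(
        t_rel >= 0,
        np.exp(-np.maximum(t_rel, 0) / tau_decay) - np.exp(-np.maximum(t_rel, 0) / tau_rise),
        0.0,
    )
    return amp * w / peak


def gen_mvc_trace(cfg: MvcSimConfig) -> tuple[ForceTrace, MvcTruth]:
    """MVC force trace with relaxed and superimposed doublets.

    Voluntary force ramps (half-cosine) to the plateau, holds, and releases.
    The superimposed twitch amplitude is TC × (1 − VA_true/100) scaled by
    F_PEAK / F_stim when the stimulus lands off the plateau, so the VA
    estimator's formula (uncorrected or corrected) inverts the construction
    exactly.
    """
    n = int(round(cfg.duration_s * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    end_hold = cfg.mvc_start_t + cfg.ramp_s + cfg.mvc_hold_s
    vol = np.zeros(n)
    ramp_up = (t >= cfg.mvc_start_t) & (t < cfg.mvc_start_t + cfg.ramp_s)
    vol[ramp_up] = 0.5 * (1 - np.cos(math.pi * (t[ramp_up] - cfg.mvc_start_t) / cfg.ramp_s))
    vol[(t >= cfg.mvc_start_t + cfg.ramp_s) & (t < end_hold)] = 1.0
    ramp_dn = (t >= end_hold) & (t < end_hold + cfg.ramp_s)
    vol[ramp_dn] = 0.5 * (1 + np.cos(math.pi * (t[ramp_dn] - end_hold) / cfg.ramp_s))
    force = cfg.mvc_force * vol

    f_stim = float(cfg.mvc_force * vol[np.searchsorted(t, cfg.stim_super_t)])
    ts_base = cfg.tc_amp * (1.0 - cfg.va_true / 100.0)
    if f_stim >= 0.999 * cfg.mvc_force or f_stim == 0.0:
        ts_amp = ts_base
    else:
        ts_amp = ts_base * cfg.mvc_force / f_stim   # corrected-formula inverse
    force += _twitch(t - cfg.stim_relaxed_t, cfg.tc_amp,
                     cfg.twitch_tau_rise, cfg.twitch_tau_decay)
    force += _twitch(t - cfg.stim_super_t, ts_amp,
                     cfg.twitch_tau_rise, cfg.twitch_tau_decay)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        force = force + rng.normal(0, cfg.noise_sd, n)
    trace = ForceTrace(
        t, force,
        stim_markers=[(cfg.stim_relaxed_t, "relaxed"), (cfg.stim_super_t, "superimposed")],
    )
    truth = MvcTruth(F_PEAK=cfg.mvc_force, TC=cfg.tc_amp, TS=ts_amp,
                     VA=cfg.va_true, force_at_stim=f_stim)
    return trace, truth


# ---------------------------------------------------------------------------
# EMG

@dataclass
class EmgSimConfig:
    rms_true: float = 0.53              # mV over the active (contraction) window
    band: tuple[float, float] = (20.0, 500.0)
    mwave_amp: float = 3.75             # mV peak-to-peak
    mwave_period_ms: float = 12.0       # dominant period of the biphasic wave
    mwave_t: float = 2.0                # s, relaxed-stimulus time
    baseline_rms: float = 0.02          # mV resting-muscle noise floor
    active_window: tuple[float, float] = (4.0, 10.0)   # voluntary contraction
    sample_rate: float = 2000.0
    duration_s: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rms_true <= 0:
            raise ValueError("rms_true must be positive")
        lo, hi = self.band
        if not (0 < lo < hi < self.sample_rate / 2):
            raise ValueError("band must lie within (0, Nyquist)")


@dataclass
class EmgTruth:
    RMS: float
    MWave: float
    mwave_t: float


def _biphasic_mwave(fs: float, amp_pp: float, period_ms: float) -> np.ndarray:
    """One Hann-windowed sine cycle, rescaled to an exact peak-to-peak."""
    n = max(8, int(round(period_ms * 1e-3 * fs)))
    u = np.arange(n) / n
    w = np.sin(2 * math.pi * u) * np.hanning(n)
    return amp_pp * w / (w.max() - w.min())


def gen_emg_trace(cfg: EmgSimConfig) -> tuple[EMGTrace, EmgTruth]:
    """Surface-EMG trace: band-limited noise plus one evoked M-wave.

    Voluntary EMG (RMS = ``rms_true``) fills the active window; elsewhere
    only the resting noise floor is present, as in a relaxed muscle.  The
    noise is white Gaussian band-passed to ``band`` and empirically rescaled
    so the active-window RMS equals ``rms_true`` exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    sos = signal.butter(4, cfg.band, btype="bandpass", fs=cfg.sample_rate, output="sos")
    noise = signal.sosfiltfilt(sos, rng.standard_normal(n))
    active = (t >= cfg.active_window[0]) & (t < cfg.active_window[1])
    sig = np.zeros(n)
    if active.any():
        sig[active] = noise[active] * (cfg.rms_true / np.sqrt(np.mean(noise[active] ** 2)))
    rest = ~active
    if rest.any() and cfg.baseline_rms > 0:
        base = signal.sosfiltfilt(sos, rng.standard_normal(n))
        sig[rest] = base[rest] * (cfg.baseline_rms / np.sqrt(np.mean(base[rest] ** 2)))
    wave = _biphasic_mwave(cfg.sample_rate, cfg.mwave_amp, cfg.mwave_period_ms)
    i0 = int(round(cfg.mwave_t * cfg.sample_rate))
    sig[i0:i0 + len(wave)] += wave[: max(0, n - i0)]
    trace = EMGTrace(t, sig, mwave_marker=cfg.mwave_t)
    return trace, EmgTruth(RMS=cfg.rms_true, MWave=cfg.mwave_amp, mwave_t=cfg.mwave_t)


# ---------------------------------------------------------------------------
# breath-by-breath series

@dataclass
class BreathSimConfig:
    vo2_per_stage: tuple = (35.0, 38.5, 42.0, 45.5, 49.0, 50.6, 50.6)
    stage_start_kmh: float = 10.0
    stage_step_kmh: float = 1.0
    stage_s: float = 180.0
    vo2_tau_s: float = 20.0             # first-order on-kinetics per stage
    rer_start: float = 0.85
    rer_end: float = 1.15
    hr_start: float = 120.0
    hr_end: float = 195.0
    breath_interval_s: float = 2.0
    noise_sd: float = 1.0               # mL/kg/min per breath
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.vo2_per_stage) == 0:
            raise ValueError("vo2_per_stage must be non-empty")
        if self.stage_s <= 0 or self.breath_interval_s <= 0:
            raise ValueError("stage_s and breath_interval_s must be positive")

    @property
    def stage_speeds(self) -> np.ndarray:
        return self.stage_start_kmh + self.stage_step_kmh * np.arange(len(self.vo2_per_stage))


@dataclass
class BreathTruth:
    vo2max: float
    vvo2max: float


def gen_breath_series(cfg: BreathSimConfig) -> tuple[BreathSeries, BreathTruth]:
    """Incremental-test breath series with a controllable terminal plateau.

    Breaths arrive at gamma-distributed intervals; VO2 follows each stage's
    target level with first-order kinetics plus Gaussian noise; RER and HR
    ramp linearly across the test.  True VO2max is the highest stage level;
    true vVO2max the speed of the earliest stage whose level is within
    1 mL·kg⁻¹·min⁻¹ of it.
    """
    rng = np.random.default_rng(cfg.seed)
    levels = np.asarray(cfg.vo2_per_stage, dtype=float)
    speeds = cfg.stage_speeds
    total = cfg.stage_s * len(levels)
    mean_iv = cfg.breath_interval_s
    n_est = int(total / mean_iv * 1.5) + 10
    intervals = rng.gamma(shape=4.0, scale=mean_iv / 4.0, size=n_est)
    t = np.cumsum(intervals)
    t = t[t < total]
    stage_idx = np.minimum((t // cfg.stage_s).astype(int), len(levels) - 1)
    target = levels[stage_idx]
    t_in_stage = t - stage_idx * cfg.stage_s
    prev = np.where(stage_idx > 0, levels[np.maximum(stage_idx - 1, 0)], levels[0] * 0.6)
    vo2 = target + (prev - target) * np.exp(-t_in_stage / cfg.vo2_tau_s)
    if cfg.noise_sd > 0:
        vo2 = vo2 + rng.normal(0, cfg.noise_sd, len(t))
    frac = t / total
    rer = cfg.rer_start + (cfg.rer_end - cfg.rer_start) * frac
    hr = cfg.hr_start + (cfg.hr_end - cfg.hr_start) * frac
    hr = hr + rng.normal(0, 1.0, len(t))
    vco2 = rer * vo2
    series = BreathSeries(t=t, vo2=vo2, vco2=vco2, hr=hr,
                          stage_speed=speeds[stage_idx].astype(float))
    vmax = float(levels.max())
    vvo2 = float(speeds[np.argmax(levels >= vmax - 1.0)])
    return series, BreathTruth(vo2max=vmax, vvo2max=vvo2)


# ---------------------------------------------------------------------------
# paired cohorts

def gen_cohort(n_players: int, effect_config: dict, seed: int = 0) -> pd.DataFrame:
    """Paired before/after table with configured true changes.

    ``effect_config`` maps variable name to a dict (or 4-tuple) with keys
    before_mean, before_sd, delta_mean, delta_sd; ``after`` is drawn as
    ``before + N(delta_mean, delta_sd)`` per subject.
    """
    if n_players < 2:
        raise ValueError("n_players must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for var, params in effect_config.items():
        if isinstance(params, dict):
            bm, bs = params["before_mean"], params["before_sd"]
            dm, ds = params["delta_mean"], params["delta_sd"]
        else:
            bm, bs, dm, ds = params
        before = rng.normal(bm, bs, n_players)
        delta = rng.normal(dm, ds, n_players) if ds > 0 else np.full(n_players, dm)
        for i in range(n_players):
            rows.append(
                {"subject": f"s{i + 1}", "variable": var,
                 "before": before[i], "after": before[i] + delta[i]}
            )
    return pd.DataFrame(rows)
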