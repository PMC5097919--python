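"""Neuromuscular assessment: MVC force, twitch interpolation and EMG.

Force traces (1000 Hz) from maximal voluntary knee-extension contractions
are low-pass filtered (zero-phase 4th-order Butterworth, 15 Hz).  The MVC
peak force F_PEAK is the highest 100-ms moving average of the plateau, with
windows overlapping the superimposed-stimulation artifact masked out.  The
control twitch TC is the amplitude of the doublet evoked on the relaxed
muscle; the superimposed twitch TS the force increment evoked during the
MVC.  Voluntary activation:

    VA = [1 − TS/TC] × 100

with, when the stimulus landed off the force plateau, the correction

    VA = [1 − TS·(F_stim/F_PEAK)/TC] × 100.

EMG (2000 Hz) is band-passed 20–500 Hz; RMS is taken over the 1-s force
plateau, the M-wave as the peak-to-peak amplitude evoked by the relaxed
supramaximal stimulus, and RMS/MW is their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "ForceTrace",
    "TwitchResult",
    "EMGTrace",
    "EMGResult",
    "filter_force",
    "detect_plateau",
    "twitch_amplitude",
    "voluntary_activation",
    "bandpass_emg",
    "rms_over_plateau",
    "mwave_amplitude",
    "analyze_force_trace",
    "analyze_emg",
    "combine_mvcs",
]


@dataclass
class ForceTrace:
    t: np.ndarray                      # s, 1000 Hz nominal
    force: np.ndarray                  # N
    stim_markers: list                 # [(time_s, "relaxed"|"superimposed"), ...]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.t) != len(self.force):
            raise ValueError("t and force must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.isfinite(self.force).all():
            raise ValueError("force must be finite")
        for ts, ctx in self.stim_markers:
            if not (self.t[0] <= ts <= self.t[-1]):
                raise ValueError(f"stim time {ts} outside trace")
            if ctx not in ("relaxed", "superimposed"):
                raise ValueError(f"unknown stim context {ctx!r}")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class TwitchResult:
    F_PEAK: float
    TC: float
    TS: float
    VA: float
    force_at_stim: float
    corrected: bool
    flags: list = field(default_factory=list)


@dataclass
class EMGTrace:
    t: np.ndarray                      # s, 2000 Hz nominal
    signal: np.ndarray                 # mV
    mwave_marker: float | None = None  # relaxed-stimulus time, s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class EMGResult:
    RMS: float
    MWave: float | None
    RMS_MW: float | None
    flags: list = field(default_factory=list)


def filter_force(trace: ForceTrace, order: int = 4, cutoff_hz: float = 15.0) -> ForceTrace:
    """Zero-phase Butterworth low-pass of the force signal."""
    fs = trace.sample_rate
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff_hz, fs=fs, output="sos")
    padlen = int(3 * fs / cutoff_hz)
    if len(trace.force) <= padlen:
        raise ValueError("trace too short to filter")
    f = signal.sosfiltfilt(sos, trace.force, padtype="odd", padlen=padlen)
    return ForceTrace(trace.t, f, trace.stim_markers)


def detect_plateau(
    trace: ForceTrace, window_ms: float = 100.0, artifact_ms: float = 300.0
) -> tuple[tuple[float, float], float]:
    """Locate the MVC force plateau and compute F_PEAK.

    F_PEAK is the maximum over the trace of the ``window_ms`` moving average,
    considering only windows free of superimposed-stimulation artifact
    (stim time to stim time + ``artifact_ms`` masked).  Returns the
    ((start_s, end_s), F_PEAK) of the winning window.
    """
    fs = trace.sample_rate
    w = max(1, int(round(window_ms * 1e-3 * fs)))
    n = len(trace.force)
    if n < w:
        raise ValueError("trace shorter than the averaging window")
    masked = np.zeros(n, dtype=bool)
    for ts, ctx in trace.stim_markers:
        if ctx == "superimposed":
            masked |= (trace.t >= ts) & (trace.t < ts + artifact_ms * 1e-3)
    kernel = np.ones(w)
    means = np.convolve(trace.force, kernel / w, mode="valid")
    bad = np.convolve(masked.astype(float), kernel, mode="valid") > 0
    if bad.all():
        raise ValueError("no artifact-free window of the requested length")
    means = np.where(bad, -np.inf, means)
    i = int(np.argmax(means))
    return (float(trace.t[i]), float(trace.t[i + w - 1])), float(means[i])


def twitch_amplitude(
    trace: ForceTrace,
    stim: tuple[float, str],
    artifact_ms: float = 300.0,
    baseline_ms: float = 50.0,
) -> tuple[float, float]:
    """Evoked-doublet force amplitude and the pre-stimulus force level.

    Amplitude = peak force in (stim, stim + artifact_ms] minus the mean over
    the ``baseline_ms`` immediately before the stimulus.  The same rule
    serves the relaxed doublet (baseline ≈ 0) and the superimposed doublet
    (baseline = voluntary force at stimulation).  Returns (amplitude,
    baseline).
    """
    ts, _ctx = stim
    t = trace.t
    pre = (t >= ts - baseline_ms * 1e-3) & (t < ts)
    post = (t > ts) & (t <= ts + artifact_ms * 1e-3)
    if not pre.any() or not post.any():
        raise ValueError("stimulation window exceeds trace extent")
    baseline = float(np.mean(trace.force[pre]))
    peak = float(np.max(trace.force[post]))
    return max(peak - baseline, 0.0), baseline


def voluntary_activation(
    TS: float,
    TC: float,
    force_at_stim: float | None = None,
    F_PEAK: float | None = None,
    on_plateau: bool = True,
) -> tuple[float, bool, list]:
    """Voluntary activation (%) by twitch interpolation.

    On-plateau: VA = [1 − TS/TC] × 100.  Off-plateau, TS is scaled by the
    ratio of the force at stimulation to F_PEAK before the same formula is
    applied.  Values outside [0, 100] are flagged, not clamped.  Returns
    (VA, corrected, flags).
    """
    if TC <= 0:
        raise ValueError("TC must be positive")
    if on_plateau:
        va = (1.0 - TS / TC) * 100.0
        corrected = False
    else:
        if F_PEAK is None or F_PEAK <= 0 or force_at_stim is None:
            raise ValueError("corrected VA needs force_at_stim and positive F_PEAK")
        va = (1.0 - (TS * (force_at_stim / F_PEAK)) / TC) * 100.0
        corrected = True
    flags = [] if 0.0 <= va <= 100.0 else ["va_out_of_range"]
    return float(va), corrected, flags


def bandpass_emg(
    trace: EMGTrace, band: tuple[float, float] = (20.0, 500.0), order: int = 4
) -> EMGTrace:
    """Zero-phase Butterworth band-pass of the EMG signal."""
    fs = trace.sample_rate
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError("band must lie strictly within (0, Nyquist)")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    padlen = int(3 * fs / lo)
    if len(trace.signal) <= padlen:
        raise ValueError("trace too short to filter")
    s = signal.sosfiltfilt(sos, trace.signal, padtype="odd", padlen=padlen)
    return EMGTrace(trace.t, s, trace.mwave_marker)


def rms_over_plateau(
    emg: EMGTrace, plateau_window: tuple[float, float], span_s: float = 1.0
) -> float:
    """RMS (mV) over a ``span_s`` window centred on the force plateau."""
    centre = 0.5 * (plateau_window[0] + plateau_window[1])
    m = (emg.t >= centre - span_s / 2) & (emg.t < centre + span_s / 2)
    if not m.any():
        raise ValueError("plateau window unavailable in the EMG timebase")
    return float(np.sqrt(np.mean(emg.signal[m] ** 2)))


def mwave_amplitude(
    emg: EMGTrace, marker: float | None = None, search_ms: float = 50.0,
    noise_ratio_min: float = 3.0,
) -> tuple[float, list]:
    """Peak-to-peak M-wave amplitude (mV) after the relaxed stimulus.

    Searches (marker, marker + search_ms].  The amplitude is flagged
    "unreliable" when it is under ``noise_ratio_min`` times the peak-to-peak
    excursion of the background signal in an equal-length window just before
    the stimulus (peak-to-peak, not SD, because the measurement itself is a
    range statistic).
    """
    marker = emg.mwave_marker if marker is None else marker
    if marker is None:
        raise ValueError("no M-wave stimulation marker")
    m = (emg.t > marker) & (emg.t <= marker + search_ms * 1e-3)
    if not m.any():
        raise ValueError("M-wave search window outside trace")
    amp = float(np.max(emg.signal[m]) - np.min(emg.signal[m]))
    pre = (emg.t >= marker - search_ms * 1e-3) & (emg.t < marker)
    flags = []
    if pre.any():
        noise_pp = float(np.max(emg.signal[pre]) - np.min(emg.signal[pre]))
        if amp < noise_ratio_min * noise_pp:
            flags.append("unreliable")
    return amp, flags


def analyze_force_trace(
    trace: ForceTrace,
    artifact_ms: float = 300.0,
    plateau_frac: float = 0.95,
    prefiltered: bool = False,
) -> TwitchResult:
    """Full twitch-interpolation analysis of one MVC trace.

    The stimulus counts as "on plateau" when the voluntary force at
    stimulation is at least ``plateau_frac`` × F_PEAK; otherwise the
    corrected VA formula is applied.
    """
    ft = trace if prefiltered else filter_force(trace)
    window, f_peak = detect_plateau(ft, artifact_ms=artifact_ms)
    relaxed = [s for s in ft.stim_markers if s[1] == "relaxed"]
    superimposed = [s for s in ft.stim_markers if s[1] == "superimposed"]
    if not relaxed or not superimposed:
        raise ValueError("need one relaxed and one superimposed stimulation")
    tc, _ = twitch_amplitude(ft, relaxed[0], artifact_ms)
    ts_amp, f_stim = twitch_amplitude(ft, superimposed[0], artifact_ms)
    on_plateau = f_stim >= plateau_frac * f_peak
    va, corrected, flags = voluntary_activation(
        ts_amp, tc, force_at_stim=f_stim, F_PEAK=f_peak, on_plateau=on_plateau
    )
    return TwitchResult(
        F_PEAK=f_peak, TC=tc, TS=ts_amp, VA=va,
        force_at_stim=f_stim, corrected=corrected, flags=flags,
    )


def analyze_emg(
    emg: EMGTrace,
    plateau_window: tuple[float, float],
    band: tuple[float, float] = (20.0, 500.0),
    prefiltered: bool = False,
) -> EMGResult:
    """RMS over the 1-s plateau, M-wave peak-to-peak and their ratio."""
    ef = emg if prefiltered else bandpass_emg(emg, band)
    rms = rms_over_plateau(ef, plateau_window)
    if ef.mwave_marker is None:
        return EMGResult(RMS=rms, MWave=None, RMS_MW=None, flags=["no_mwave_marker"])
    mw, flags = mwave_amplitude(ef)
    ratio = rms / mw if mw > 0 else None
    if mw <= 0:
        flags = flags + ["mwave_nonpositive"]
    return EMGResult(RMS=rms, MWave=mw, RMS_MW=ratio, flags=flags)


def combine_mvcs(results: list[TwitchResult], rule: str = "best") -> TwitchResult:
    """Reduce the session's MVC attempts to one result.

    "best" keeps the attempt with the higher F_PEAK (default); "mean"
    averages the numeric fields.
    """
    if not results:
        raise ValueError("no MVC results")
    if rule == "best":
        return max(results, key=lambda r: r.F_PEAK)
    if rule == "mean":
        fields = ("F_PEAK", "TC", "TS", "VA", "force_at_stim")
        means = {f: float(np.mean([getattr(r, f) for r in results])) for f in fields}
        return TwitchResult(
            corrected=any(r.corrected for r in results),
            flags=sorted({f for r in results for f in r.flags}),
            **means,
        )
    raise ValueError(f"unknown rule {rule!r}")
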