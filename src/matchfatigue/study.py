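"""End-to-end replica of the simulated-game fatigue study.

``run_study`` wires the synthetic generators through every processing
module in protocol order — incremental test, simulated game (4 × 10-min
periods) with time-motion tracking, three sets of finishing kicks, and
before/after neuromuscular assessment — then applies the statistics layer:
paired comparisons between halves and testing moments, one-way ANOVA
across kick sets, and Pearson correlations between the change scores
(Δ running vs Δ neuromuscular), with a latent per-player fatigue factor
coupling the second-half running decrement to the force loss so that the
planted correlation is recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kicks as km
from . import neuro as nm
from . import physio as pm
from . import stats as st
from . import synthgame as sg
from . import tracking as tm

__all__ = ["StudyConfig", "StudyReport", "run_study"]


@dataclass
class StudyConfig:
    n_players: int = 10
    n_neuro: int = 6                    # subset with twitch interpolation
    seed: int = 0
    play_duration_s: float = 2400.0     # 4 x 10-min periods
    scheduled_period_minutes: float = 10.0
    half2_decrement: float = 0.066      # mean 2nd-half speed decrement
    fatigue_sd: float = 0.35            # spread of the latent fatigue factor
    kick_set_speeds_kmh: tuple = (109.3, 113.1, 110.2)
    kicks_per_set: int = 3
    age_years: float = 22.0
    # before-moment population means/SDs and fatigue-coupled mean changes
    neuro_population: dict = field(default_factory=lambda: {
        "F_PEAK": (840.2, 66.2, -88.6, 30.0),
        "TC": (288.6, 45.5, -40.6, 25.0),
        "VA": (85.9, 5.0, -11.9, 4.0),
        "RMS": (0.53, 0.14, -0.04, 0.08),
        "MWave": (3.75, 1.0, 0.62, 0.9),
    })


@dataclass
class StudyReport:
    running: pd.DataFrame               # per player x scope running summary
    running_effects: list               # EffectReport per running variable, H2 vs H1
    physio_effects: list                # EffectReport for La / HR summaries
    kick_sets: pd.DataFrame             # per player x set means
    kick_anova: dict                    # variable -> (F, p)
    neuro_effects: list                 # Table-1-style EffectReport rows
    correlations: pd.DataFrame          # r / p for Δ running vs Δ neuro
    vvo2max_kmh: np.ndarray

    def summary(self) -> str:
        lines = ["Simulated-game fatigue study — synthetic cohort", ""]
        lines.append("Running performance (2nd half vs 1st half):")
        lines += ["  " + e.summary() for e in self.running_effects]
        lines.append("Physiology (2nd half vs 1st half):")
        lines += ["  " + e.summary() for e in self.physio_effects]
        lines.append("Kick sets (ANOVA across sets):")
        for var, (f, p) in self.kick_anova.items():
            lines.append(f"  {var:<12} F={f:5.2f}  P={p:4.2f}")
        lines.append("Neuromuscular (after vs before):")
        lines += ["  " + e.summary() for e in self.neuro_effects]
        lines.append("Correlations of change scores (r, p):")
        for _, row in self.correlations.iterrows():
            lines.append(
                f"  {row['x']:<8} vs {row['y']:<8} r={row['r']:+5.2f}  P={row['p']:4.2f}"
            )
        return "\n".join(lines)


def _paired(df: pd.DataFrame, var: str) -> st.PairedSample:
    sub = df[df["variable"] == var]
    return st.PairedSample(sub["subject"].to_numpy(),
                           sub["before"].to_numpy(), sub["after"].to_numpy())


def run_study(cfg: StudyConfig | None = None) -> StudyReport:
    cfg = cfg or StudyConfig()
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    player_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(cfg.n_players)]

    fatigue = np.clip(rng.normal(1.0, cfg.fatigue_sd, cfg.n_players), 0.1, 2.0)

    # --- incremental test: vVO2max per player -------------------------------
    vvo2 = np.empty(cfg.n_players)
    for i in range(cfg.n_players):
        series, _ = sg.gen_breath_series(sg.BreathSimConfig(seed=player_seeds[i]))
        res = pm.vo2max(pm.resample_breaths(series), age_years=cfg.age_years)
        vvo2[i] = res.vvo2max

    # --- simulated game: tracking ------------------------------------------
    run_rows = []
    for i in range(cfg.n_players):
        dec = float(np.clip(cfg.half2_decrement * fatigue[i], 0.0, 0.4))
        track, _truth = sg.gen_player_track(
            sg.TrackSimConfig(duration_s=cfg.play_duration_s,
                              half2_decrement=dec, seed=player_seeds[i] + 1),
            player_id=f"p{i + 1}",
        )
        for s in tm.summarize(track, vvo2max_ms=vvo2[i] / 3.6,
                              scheduled_period_minutes=cfg.scheduled_period_minutes):
            run_rows.append({"player_id": s.player_id, "scope": s.scope,
                             "DC": s.DC, "DC_MIN": s.DC_MIN,
                             "S_N": s.S_N, "S_T": s.S_T})
    running = pd.DataFrame(run_rows)

    halves = running[running["scope"].isin(["H1", "H2"])].pivot(
        index="player_id", columns="scope")
    running_effects = []
    for var in ("DC", "DC_MIN", "S_N", "S_T"):
        s = st.PairedSample(halves.index.to_numpy(),
                            halves[(var, "H1")].to_numpy(),
                            halves[(var, "H2")].to_numpy())
        running_effects.append(st.effect_report(s, variable=var))

    # --- physiology: lactate and heart rate per half ------------------------
    phys_rows = []
    for i in range(cfg.n_players):
        prng = np.random.default_rng(player_seeds[i] + 2)
        la = {
            "H1": prng.normal(4.8, 2.0, 2).clip(0.8),
            "H2": prng.normal(4.5, 2.0, 2).clip(0.8),
        }
        for half in ("H1", "H2"):
            hr_mean = prng.normal(168.0 if half == "H1" else 166.0, 10.0)
            t = np.arange(0, 1200.0)
            hr = hr_mean + 12 * np.sin(2 * math.pi * t / 300.0) + prng.normal(0, 3, len(t))
            la_sum = pm.lactate_summary(la[half], scope=half)
            hr_sum = pm.hr_summary(hr, scope=half)
            phys_rows.append({"player_id": f"p{i + 1}", "half": half,
                              "La_PEAK": la_sum.peak, "La_MEAN": la_sum.mean,
                              "HR_PEAK": hr_sum.peak, "HR_MEAN": hr_sum.mean})
    phys = pd.DataFrame(phys_rows).pivot(index="player_id", columns="half")
    physio_effects = []
    for var in ("La_PEAK", "La_MEAN", "HR_PEAK", "HR_MEAN"):
        s = st.PairedSample(phys.index.to_numpy(),
                            phys[(var, "H1")].to_numpy(),
                            phys[(var, "H2")].to_numpy())
        physio_effects.append(st.effect_report(s, variable=var))

    # --- finishing kicks -----------------------------------------------------
    goal = km.GoalTarget()
    kick_rows = []
    for i in range(cfg.n_players):
        krng = np.random.default_rng(player_seeds[i] + 3)
        for set_no, set_kmh in enumerate(cfg.kick_set_speeds_kmh, start=1):
            results = []
            for j in range(cfg.kicks_per_set):
                speed = krng.normal(set_kmh, 5.0) / 3.6
                th = math.radians(krng.normal(0.0, 2.0))      # lateral aim error
                tv = math.radians(krng.normal(8.5, 2.5))      # elevation
                v0 = (speed * math.cos(tv) * math.sin(th),
                      speed * math.cos(tv) * math.cos(th),
                      speed * math.sin(tv))
                traj, _ = sg.gen_kick(
                    sg.KickSimConfig(v0=v0, seed=int(krng.integers(2 ** 31))),
                    kick_id=f"p{i + 1}s{set_no}k{j + 1}")
                results.append(km.analyze_kick(traj, goal))
            sp, acc = km.summarize_set(results)
            kick_rows.append({"player_id": f"p{i + 1}", "set": set_no,
                              "speed_kmh": sp, "accuracy_m": acc})
    kick_sets = pd.DataFrame(kick_rows)
    kick_anova = {}
    for var in ("speed_kmh", "accuracy_m"):
        groups = [g[var].to_numpy() for _, g in kick_sets.groupby("set")]
        kick_anova[var] = st.oneway_anova(groups)

    # --- neuromuscular assessment -------------------------------------------
    neuro_rows = []
    for i in range(cfg.n_neuro):
        nrng = np.random.default_rng(player_seeds[i] + 4)
        pop = cfg.neuro_population
        mvc_b = nrng.normal(*pop["F_PEAK"][:2])
        tc_b = max(nrng.normal(*pop["TC"][:2]), 60.0)
        va_b = float(np.clip(nrng.normal(*pop["VA"][:2]), 50.0, 99.0))
        rms_b = max(nrng.normal(*pop["RMS"][:2]), 0.1)
        mw_b = max(nrng.normal(*pop["MWave"][:2]), 0.8)
        mvc_a = mvc_b + pop["F_PEAK"][2] * fatigue[i] + nrng.normal(0, pop["F_PEAK"][3])
        tc_a = max(tc_b + pop["TC"][2] * fatigue[i] + nrng.normal(0, pop["TC"][3]), 40.0)
        va_a = float(np.clip(va_b + pop["VA"][2] * fatigue[i]
                             + nrng.normal(0, pop["VA"][3]), 30.0, 99.0))
        rms_a = max(rms_b + pop["RMS"][2] + nrng.normal(0, pop["RMS"][3]), 0.05)
        mw_a = max(mw_b + pop["MWave"][2] + nrng.normal(0, pop["MWave"][3]), 0.5)
        for moment, mvc, tc, va, rms, mw in (
            ("before", mvc_b, tc_b, va_b, rms_b, mw_b),
            ("after", mvc_a, tc_a, va_a, rms_a, mw_a),
        ):
            # two MVC attempts per session, reduced by the higher F_PEAK
            attempts = []
            for a in range(2):
                scale = 1.0 if a == 0 else nrng.uniform(0.96, 1.0)
                trace, _ = sg.gen_mvc_trace(sg.MvcSimConfig(
                    mvc_force=mvc * scale, va_true=va, tc_amp=tc,
                    seed=int(nrng.integers(2 ** 31))))
                attempts.append(nm.analyze_force_trace(trace))
            tw = nm.combine_mvcs(attempts)
            emg, _ = sg.gen_emg_trace(sg.EmgSimConfig(
                rms_true=rms, mwave_amp=mw, seed=int(nrng.integers(2 ** 31))))
            ftrace, _ = sg.gen_mvc_trace(sg.MvcSimConfig(
                mvc_force=mvc, va_true=va, tc_amp=tc, noise_sd=0.0))
            window, _ = nm.detect_plateau(nm.filter_force(ftrace))
            er = nm.analyze_emg(emg, window)
            neuro_rows += [
                {"subject": f"p{i + 1}", "moment": moment, "variable": v, "value": val}
                for v, val in (("F_PEAK", tw.F_PEAK), ("TC", tw.TC), ("VA", tw.VA),
                               ("RMS", er.RMS), ("MWave", er.MWave),
                               ("RMS_MW", er.RMS_MW))
            ]
    ndf = pd.DataFrame(neuro_rows).pivot(
        index=["subject", "variable"], columns="moment", values="value").reset_index()
    neuro_effects = []
    for var in ("F_PEAK", "TC", "VA", "RMS", "MWave", "RMS_MW"):
        sub = ndf[ndf["variable"] == var]
        s = st.PairedSample(sub["subject"].to_numpy(),
                            sub["before"].to_numpy(), sub["after"].to_numpy())
        neuro_effects.append(st.effect_report(s, variable=var))

    # --- correlations of change scores --------------------------------------
    neuro_ids = [f"p{i + 1}" for i in range(cfg.n_neuro)]
    run_delta = {
        var: (halves.loc[neuro_ids, (var, "H2")] - halves.loc[neuro_ids, (var, "H1")]).to_numpy()
        for var in ("DC", "DC_MIN", "S_N", "S_T")
    }
    neuro_delta = {}
    for var in ("F_PEAK", "TC", "VA", "RMS", "MWave", "RMS_MW"):
        sub = ndf[ndf["variable"] == var].set_index("subject").loc[neuro_ids]
        neuro_delta[var] = (sub["after"] - sub["before"]).to_numpy()
    corr_rows = []
    for rv, rd in run_delta.items():
        for nv, nd in neuro_delta.items():
            try:
                r, p = st.pearson_r(rd, nd)
            except ValueError:
                r, p = float("nan"), float("nan")
            corr_rows.append({"x": f"Δ{rv}", "y": f"Δ{nv}", "r": r, "p": p})
    correlations = pd.DataFrame(corr_rows)

    return StudyReport(
        running=running, running_effects=running_effects,
        physio_effects=physio_effects, kick_sets=kick_sets,
        kick_anova=kick_anova, neuro_effects=neuro_effects,
        correlations=correlations, vvo2max_kmh=vvo2,
    )
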