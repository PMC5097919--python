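"""Time-motion variables: filtering, speed, distance and sprint detection."""

import math

import numpy as np
import pytest

from matchfatigue import synthgame as sg
from matchfatigue import tracking as tm


def make_track(t, x, y, period="P1", pid="p1"):
    per = np.full(len(t), period, dtype=object)
    return tm.PlayerTrack(pid, np.asarray(t, float), np.asarray(x, float),
                          np.asarray(y, float), per)


@pytest.fixture
def jog_track():
    """60 s straight jog at 2 m/s with 5-cm jitter; true length 120 m."""
    t = np.arange(0, 60, 1 / 30)
    rng = np.random.default_rng(42)
    x = 2.0 * t + rng.normal(0, 0.05, len(t))
    y = 5.0 + rng.normal(0, 0.05, len(t))
    return make_track(t, x, y)


class TestFilterTrack:
    def test_constant_position_unchanged(self):
        t = np.arange(0, 30, 1 / 30)
        tr = make_track(t, np.full(len(t), 5.0), np.full(len(t), 5.0))
        f = tm.filter_track(tr)
        assert np.allclose(f.x, 5.0, atol=1e-9)
        assert tm.distance_covered(f) == pytest.approx(0.0, abs=1e-9)

    def test_high_frequency_jitter_removed(self):
        # 5-Hz sinusoid, 0.05 m: 3rd-order response at 5/0.4, squared for the
        # dual pass, leaves < 1e-3 m of amplitude
        t = np.arange(0, 60, 1 / 30)
        tr = make_track(t, 10 + 0.05 * np.sin(2 * np.pi * 5 * t), np.zeros(len(t)))
        f = tm.filter_track(tr)
        interior = slice(100, -100)
        assert np.max(np.abs(f.x[interior] - 10.0)) < 1e-3

    def test_linear_motion_preserved(self):
        t = np.arange(0, 30, 1 / 30)
        tr = make_track(t, 2.0 * t, np.zeros(len(t)))
        f = tm.filter_track(tr)
        # interior = beyond the 0.4-Hz filter's settling time (~5 s)
        interior = slice(150, -150)
        assert np.max(np.abs(f.x[interior] - 2.0 * t[interior])) < 1e-6

    def test_cutoff_above_nyquist_rejected(self):
        t = np.arange(0, 30, 1 / 30)
        tr = make_track(t, t, t)
        with pytest.raises(ValueError):
            tm.filter_track(tr, cutoff_hz=20.0)


class TestComputeSpeed:
    def test_linear_motion(self):
        t = np.arange(0, 20, 1 / 30)
        tr = make_track(t, 3.0 * t, np.zeros(len(t)))
        assert np.allclose(tm.compute_speed(tr), 3.0, atol=1e-9)

    def test_stationary(self):
        t = np.arange(0, 20, 1 / 30)
        tr = make_track(t, np.ones(len(t)), np.ones(len(t)))
        assert np.allclose(tm.compute_speed(tr), 0.0, atol=1e-12)

    def test_circular_motion(self):
        r, w = 5.0, 0.8
        t = np.arange(0, 30, 1 / 30)
        tr = make_track(t, r * np.cos(w * t), r * np.sin(w * t))
        sp = tm.compute_speed(tr)
        assert np.allclose(sp[1:-1], r * w, rtol=1e-3)


class TestDistance:
    def test_square_path_exact(self):
        # 4 x 10 m legs walked at 1 m/s, sampled at 10 Hz
        t = np.arange(0, 40, 0.1)
        s = t % 40
        x = np.select([s < 10, s < 20, s < 30, s >= 30],
                      [s, 10.0, 30 - s, 0.0])
        y = np.select([s < 10, s < 20, s < 30, s >= 30],
                      [0.0, s - 10, 10.0, 40 - s])
        tr = make_track(t, x, y)
        assert tm.distance_covered(tr) == pytest.approx(39.9, abs=1e-9)  # 399 steps

    def test_noisy_jog_recovered_within_one_percent(self, jog_track):
        f = tm.filter_track(jog_track)
        dc = tm.distance_covered(f)
        assert abs(dc - 120.0) / 120.0 < 0.01

    def test_unfiltered_noise_inflates_path(self, jog_track):
        assert tm.distance_covered(jog_track) > 120.0

    def test_distance_per_minute(self):
        assert tm.distance_per_minute(2000.0, 20.0) == pytest.approx(100.0)
        assert tm.distance_per_minute(0.0, 20.0) == 0.0
        with pytest.raises(ValueError):
            tm.distance_per_minute(100.0, 0.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 30, 1 / 30)
        x = np.cumsum(rng.normal(0, 0.05, len(t)))
        y = np.cumsum(rng.normal(0, 0.05, len(t)))
        tr = make_track(t, x, y)
        ang = 1.1
        c, s = math.cos(ang), math.sin(ang)
        tr2 = make_track(t, c * x - s * y + 12.0, s * x + c * y - 4.0)
        assert tm.distance_covered(tr2) == pytest.approx(tm.distance_covered(tr))

    def test_filtering_never_lengthens_straight_line(self):
        t = np.arange(0, 30, 1 / 30)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr = make_track(t, 1.5 * t + rng.normal(0, 0.05, len(t)),
                            rng.normal(0, 0.05, len(t)))
            assert tm.distance_covered(tm.filter_track(tr)) <= tm.distance_covered(tr)


class TestDetectSprints:
    def test_never_above_threshold(self):
        t = np.arange(0, 10, 1 / 30)
        bouts = tm.detect_sprints(t, np.full(len(t), 2.0), threshold=4.0)
        assert bouts == []

    def test_two_separated_excursions(self):
        t = np.arange(0, 10, 1 / 30)
        sp = np.full(len(t), 2.0)
        sp[(t >= 1) & (t < 3)] = 5.0
        sp[(t >= 6) & (t < 8)] = 5.0
        bouts = tm.detect_sprints(t, sp, threshold=4.0)
        assert len(bouts) == 2
        assert sum(b.duration_s for b in bouts) == pytest.approx(4.0, abs=0.1)

    def test_min_duration_filters_blips(self):
        t = np.arange(0, 10, 1 / 30)
        sp = np.full(len(t), 2.0)
        sp[100] = 9.0
        assert len(tm.detect_sprints(t, sp, 4.0)) == 1
        assert tm.detect_sprints(t, sp, 4.0, min_duration_s=0.5) == []

    def test_merging_adjacent_bouts_never_increases_count(self):
        t = np.arange(0, 10, 1 / 30)
        sp = np.full(len(t), 2.0)
        sp[(t >= 1) & (t < 3)] = 5.0
        sp[(t >= 4) & (t < 6)] = 5.0
        n_sep = len(tm.detect_sprints(t, sp, 4.0))
        sp[(t >= 3) & (t < 4)] = 5.0     # bridge the gap
        n_merged = len(tm.detect_sprints(t, sp, 4.0))
        assert n_merged <= n_sep

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            tm.detect_sprints(np.arange(5.0), np.ones(5), 0.0)


class TestSummarize:
    @pytest.fixture
    def four_period_track(self):
        track, truth = sg.gen_player_track(
            sg.TrackSimConfig(duration_s=480.0, half2_decrement=0.1, seed=2))
        return track, truth

    def test_halves_and_match_are_additive(self, four_period_track):
        track, _ = four_period_track
        out = {s.scope: s for s in tm.summarize(track, vvo2max_ms=3.9,
                                                scheduled_period_minutes=2.0)}
        assert out["H1"].DC == pytest.approx(out["P1"].DC + out["P2"].DC)
        assert out["match"].DC == pytest.approx(out["H1"].DC + out["H2"].DC)
        assert out["H1"].S_T == pytest.approx(out["P1"].S_T + out["P2"].S_T)
        assert out["match"].S_N == out["H1"].S_N + out["H2"].S_N

    def test_sprint_time_bounded_by_scope_duration(self, four_period_track):
        track, _ = four_period_track
        for s in tm.summarize(track, vvo2max_ms=3.9, scheduled_period_minutes=2.0):
            dur = {"P": 120.0, "H": 240.0, "m": 480.0}[s.scope[0]]
            assert 0.0 <= s.S_T <= dur
            assert s.S_N >= 0

    def test_decremented_second_half_covers_less_ground(self, four_period_track):
        track, _ = four_period_track
        out = {s.scope: s for s in tm.summarize(track, vvo2max_ms=3.9,
                                                scheduled_period_minutes=2.0)}
        assert out["H2"].DC < out["H1"].DC

    def test_dc_at_least_straight_line_displacement(self, four_period_track):
        track, _ = four_period_track
        f = tm.filter_track(track)
        for p in ("P1", "P2", "P3", "P4"):
            sub = f.select(p)
            disp = math.hypot(sub.x[-1] - sub.x[0], sub.y[-1] - sub.y[0])
            assert tm.distance_covered(sub) >= disp - 1e-9

    def test_effective_time_denominator_mode(self, four_period_track):
        track, _ = four_period_track
        sched = {s.scope: s for s in tm.summarize(track, 3.9,
                                                  scheduled_period_minutes=2.0)}
        eff = {s.scope: s for s in tm.summarize(track, 3.9,
                                                scheduled_period_minutes=None)}
        assert sched["match"].DC == pytest.approx(eff["match"].DC)
        # effective span is one sample short of the schedule -> higher DC_MIN
        assert eff["match"].DC_MIN >= sched["match"].DC_MIN
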