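"""MVC force processing, twitch interpolation and EMG measures."""

import numpy as np
import pytest

from matchfatigue import neuro as nm
from matchfatigue import synthgame as sg


def flat_trace(level=800.0, fs=1000.0, dur=12.0, markers=()):
    t = np.arange(int(dur * fs)) / fs
    return nm.ForceTrace(t, np.full(len(t), level), list(markers))


class TestFilterForce:
    def test_dc_level_unchanged(self):
        f = nm.filter_force(flat_trace(800.0))
        assert np.allclose(f.force, 800.0, atol=1e-9)

    def test_100hz_component_strongly_attenuated(self):
        t = np.arange(12000) / 1000.0
        tr = nm.ForceTrace(t, 800 + 50 * np.sin(2 * np.pi * 100 * t), [])
        f = nm.filter_force(tr)
        assert np.max(np.abs(f.force[500:-500] - 800.0)) < 0.1

    def test_ramp_preserved_in_interior(self):
        t = np.arange(12000) / 1000.0
        tr = nm.ForceTrace(t, 100.0 * t, [])
        f = nm.filter_force(tr)
        assert np.allclose(f.force[500:-500], 100.0 * t[500:-500], atol=1e-3)


class TestDetectPlateau:
    def test_noise_free_plateau_level(self):
        trace, _ = sg.gen_mvc_trace(sg.MvcSimConfig(mvc_force=840.2, noise_sd=0.0))
        _, fpeak = nm.detect_plateau(nm.filter_force(trace))
        assert fpeak == pytest.approx(840.2, abs=1.0)

    def test_superimposed_twitch_masked_out(self):
        """A +40-N twitch inside the masked artifact window must not lift
        F_PEAK above the true 800-N plateau."""
        trace, _ = sg.gen_mvc_trace(sg.MvcSimConfig(
            mvc_force=800.0, va_true=86.14, tc_amp=288.6, noise_sd=0.0))
        _, fpeak = nm.detect_plateau(nm.filter_force(trace))
        assert fpeak == pytest.approx(800.0, abs=2.0)
        assert fpeak < 810.0

    def test_noisy_plateau_recovery(self):
        vals = []
        for seed in range(100):
            trace, _ = sg.gen_mvc_trace(sg.MvcSimConfig(
                mvc_force=800.0, noise_sd=5.0, seed=seed))
            _, fpeak = nm.detect_plateau(nm.filter_force(trace))
            vals.append(fpeak)
        assert abs(np.mean(vals) - 800.0) < 3.0

    def test_everything_masked_rejected(self):
        t = np.arange(300) / 1000.0
        tr = nm.ForceTrace(t, np.full(300, 100.0), [(0.0, "superimposed")])
        with pytest.raises(ValueError):
            nm.detect_plateau(tr, artifact_ms=400.0)


class TestTwitchAmplitude:
    def test_relaxed_doublet_construction(self):
        trace, truth = sg.gen_mvc_trace(sg.MvcSimConfig(tc_amp=288.6, noise_sd=0.0))
        amp, base = nm.twitch_amplitude(trace, (2.0, "relaxed"))
        assert amp == pytest.approx(288.6, abs=0.5)
        assert base == pytest.approx(0.0, abs=1e-6)

    def test_superimposed_recovery_with_noise(self):
        errs = []
        for seed in range(50):
            trace, truth = sg.gen_mvc_trace(sg.MvcSimConfig(
                mvc_force=840.2, va_true=85.9, tc_amp=288.6, seed=seed))
            ft = nm.filter_force(trace)
            amp, _ = nm.twitch_amplitude(ft, (7.0, "superimposed"))
            errs.append(amp - truth.TS)
        assert abs(np.mean(errs)) < 0.5

    def test_flat_trace_gives_zero(self):
        amp, _ = nm.twitch_amplitude(flat_trace(), (2.0, "relaxed"))
        assert amp == 0.0


class TestVoluntaryActivation:
    def test_limits(self):
        assert nm.voluntary_activation(0.0, 288.6)[0] == pytest.approx(100.0)
        assert nm.voluntary_activation(288.6, 288.6)[0] == pytest.approx(0.0)

    def test_uncorrected_worked_example(self):
        va, corrected, flags = nm.voluntary_activation(40.0, 288.6)
        assert va == pytest.approx(86.14, abs=0.005)
        assert not corrected and flags == []

    def test_corrected_worked_example(self):
        va, corrected, _ = nm.voluntary_activation(
            40.0, 288.6, force_at_stim=700.0, F_PEAK=840.2, on_plateau=False)
        assert va == pytest.approx(88.45, abs=0.005)
        assert corrected

    def test_corrected_equals_uncorrected_at_peak_force(self):
        va_u, _, _ = nm.voluntary_activation(35.0, 250.0)
        va_c, _, _ = nm.voluntary_activation(
            35.0, 250.0, force_at_stim=800.0, F_PEAK=800.0, on_plateau=False)
        assert va_c == pytest.approx(va_u)

    def test_out_of_range_flagged_not_clamped(self):
        va, _, flags = nm.voluntary_activation(300.0, 250.0)
        assert va < 0 and "va_out_of_range" in flags

    def test_nonpositive_tc_rejected(self):
        with pytest.raises(ValueError):
            nm.voluntary_activation(10.0, 0.0)


class TestBandpassEmg:
    def test_drift_removed_and_passband_preserved(self):
        fs = 2000.0
        t = np.arange(int(10 * fs)) / fs
        drift = 0.5 * np.sin(2 * np.pi * 5 * t)
        mid = 0.3 * np.sin(2 * np.pi * 100 * t)
        tr = nm.EMGTrace(t, drift + mid)
        f = nm.bandpass_emg(tr)
        sl = slice(2000, -2000)
        resid = f.signal[sl] - mid[sl]
        # 5-Hz drift: > 20 dB down; 100-Hz component preserved within 1%
        assert np.max(np.abs(resid)) < 0.05 * 0.5
        amp = (np.max(f.signal[sl]) - np.min(f.signal[sl])) / 2
        assert amp == pytest.approx(0.3, rel=0.01)

    def test_zero_signal_stays_zero(self):
        t = np.arange(4000) / 2000.0
        f = nm.bandpass_emg(nm.EMGTrace(t, np.zeros(len(t))))
        assert np.allclose(f.signal, 0.0, atol=1e-12)

    def test_invalid_band_rejected(self):
        t = np.arange(4000) / 2000.0
        with pytest.raises(ValueError):
            nm.bandpass_emg(nm.EMGTrace(t, np.zeros(len(t))), band=(20.0, 1500.0))


class TestRmsAndMwave:
    def test_rms_closed_forms(self):
        fs = 2000.0
        t = np.arange(int(4 * fs)) / fs
        const = nm.EMGTrace(t, np.full(len(t), 0.5))
        assert nm.rms_over_plateau(const, (1.5, 2.5)) == pytest.approx(0.5)
        sine = nm.EMGTrace(t, 0.8 * np.sin(2 * np.pi * 50 * t))
        assert nm.rms_over_plateau(sine, (1.5, 2.5)) == pytest.approx(
            0.8 / np.sqrt(2), rel=1e-3)

    def test_rms_of_concatenated_windows_matches(self):
        fs = 2000.0
        t = np.arange(int(4 * fs)) / fs
        rng = np.random.default_rng(0)
        one = rng.normal(0, 0.5, int(fs))
        sig = np.concatenate([one, one, one, one])
        tr = nm.EMGTrace(t, sig)
        r1 = nm.rms_over_plateau(tr, (0.0, 1.0), span_s=1.0)
        r4 = float(np.sqrt(np.mean(sig ** 2)))
        assert r1 == pytest.approx(r4, rel=1e-9)

    def test_rms_recovery_from_generator(self):
        errs = []
        for seed in range(20):
            emg, truth = sg.gen_emg_trace(sg.EmgSimConfig(rms_true=0.53, seed=seed))
            rms = nm.rms_over_plateau(emg, (6.5, 7.5))
            errs.append(abs(rms - 0.53) / 0.53)
        assert np.mean(errs) < 0.02

    def test_mwave_amplitude_construction(self):
        emg, truth = sg.gen_emg_trace(sg.EmgSimConfig(
            mwave_amp=3.75, baseline_rms=0.0, seed=1))
        amp, flags = nm.mwave_amplitude(emg)
        assert amp == pytest.approx(3.75, abs=0.01)
        assert flags == []

    def test_ratio_and_missing_marker(self):
        emg, _ = sg.gen_emg_trace(sg.EmgSimConfig(rms_true=0.53, mwave_amp=3.75, seed=2))
        trace, _ = sg.gen_mvc_trace(sg.MvcSimConfig(noise_sd=0.0))
        window, _ = nm.detect_plateau(nm.filter_force(trace))
        res = nm.analyze_emg(emg, window)
        assert res.RMS_MW == pytest.approx(res.RMS / res.MWave)
        emg.mwave_marker = None
        res2 = nm.analyze_emg(emg, window)
        assert res2.MWave is None and "no_mwave_marker" in res2.flags

    def test_noise_only_window_flagged_unreliable(self):
        emg, _ = sg.gen_emg_trace(sg.EmgSimConfig(
            mwave_amp=0.01, baseline_rms=0.05, seed=3))
        amp, flags = nm.mwave_amplitude(emg)
        assert "unreliable" in flags


class TestEndToEnd:
    def test_full_twitch_analysis_recovers_truth(self):
        trace, truth = sg.gen_mvc_trace(sg.MvcSimConfig(
            mvc_force=840.2, va_true=85.9, tc_amp=288.6, seed=0))
        res = nm.analyze_force_trace(trace)
        assert res.F_PEAK == pytest.approx(truth.F_PEAK, abs=3.0)
        assert res.TC == pytest.approx(truth.TC, abs=2.0)
        assert res.TS == pytest.approx(truth.TS, abs=1.0)
        assert res.VA == pytest.approx(truth.VA, abs=1.0)
        assert not res.corrected

    def test_fpeak_invariant_to_masked_twitch_size(self):
        base, _ = sg.gen_mvc_trace(sg.MvcSimConfig(
            mvc_force=800.0, va_true=95.0, noise_sd=0.0))
        big, _ = sg.gen_mvc_trace(sg.MvcSimConfig(
            mvc_force=800.0, va_true=60.0, noise_sd=0.0))
        f1 = nm.analyze_force_trace(base).F_PEAK
        f2 = nm.analyze_force_trace(big).F_PEAK
        # tolerance covers the twitch tail outlasting the 300-ms mask
        assert f2 == pytest.approx(f1, abs=3.0)

    def test_combine_mvcs_best_and_mean(self):
        r1 = nm.TwitchResult(800.0, 280.0, 30.0, 89.0, 798.0, False)
        r2 = nm.TwitchResult(820.0, 285.0, 28.0, 90.0, 818.0, False)
        assert nm.combine_mvcs([r1, r2]).F_PEAK == 820.0
        assert nm.combine_mvcs([r1, r2], rule="mean").F_PEAK == pytest.approx(810.0)
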