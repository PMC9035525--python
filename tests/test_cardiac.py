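import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import perictal as pc
from perictal.cardiac import (
    RrSeries,
    detect_r_peaks,
    epoch_mean_hr,
    hrv_metrics,
    instant_hr,
    qtc,
    stage_hr_summary,
)
from perictal.errors import InsufficientDataError, ParameterError
from perictal.synth import _pqrst_template

from conftest import quiet_ecg_params, quiet_lfp_params, short_config


def clean_ecg(hr_bpm, duration=60.0, rate=2000.0, noise=0.0, seed=0):
    """Jitter-free template train at a constant programmed heart rate."""
    template, r_idx = _pqrst_template(rate)
    n = int(duration * rate)
    sig = (np.random.default_rng(seed).normal(0, noise, n) if noise
           else np.zeros(n))
    rr = 60.0 / hr_bpm
    beats = np.arange(0.2, duration - 0.1, rr)
    for tb in beats:
        i = int(round(tb * rate)) - r_idx
        sig[i:i + template.size] += template
    return pc.TimeSeries(sig, rate, label="ECG", units="mV"), beats


class TestDetection:
    def test_600bpm_train_counts_and_rr(self):
        ecg, beats = clean_ecg(600.0)
        rr = detect_r_peaks(ecg)
        assert beats.size - 1 <= rr.n_peaks <= beats.size + 1
        assert np.all(np.abs(rr.rr - 100.0) <= 1000.0 / ecg.rate)

    def test_725bpm_mean_rr(self):
        ecg, _ = clean_ecg(725.0)
        rr = detect_r_peaks(ecg)
        assert abs(rr.rr.mean() - 60000.0 / 725.0) / (60000.0 / 725.0) < 0.02

    @pytest.mark.parametrize("hr", [300.0, 600.0, 725.0, 1000.0])
    def test_f1_perfect_on_clean_trains(self, hr):
        ecg, beats = clean_ecg(hr)
        got = detect_r_peaks(ecg).peak_times
        tol = 0.003
        hits = sum(np.any(np.abs(got - b) < tol) for b in beats)
        assert hits == beats.size == got.size  # F1 = 1.0

    def test_rr_timing_with_noise_snr10(self):
        # R amplitude 1 mV; SNR 10 dB on the broadband trace
        ecg, beats = clean_ecg(600.0, noise=0.10, seed=1)
        rr = detect_r_peaks(ecg)
        assert abs(rr.n_peaks - beats.size) <= 1
        assert np.median(np.abs(rr.rr - 100.0)) <= 3 * 1000.0 / ecg.rate

    def test_flatline_warns_and_returns_empty(self):
        flat = pc.TimeSeries(np.zeros(10000), 2000.0)
        with pytest.warns(UserWarning):
            rr = detect_r_peaks(flat)
        assert rr.n_peaks == 0

    def test_post_asystole_has_zero_peaks(self):
        cfg = short_config(postictal_s=140.0)
        cfg.ecg = quiet_ecg_params()
        cfg.ecg.asystole_delay_range_s = (120.0, 120.0)
        ecg = pc.generate_ecg(cfg.ecg, cfg, "non_survivor", 3)
        death = cfg.markers("non_survivor").death_time
        rr = detect_r_peaks(ecg, pc.Epoch("post", death + 121.0, death + 135.0))
        assert rr.n_peaks == 0

    def test_low_rate_rejected(self):
        with pytest.raises(ParameterError):
            detect_r_peaks(pc.TimeSeries(np.zeros(1000), 250.0))


class TestInstantHr:
    def test_constant_rr_gives_600(self):
        times = np.arange(0.0, 60.0, 0.1)
        rr = RrSeries(times, np.diff(times) * 1000.0)
        _, hr = instant_hr(rr)
        assert np.allclose(hr, 600.0, atol=1e-6)

    def test_step_transition_inside_smoothing_window(self):
        t1 = np.arange(0.0, 30.0, 0.1)
        t2 = np.arange(30.0, 60.0, 0.2)
        times = np.concatenate([t1, t2])
        rr = RrSeries(times, np.diff(times) * 1000.0)
        grid, hr = instant_hr(rr)
        assert np.all(hr[grid < 29.0] > 590)
        assert np.all(hr[grid > 32.0] < 310)

    def test_fewer_than_two_peaks_empty(self):
        t, hr = instant_hr(RrSeries(np.array([1.0]), np.array([])))
        assert t.size == 0 and hr.size == 0


class TestHrv:
    def test_hand_computed_series(self):
        rr = RrSeries(np.array([]), np.array([100.0, 110.0, 90.0, 100.0, 100.0]))
        m = hrv_metrics(rr)
        v = np.array([100.0, 110.0, 90.0, 100.0, 100.0])
        assert m.mean_rr == pytest.approx(v.mean(), rel=1e-9)
        assert m.sdnn == pytest.approx(v.std(ddof=1), rel=1e-9)
        assert m.cv == pytest.approx(100 * v.std(ddof=1) / v.mean(), rel=1e-9)
        assert m.rmssd == pytest.approx(np.sqrt(np.mean(np.diff(v) ** 2)), rel=1e-9)
        assert m.sdnn == pytest.approx(7.0710678, rel=1e-6)
        assert m.rmssd == pytest.approx(12.2474487, rel=1e-6)

    def test_constant_rr_zero_variability(self):
        m = hrv_metrics(RrSeries(np.array([]), np.full(50, 100.0)))
        assert m.sdnn == m.cv == m.rmssd == 0.0

    def test_sdnn_recovery_from_generator(self):
        cfg = short_config(baseline_s=150.0)
        cfg.ecg = quiet_ecg_params()
        ecg = pc.generate_ecg(cfg.ecg, cfg, "survivor", 9)
        rr = detect_r_peaks(ecg, pc.Epoch("baseline", 5.0, 120.0))
        assert rr.rr.size > 1000
        m = hrv_metrics(rr)
        assert 4.0 <= m.sdnn <= 6.0  # target 5 ms; SD sampling error at n~1100

    def test_too_few_intervals_rejected(self):
        with pytest.raises(InsufficientDataError):
            hrv_metrics(RrSeries(np.array([0.0]), np.array([100.0])))


class TestQtc:
    @pytest.mark.parametrize("qt,rr,expected", [(50, 100, 50), (50, 400, 25),
                                                (40, 25, 80)])
    def test_formula_values(self, qt, rr, expected):
        assert qtc(qt, rr) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(k=st.floats(0.1, 10.0), qt=st.floats(1.0, 200.0),
           rr=st.floats(10.0, 500.0))
    def test_homogeneous_in_qt(self, k, qt, rr):
        assert qtc(k * qt, rr) == pytest.approx(k * qtc(qt, rr), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            qtc(0.0, 100.0)
        with pytest.raises(ParameterError):
            qtc(50.0, -1.0)


class TestStageSummary:
    def test_survivor_postictal_back_at_baseline(self):
        cfg = short_config()
        cfg.ecg = quiet_ecg_params()
        rec = pc.generate_recording(cfg, "survivor", 21)
        tbl = stage_hr_summary(rec).set_index("epoch")
        base = tbl.loc["baseline", "mean_hr_bpm"]
        post = tbl.loc["postictal", "mean_hr_bpm"]
        assert abs(post - base) / base < 0.05

    def test_non_survivor_ictal_tachycardia(self):
        cfg = short_config()
        cfg.ecg = quiet_ecg_params()
        rec = pc.generate_recording(cfg, "non_survivor", 22)
        tbl = stage_hr_summary(rec).set_index("epoch")
        assert tbl.loc["ictal", "mean_hr_bpm"] > tbl.loc["baseline", "mean_hr_bpm"]

    def test_stage_hr_recovery_within_2pct(self):
        cfg = short_config()
        cfg.ecg = quiet_ecg_params()
        cfg.ecg.sdnn_ms = 0.0
        rec = pc.generate_recording(cfg, "non_survivor", 23)
        tbl = stage_hr_summary(rec).set_index("epoch")
        assert abs(tbl.loc["baseline", "mean_hr_bpm"] - 600.0) / 600.0 < 0.02
        assert abs(tbl.loc["ictal", "mean_hr_bpm"] - 725.0) / 725.0 < 0.02
        assert abs(tbl.loc["postictal", "mean_hr_bpm"] - 181.0) / 181.0 < 0.02

    def test_no_peaks_yields_zero_beats(self):
        cfg = short_config()
        rec = pc.generate_recording(cfg, "survivor", 24)
        flat = pc.TimeSeries(np.zeros(rec.ecg.n), rec.ecg.rate, label="ECG")
        rec2 = pc.SeizureRecording(m1=rec.m1, dr=rec.dr, ecg=flat,
                                   markers=rec.markers, outcome=rec.outcome,
                                   animal_id="flat")
        with pytest.warns(UserWarning):
            tbl = stage_hr_summary(rec2)
        assert (tbl["n_beats"] == 0).all()
        assert tbl["mean_hr_bpm"].isna().all()
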