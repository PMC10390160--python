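"""Pan-Tompkins detection, tachogram assembly, NN screening, Berger resampling."""

import numpy as np
import pytest

from mousehrv import (
    EcgRecord,
    ModulationSpec,
    RPeakList,
    RRSeries,
    berger_resample,
    generate_ecg,
    generate_rr_series,
    nn_filter,
    pan_tompkins_detect,
    rr_from_peaks,
)

from oracles import berger_value


def _match(truth, detected, tol_s=0.0025):
    d = np.abs(truth[:, None] - detected[None, :])
    sens = float((d.min(axis=1) <= tol_s).mean())
    ppv = float((d.min(axis=0) <= tol_s).mean())
    return sens, ppv, float(d.min(axis=1).max())


class TestPanTompkins:
    def test_clean_ecg_recovers_all_peaks(self):
        spec = ModulationSpec(mean_rr=200.0, frac_vlf=0.3, frac_lf=0.3,
                              frac_hf=0.2, total_sd=4.0)
        rr = generate_rr_series(spec, duration=60.0, seed=2)
        ecg, truth = generate_ecg(rr, fs=4000.0, seed=2)
        peaks = pan_tompkins_detect(ecg)
        assert abs(len(peaks) - truth.size) <= 1
        sens, ppv, worst = _match(truth, peaks.times)
        assert sens == 1.0 and ppv == 1.0
        assert worst <= 0.0025

    def test_flat_trace_warns_and_returns_zero_peaks(self):
        ecg = EcgRecord(np.zeros(20000), fs=4000.0)
        with pytest.warns(UserWarning, match="all-constant"):
            peaks = pan_tompkins_detect(ecg)
        assert len(peaks) == 0

    def test_polarity_agnostic_on_inverted_lead(self):
        rr = RRSeries(np.full(250, 200.0))
        ecg, truth = generate_ecg(rr, fs=2000.0, seed=4)
        inverted = EcgRecord(-ecg.samples, fs=2000.0)
        peaks = pan_tompkins_detect(inverted)
        sens, ppv, _ = _match(truth, peaks.times)
        assert sens == 1.0 and ppv == 1.0

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            pan_tompkins_detect(EcgRecord(np.random.default_rng(0).normal(size=1000),
                                          fs=4000.0))


class TestTachogram:
    def test_rr_from_peak_times(self):
        peaks = RPeakList(np.array([0.0, 0.2, 0.4, 0.6]), np.ones(4))
        rr = rr_from_peaks(peaks)
        np.testing.assert_allclose(rr.intervals, [200.0, 200.0, 200.0])
        peaks = RPeakList(np.array([0.0, 0.2, 0.5]), np.ones(3))
        np.testing.assert_allclose(rr_from_peaks(peaks).intervals, [200.0, 300.0])

    def test_two_peaks_insufficient(self):
        with pytest.raises(ValueError, match="3 peaks"):
            rr_from_peaks(RPeakList(np.array([0.0, 0.2]), np.ones(2)))

    def test_detection_reproduces_generator_intervals(self):
        spec = ModulationSpec(mean_rr=220.0, frac_lf=0.4, frac_hf=0.3, total_sd=5.0)
        rr = generate_rr_series(spec, duration=60.0, seed=7)
        ecg, _ = generate_ecg(rr, fs=4000.0, seed=7)
        det = rr_from_peaks(pan_tompkins_detect(ecg))
        n = min(len(det), len(rr)) - 1
        np.testing.assert_allclose(det.intervals[:n], rr.intervals[1:n + 1], atol=2.5)


class TestNnFilter:
    def test_clean_constant_series_unflagged(self):
        rr = nn_filter(RRSeries(np.full(50, 200.0)))
        assert rr.normal_flags.all()

    def test_single_ectopic_interval_flagged(self):
        x = np.full(51, 200.0)
        x[25] = 400.0
        rr = nn_filter(RRSeries(x), deviation_limit=0.2)
        assert not rr.normal_flags[25]
        assert rr.normal_flags.sum() == 50

    def test_invalid_limit_rejected(self):
        with pytest.raises(ValueError, match="deviation_limit"):
            nn_filter(RRSeries(np.full(10, 200.0)), deviation_limit=1.5)
        with pytest.raises(ValueError, match="window"):
            nn_filter(RRSeries(np.full(10, 200.0)), window=4)


class TestBergerResample:
    def test_constant_series_resamples_exactly(self):
        rr = RRSeries(np.full(400, 150.0))
        u = berger_resample(rr, fs_out=10.0)
        np.testing.assert_allclose(u.values, 150.0, rtol=1e-9)

    def test_step_series_monotone_with_correct_limits(self):
        intervals = np.concatenate([np.full(400, 150.0), np.full(300, 200.0)])
        rr = RRSeries(intervals)
        u = berger_resample(rr, fs_out=10.0)
        assert np.all(np.diff(u.values) >= -1e-9)
        np.testing.assert_allclose(u.values[0], 150.0, rtol=1e-9)
        np.testing.assert_allclose(u.values[-1], 200.0, rtol=1e-9)
        # direct windowed-count oracle at points away from the step
        beats = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
        for t in (10.0, 30.0, 100.0):
            expect = berger_value(beats, t, 10.0)
            got = u.values[int(round((t - u.t0) * 10.0))]
            assert got == pytest.approx(expect, rel=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        intervals = 200.0 + 5.0 * rng.standard_normal(300)
        a = berger_resample(RRSeries(intervals))
        shifted = RRSeries(intervals, beat_times=np.cumsum(intervals) / 1000.0 + 17.3)
        b = berger_resample(shifted)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)
        assert b.t0 - a.t0 == pytest.approx(17.3, abs=1e-9)

    def test_mean_preserved_within_one_percent(self, kx_rr):
        u = berger_resample(kx_rr)
        assert np.mean(u.values) == pytest.approx(np.mean(kx_rr.nn), rel=0.01)

    def test_flagged_interval_merged_with_neighbor(self):
        x = np.full(200, 150.0)
        x[100] = 50.0  # short ectopic-like interval
        flags = np.ones(200, bool)
        flags[100] = False
        u = berger_resample(RRSeries(x, normal_flags=flags))
        # merged span removes the rate spike: without merging the windowed
        # count would dip to ~100 ms around the ectopic interval
        assert u.values.min() > 140.0

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            berger_resample(RRSeries(np.array([150.0, 150.0])))
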