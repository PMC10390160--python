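"""R-peak detection and tachogram construction.

The detector is a Pan-Tompkins pipeline with constants rescaled for murine
timing: band-pass, five-point derivative, squaring, moving-window
integration, dual adaptive thresholds with running signal/noise estimates,
refractory blanking and half-threshold searchback.  A mouse QRS complex is
~10 ms wide (vs ~80-100 ms in humans), so the default pass-band is
10-100 Hz, the integration window 15 ms and the refractory period 50 ms;
all constants are configurable.

Also here: RR tachogram assembly, median-rule flagging of non-normal
(ectopic-like) intervals, and Berger's windowed fractional-beat-count
resampling onto a uniform 10 Hz grid for spectral analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .series import EcgRecord, RPeakList, RRSeries, UniformSeries

__all__ = [
    "DetectorParams",
    "pan_tompkins_detect",
    "rr_from_peaks",
    "nn_filter",
    "berger_resample",
]


@dataclass(frozen=True)
class DetectorParams:
    """Pan-Tompkins constants, with murine defaults.

    ``threshold_coef`` is the weight of new peaks in the running signal /
    noise estimates (classic 1/8, halved to 1/16-equivalent learning during
    searchback by ``searchback_learning``).
    """

    bandpass_low: float = 10.0
    bandpass_high: float = 100.0
    integration_window: float = 15.0  # ms
    refractory: float = 50.0  # ms
    searchback_factor: float = 1.66
    threshold_coef: float = 0.125
    searchback_learning: float = 0.25
    polarity_agnostic: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high < fs / 2:
            raise ValueError("band-pass edges must satisfy 0 < low < high < fs/2")
        if self.integration_window <= 0 or self.refractory <= 0:
            raise ValueError("integration window and refractory period must be positive")
        if not 0 < self.threshold_coef < 1:
            raise ValueError("threshold_coef must lie in (0, 1)")


def _preprocess(ecg: EcgRecord, params: DetectorParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (band-passed signal, moving-window-integrated energy signal)."""
    sos = _signal.butter(
        2, [params.bandpass_low, params.bandpass_high], btype="band", fs=ecg.fs, output="sos"
    )
    filtered = _signal.sosfiltfilt(sos, ecg.samples)
    # five-point derivative, classic kernel (1/8)[1 2 0 -2 -1] scaled by fs
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (ecg.fs / 8.0)
    deriv = np.convolve(filtered, kernel, mode="same")
    squared = deriv * deriv
    win = max(1, int(round(params.integration_window / 1000.0 * ecg.fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return filtered, mwi


def pan_tompkins_detect(
    ecg: EcgRecord, params: DetectorParams | None = None
) -> RPeakList:
    """Detect R peaks in a raw ECG record.

    Candidate fiducials are local maxima of the integrated energy signal;
    they are accepted against adaptive thresholds maintained on both the
    integrated and the band-passed signal, with refractory blanking and a
    searchback pass at half threshold whenever the gap since the last
    accepted beat exceeds ``searchback_factor`` times the running RR
    average.  Accepted fiducials are refined to the local extremum of the
    raw trace within +/- one integration window.
    """
    params = params or DetectorParams()
    params.validate(ecg.fs)
    if ecg.n_samples < 2 * ecg.fs:
        raise ValueError("record must be at least 2 s long for detection")
    if np.ptp(ecg.samples) == 0:
        warnings.warn("all-constant ECG signal: no peaks detected", stacklevel=2)
        return RPeakList(times=np.array([]), amplitudes=np.array([]))

    filtered, mwi = _preprocess(ecg, params)
    fs = ecg.fs
    refr = int(round(params.refractory / 1000.0 * fs))
    cand_idx, _ = _signal.find_peaks(mwi, distance=refr)
    if cand_idx.size == 0:
        raise ValueError("too few beats: no candidate peaks found")

    fabs = np.abs(filtered)
    win = max(1, int(round(params.integration_window / 1000.0 * fs)))

    def _fpeak(i: int) -> float:
        lo, hi = max(0, i - win), min(len(fabs), i + win + 1)
        return float(fabs[lo:hi].max())

    # learning phase: first two seconds
    learn = slice(0, int(2 * fs))
    spki = 0.5 * float(mwi[learn].max())
    npki = float(np.mean(mwi[learn])) * 0.5
    spkf = 0.5 * float(fabs[learn].max())
    npkf = float(np.mean(fabs[learn])) * 0.5

    c = params.threshold_coef
    accepted: list[int] = []
    rr_hist: list[float] = []
    pending: list[int] = []  # rejected candidates since last accepted beat

    def _thr_i() -> float:
        return npki + 0.25 * (spki - npki)

    def _thr_f() -> float:
        return npkf + 0.25 * (spkf - npkf)

    for i in cand_idx:
        pi = float(mwi[i])
        pf = _fpeak(int(i))
        gap_ok = not accepted or (i - accepted[-1]) > refr
        if gap_ok and pi > _thr_i() and pf > _thr_f():
            accepted.append(int(i))
            spki = c * pi + (1 - c) * spki
            spkf = c * pf + (1 - c) * spkf
            if len(accepted) > 1:
                rr_hist.append(accepted[-1] - accepted[-2])
                del rr_hist[:-8]
            pending = []
        else:
            npki = c * pi + (1 - c) * npki
            npkf = c * pf + (1 - c) * npkf
            pending.append(int(i))
        # searchback: gap since last beat exceeds searchback_factor * mean RR
        if accepted and rr_hist:
            rr_avg = float(np.mean(rr_hist))
            if (i - accepted[-1]) > params.searchback_factor * rr_avg and pending:
                back = [j for j in pending
                        if j > accepted[-1] + refr and mwi[j] > 0.5 * _thr_i()]
                if back:
                    j = int(max(back, key=lambda k: mwi[k]))
                    accepted.append(j)
                    accepted.sort()
                    sc = params.searchback_learning * c
                    spki = sc * float(mwi[j]) + (1 - sc) * spki
                    rr_hist.append(accepted[-1] - accepted[-2])
                    del rr_hist[:-8]
                    pending = [k for k in pending if k > j]

    if len(accepted) < 2:
        raise ValueError("too few beats: fewer than 2 peaks detected")

    # refine fiducials on the raw trace (avoids filter group delay)
    raw = ecg.samples
    ref_sig = np.abs(raw - np.median(raw)) if params.polarity_agnostic else raw
    refined: list[int] = []
    for i in accepted:
        lo, hi = max(0, i - win), min(len(raw), i + win + 1)
        refined.append(lo + int(np.argmax(ref_sig[lo:hi])))
    refined_arr = np.unique(refined)
    times = ecg.start_time + refined_arr / fs
    return RPeakList(times=times, amplitudes=raw[refined_arr])


def rr_from_peaks(peaks: RPeakList) -> RRSeries:
    """Build the RR tachogram (ms) from detected R-peak times."""
    if len(peaks) < 3:
        raise ValueError("at least 3 peaks are required to build a tachogram")
    dt = np.diff(peaks.times)
    if np.any(dt <= 0):
        raise ValueError("peak times must be strictly increasing")
    return RRSeries(intervals=dt * 1000.0, beat_times=peaks.times[1:])


def nn_filter(rr: RRSeries, deviation_limit: float = 0.2, window: int = 11) -> RRSeries:
    """Flag non-normal intervals by a running-median rule.

    An interval is flagged when it deviates from the median of the
    surrounding ``window`` beats by more than ``deviation_limit`` times
    that median.  Flagged intervals are excluded from all downstream
    metrics.  This is a conventional ectopy screen; it defaults to *off*
    in the pipeline for synthetic data.
    """
    if not 0 < deviation_limit < 1:
        raise ValueError("deviation_limit must lie in (0, 1)")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd number of beats, at least 3")
    x = rr.intervals
    n = x.size
    half = window // 2
    flags = np.array(rr.normal_flags, copy=True)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med = float(np.median(x[lo:hi]))
        if med > 0 and abs(x[i] - med) > deviation_limit * med:
            flags[i] = False
    return RRSeries(intervals=x, beat_times=rr.beat_times, normal_flags=flags)


def _beat_count_nodes(rr: RRSeries) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear cumulative beat count over the beat train.

    Non-normal intervals are merged with their following (or, at the end,
    preceding) neighbor: the shared beat is removed so the merged span
    counts as a single interval.
    """
    open_time = rr.beat_times[0] - rr.intervals[0] / 1000.0
    times = [open_time]
    counts = [0.0]
    i = 0
    n = len(rr)
    while i < n:
        if rr.normal_flags[i] or i == n - 1:
            times.append(rr.beat_times[i])
            counts.append(counts[-1] + 1.0)
            i += 1
        else:
            # merge flagged interval with its successor: one count across both
            times.append(rr.beat_times[i + 1])
            counts.append(counts[-1] + 1.0)
            i += 2
    return np.asarray(times), np.asarray(counts)


def berger_resample(rr: RRSeries, fs_out: float = 10.0) -> UniformSeries:
    """Resample a tachogram to a uniform interval signal by Berger's method.

    For each output sample a window of width ``2/fs_out`` centered on the
    sample counts the fractional number of beat intervals it covers; the
    local rate is ``fs_out/2`` times that count and the stored value is the
    corresponding interval in ms.  Windows extending beyond the record are
    dropped rather than padded.
    """
    if not fs_out > 0:
        raise ValueError("fs_out must be positive")
    if rr.n_normal < 3:
        raise ValueError("at least 3 normal intervals are required")
    if rr.span < 2.0 / fs_out:
        raise ValueError("record span shorter than one Berger window")
    node_t, node_c = _beat_count_nodes(rr)
    h = 1.0 / fs_out
    t0 = node_t[0] + h
    t_last = node_t[-1] - h
    n_out = int(np.floor((t_last - t0) * fs_out)) + 1
    if n_out < 1:
        raise ValueError("record span shorter than one Berger window")
    grid = t0 + np.arange(n_out) / fs_out
    count = np.interp(grid + h, node_t, node_c) - np.interp(grid - h, node_t, node_c)
    rate = fs_out / 2.0 * count  # beats per second
    values = 1000.0 / rate
    return UniformSeries(values=values, fs_out=fs_out, t0=t0)
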