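"""Time-domain HRV metrics: SDNN, RMSSD, TINN and mean heart rate.

All operate on the normal (NN) subset of an :class:`~mousehrv.series.RRSeries`.
SDNN is the sample standard deviation (denominator N-1); mean HR is defined
via the mean interval, ``60000 / mean(NN)``, not the mean of instantaneous
rates — the two differ for variable series.  TINN is the baseline width of
the best-fit triangle to the NN histogram, found by exhaustive search over
bin-aligned triangle feet; the default 1 ms bin suits the narrow murine NN
spread (a few ms) where the human-standard 1/128 s bin would be too coarse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import RRSeries

__all__ = ["TimeDomainResult", "sdnn", "rmssd", "tinn", "mean_hr",
           "time_domain_metrics", "five_minute_windows"]


@dataclass(frozen=True)
class TimeDomainResult:
    sdnn: float
    rmssd: float
    tinn: float
    mean_hr: float
    mean_nn: float
    n_beats: int
    segment_length: float


def _nn(rr: RRSeries | np.ndarray) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.nn
    return np.asarray(rr, dtype=float)


def sdnn(rr: RRSeries | np.ndarray) -> float:
    """Sample standard deviation of NN intervals, ms."""
    x = _nn(rr)
    if x.size < 2:
        raise ValueError("sdnn requires at least 2 normal intervals")
    return float(np.std(x, ddof=1))


def rmssd(rr: RRSeries | np.ndarray) -> float:
    """Root mean square of successive NN differences, ms.

    Differences are taken only between adjacent normal intervals; the mean
    is over the number of differences.
    """
    if isinstance(rr, RRSeries):
        d = _adjacent_normal_diffs(rr)
    else:
        x = np.asarray(rr, dtype=float)
        d = np.diff(x)
    if d.size < 1 or (d.size < 2 and _nn(rr).size < 3):
        raise ValueError("rmssd requires at least 2 successive differences")
    return float(np.sqrt(np.mean(d * d)))


def _adjacent_normal_diffs(rr: RRSeries) -> np.ndarray:
    """Successive differences between intervals that are adjacent and both normal."""
    x = rr.intervals
    f = rr.normal_flags
    keep = f[1:] & f[:-1]
    return (x[1:] - x[:-1])[keep]


def tinn(rr: RRSeries | np.ndarray, bin_width: float = 1.0) -> float:
    """Triangular interpolation of the NN histogram: baseline width M - N, ms.

    With the mode bin (center X, count Y) fixed, the triangle that is zero
    outside [N, M] and linear N -> (X, Y) -> M is fitted by exhaustive
    search over bin-aligned feet minimizing the squared error against the
    histogram.  A histogram concentrated in a single bin returns 0.
    """
    x = _nn(rr)
    if x.size < 20:
        raise ValueError("tinn requires at least 20 normal intervals")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil((x.max() + 1e-12) / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, lo + nbins * bin_width))
    centers = (edges[:-1] + edges[1:]) / 2.0
    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        return 0.0

    mode = int(np.argmax(counts))
    X, Y = centers[mode], float(counts[mode])
    # allow the triangle feet to extend beyond the occupied support
    ext = max(nbins, 2)
    grid = lo + bin_width / 2.0 + bin_width * np.arange(-ext, nbins + ext)
    eval_counts = np.zeros(grid.size)
    eval_counts[ext: ext + nbins] = counts

    def tri_err(N: float, M: float) -> float:
        t = np.zeros(grid.size)
        left = (grid >= N) & (grid <= X)
        right = (grid > X) & (grid <= M)
        if X > N:
            t[left] = Y * (grid[left] - N) / (X - N)
        else:
            t[left] = Y
        if M > X:
            t[right] = Y * (M - grid[right]) / (M - X)
        d = eval_counts - t
        return float(d @ d)

    best = (np.inf, 0.0)
    n_candidates = grid[grid <= X]
    m_candidates = grid[grid >= X]
    for N in n_candidates:
        for M in m_candidates:
            if M <= N:
                continue
            e = tri_err(N, M)
            if e < best[0] - 1e-12:
                best = (e, M - N)
    return float(best[1])


def mean_hr(rr: RRSeries | np.ndarray) -> float:
    """Mean heart rate, bpm, defined as 60000 / mean NN interval."""
    x = _nn(rr)
    if x.size < 1:
        raise ValueError("mean_hr requires at least 1 normal interval")
    return 60000.0 / float(np.mean(x))


def time_domain_metrics(rr: RRSeries, bin_width: float = 1.0) -> TimeDomainResult:
    """Bundle of all time-domain metrics for one segment."""
    x = rr.nn
    return TimeDomainResult(
        sdnn=sdnn(rr),
        rmssd=rmssd(rr),
        tinn=tinn(rr, bin_width=bin_width),
        mean_hr=mean_hr(rr),
        mean_nn=float(np.mean(x)),
        n_beats=int(x.size),
        segment_length=rr.span,
    )


def five_minute_windows(rr: RRSeries, window_s: float = 300.0) -> list[RRSeries]:
    """Split a tachogram into consecutive windows (default the standard 5 min)."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    out: list[RRSeries] = []
    t_open = rr.beat_times[0] - rr.intervals[0] / 1000.0
    start = t_open
    while start < rr.beat_times[-1]:
        mask = (rr.beat_times > start) & (rr.beat_times <= start + window_s)
        if np.count_nonzero(mask) >= 2:
            out.append(RRSeries(
                intervals=rr.intervals[mask],
                beat_times=rr.beat_times[mask],
                normal_flags=rr.normal_flags[mask],
            ))
        start += window_s
    return out
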