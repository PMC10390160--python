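"""Nonlinear HRV metrics: DFA, Poincaré plot geometry, and entropies.

Detrended fluctuation analysis integrates the mean-centered tachogram,
y(k) = sum_{i<=k} (RR_i - RR_mean), detrends it box-wise with least-squares
lines, and measures the RMS fluctuation F(n) per box size n.  The short-
and long-term scaling exponents alpha1 and alpha2 are the log-log slopes of
F(n) over box sizes 4-11 and 12-64 beats (inclusive integer ranges; a
strict-inequality reading is available via the range arguments).

Poincaré SD1/SD2 are the dispersions of successive-interval pairs across
and along the line of identity; with the pair-count denominator used here
SD1 equals RMSSD/sqrt(2) exactly whenever the mean successive difference
is zero.

Approximate and sample entropy count repeating templates of length m within
a Chebyshev tolerance r (a fraction of the series SD, conventionally 20%);
ApEn includes self-matches, SampEn excludes them — the defining difference.
An undefined SampEn (no matches at length m+1) is reported as NaN, never as
infinity, keeping group tables numeric with explicit missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .series import RRSeries

__all__ = [
    "DfaResult", "PoincareResult", "EntropyResult",
    "dfa", "poincare", "apen", "sampen", "entropy_metrics",
]


@dataclass(frozen=True)
class DfaResult:
    box_sizes: np.ndarray
    fluctuation: np.ndarray  # F(n), ms
    alpha1: float
    alpha2: float
    range1: tuple[int, int]
    range2: tuple[int, int]


@dataclass(frozen=True)
class PoincareResult:
    sd1: float
    sd2: float
    ratio_sd2_sd1: float  # NaN when sd1 == 0
    center: tuple[float, float]


@dataclass(frozen=True)
class EntropyResult:
    apen: float
    sampen: float
    m: int
    r: float  # ms
    n_used: int


def _nn(rr: RRSeries | np.ndarray) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.nn
    return np.asarray(rr, dtype=float)


def _box_fluctuation(y: np.ndarray, n: int) -> float:
    """RMS deviation of y from per-box least-squares lines, boxes of size n."""
    n_boxes = y.size // n
    seg = y[: n_boxes * n].reshape(n_boxes, n)
    t = np.arange(n, dtype=float)
    t_mean = t.mean()
    t_var = float(((t - t_mean) ** 2).sum())
    seg_mean = seg.mean(axis=1, keepdims=True)
    slope = ((seg - seg_mean) @ (t - t_mean)) / t_var
    trend = seg_mean + slope[:, None] * (t - t_mean)
    resid = seg - trend
    return float(np.sqrt(np.mean(resid * resid)))


def dfa(
    rr: RRSeries | np.ndarray,
    range1: tuple[int, int] = (4, 11),
    range2: tuple[int, int] = (12, 64),
) -> DfaResult:
    """Detrended fluctuation analysis of the NN tachogram.

    Boxes are taken from the start of the series with the tail discarded.
    Raises on degenerate input (any F(n) = 0 inside a fit range, as for a
    perfectly linear tachogram).
    """
    x = _nn(rr)
    n_max = max(range1[1], range2[1])
    if x.size < 2 * n_max + 2:
        raise ValueError(
            f"series too short for DFA: need at least {2 * n_max + 2} intervals"
        )
    y = np.cumsum(x - x.mean())
    sizes = np.arange(min(range1[0], range2[0]), n_max + 1)
    fluct = np.array([_box_fluctuation(y, int(n)) for n in sizes])

    def _slope(rng: tuple[int, int]) -> float:
        mask = (sizes >= rng[0]) & (sizes <= rng[1])
        fr = fluct[mask]
        if np.any(fr == 0):
            raise ValueError("degenerate fluctuation: F(n) = 0 inside fit range")
        if np.count_nonzero(mask) < 3:
            raise ValueError("fewer than 3 box sizes in fit range")
        return float(np.polyfit(np.log(sizes[mask]), np.log(fr), 1)[0])

    return DfaResult(
        box_sizes=sizes,
        fluctuation=fluct,
        alpha1=_slope(range1),
        alpha2=_slope(range2),
        range1=tuple(range1),
        range2=tuple(range2),
    )


def poincare(rr: RRSeries | np.ndarray) -> PoincareResult:
    """Poincaré plot dispersion: SD1 (width), SD2 (length), SD2/SD1.

    With x = RR_n and y = RR_{n+1}, SD1 and SD2 are the standard deviations
    of (x - y)/sqrt(2) and (x + y)/sqrt(2) about their means, with the pair
    count as denominator.
    """
    v = _nn(rr)
    if v.size < 3:
        raise ValueError("poincare requires at least 3 normal intervals")
    x, y = v[:-1], v[1:]
    d1 = (x - y) / np.sqrt(2.0)
    d2 = (x + y) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean((d1 - d1.mean()) ** 2)))
    sd2 = float(np.sqrt(np.mean((d2 - d2.mean()) ** 2)))
    ratio = sd2 / sd1 if sd1 > 0 else float("nan")
    return PoincareResult(sd1=sd1, sd2=sd2, ratio_sd2_sd1=ratio,
                          center=(float(x.mean()), float(y.mean())))


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def apen(rr: RRSeries | np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Approximate entropy with Chebyshev distance and self-matches included.

    r is ``r_frac`` times the sample SD of the series; a constant series
    returns 0 by convention.
    """
    x = _nn(rr)
    _check_entropy_input(x, m)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm: int) -> float:
        templ = _embed(x, mm)
        d = cdist(templ, templ, metric="chebyshev")
        c = np.count_nonzero(d <= r, axis=1) / templ.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sampen(rr: RRSeries | np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) over ordered template pairs, self-matches excluded.

    A and B are counted over the same N-m templates of length m+1 and m.
    Returns NaN when no length-(m+1) pair matches (undefined, reported as
    missing rather than infinite); a constant series returns 0.
    """
    x = _nn(rr)
    _check_entropy_input(x, m)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    r = r_frac * sd
    tm = _embed(x, m)[: x.size - m]  # N - m templates for both lengths
    tm1 = _embed(x, m + 1)
    db = cdist(tm, tm, metric="chebyshev")
    da = cdist(tm1, tm1, metric="chebyshev")
    nb = tm.shape[0]
    b = int(np.count_nonzero(db <= r)) - nb  # remove self-pairs
    a = int(np.count_nonzero(da <= r)) - tm1.shape[0]
    if b == 0:
        raise ValueError("no template matches at length m; r too small")
    if a == 0:
        return float("nan")
    return float(-np.log(a / b))


def _check_entropy_input(x: np.ndarray, m: int) -> None:
    if m < 1:
        raise ValueError("m must be at least 1")
    if m >= x.size:
        raise ValueError("m must be smaller than the series length")
    if x.size < 50:
        raise ValueError("entropy estimates require at least 50 normal intervals")


def entropy_metrics(rr: RRSeries | np.ndarray, m: int = 2, r_frac: float = 0.2) -> EntropyResult:
    """ApEn and SampEn with a shared (m, r) convention."""
    x = _nn(rr)
    _check_entropy_input(x, m)
    sd = float(np.std(x, ddof=1))
    return EntropyResult(
        apen=apen(x, m=m, r_frac=r_frac),
        sampen=sampen(x, m=m, r_frac=r_frac),
        m=m,
        r=r_frac * sd,
        n_used=int(x.size),
    )
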