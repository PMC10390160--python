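"""Frequency-domain HRV: Welch spectral estimate and murine band powers.

The uniform 10 Hz interval signal is analyzed with Welch-averaged tapered
periodograms (default 60 s Hann segments, 50% overlap, per-segment linear
detrend).  Band powers integrate the one-sided density over the murine
bands VLF 0-0.15 Hz, LF 0.15-1.5 Hz, HF 1.5-5 Hz; the 0 Hz (mean) bin is
excluded from VLF, total power is the sum of the three bands, and relative
powers are percentages of that total, so the three always sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .series import UniformSeries

__all__ = ["Spectrum", "BandPowerResult", "welch_psd", "band_powers",
           "segment_detrended_variance", "BANDS"]

#: murine band edges, Hz
BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.0, 0.15),
    "lf": (0.15, 1.5),
    "hf": (1.5, 5.0),
}


@dataclass(frozen=True)
class Spectrum:
    frequencies: np.ndarray  # Hz, strictly increasing, up to fs_out/2
    density: np.ndarray  # ms^2 / Hz, one-sided
    window_s: float
    overlap: float
    taper: str


@dataclass(frozen=True)
class BandPowerResult:
    vlf_abs: float
    lf_abs: float
    hf_abs: float
    total_power: float
    vlf_rel: float
    lf_rel: float
    hf_rel: float
    lf_hf: float


def welch_psd(series: UniformSeries, window: float = 60.0, overlap: float = 0.5,
              taper: str = "hann") -> Spectrum:
    """Welch power spectral density of the interval signal, ms^2/Hz."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if series.span < window:
        raise ValueError(
            f"series span {series.span:.1f} s is shorter than the {window:.0f} s "
            "analysis window; use a shorter window"
        )
    nperseg = int(round(window * series.fs_out))
    noverlap = int(round(overlap * nperseg))
    f, pxx = _signal.welch(
        series.values,
        fs=series.fs_out,
        window=taper,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="linear",
        scaling="density",
    )
    return Spectrum(frequencies=f, density=pxx, window_s=window, overlap=overlap,
                    taper=taper)


def segment_detrended_variance(series: UniformSeries, window: float = 60.0,
                               overlap: float = 0.5) -> float:
    """Mean variance of the linearly detrended Welch segments (ms^2).

    This is the time-domain quantity a Welch estimate with per-segment
    linear detrending conserves, i.e. the Parseval counterpart of the
    integrated density; it is computed directly from the samples without
    any spectral step.
    """
    x = series.values
    nperseg = int(round(window * series.fs_out))
    step = nperseg - int(round(overlap * nperseg))
    if x.size < nperseg:
        raise ValueError("series span shorter than one segment")
    out = []
    for start in range(0, x.size - nperseg + 1, step):
        seg = x[start: start + nperseg]
        out.append(float(np.var(_signal.detrend(seg, type="linear"))))
    return float(np.mean(out))


def _integrate_band(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density between lo and hi Hz.

    Band edges falling between grid points are handled by linear
    interpolation of the density at the exact edge.
    """
    lo = max(lo, float(f[0]))
    hi = min(hi, float(f[-1]))
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    fg = np.concatenate(([lo], f[inner], [hi]))
    pg = np.concatenate(([np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]))
    return float(np.trapezoid(pg, fg))


def band_powers(spec: Spectrum) -> BandPowerResult:
    """Integrate the murine VLF/LF/HF bands into absolute and relative powers."""
    f, p = spec.frequencies, spec.density
    if f[-1] < BANDS["hf"][1] - 1e-9:
        raise ValueError("spectrum must cover the full 0-5 Hz murine range")
    # exclude the 0 Hz (mean) bin from VLF: start at the first positive grid point
    vlf_lo = float(f[f > 0][0])
    vlf = _integrate_band(f, p, vlf_lo, BANDS["vlf"][1])
    lf = _integrate_band(f, p, *BANDS["lf"])
    hf = _integrate_band(f, p, *BANDS["hf"])
    total = vlf + lf + hf
    if total <= 1e-12:
        raise ValueError("total spectral power is zero: relative powers undefined")
    return BandPowerResult(
        vlf_abs=vlf,
        lf_abs=lf,
        hf_abs=hf,
        total_power=total,
        vlf_rel=100.0 * vlf / total,
        lf_rel=100.0 * lf / total,
        hf_rel=100.0 * hf / total,
        lf_hf=lf / hf if hf > 0 else float("inf"),
    )
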