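"""Core data containers for the analysis pipeline.

Everything downstream operates on one of three containers: a uniformly
sampled voltage trace (:class:`EcgRecord`), the beat-to-beat interval
tachogram (:class:`RRSeries`), or the uniformly resampled interval signal
(:class:`UniformSeries`) that spectral analysis requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EcgRecord", "RPeakList", "RRSeries", "UniformSeries"]


@dataclass
class EcgRecord:
    """Single-lead ECG trace sampled uniformly at ``fs`` Hz.

    Parameters
    ----------
    samples : array-like
        Voltage in mV.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("ECG samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class RPeakList:
    """Detected R-wave fiducials: strictly increasing times (s) and amplitudes (mV)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RRSeries:
    """Beat-to-beat interval tachogram.

    ``intervals`` are in ms; ``beat_times`` (s) give the time of the beat
    *closing* each interval; ``normal_flags`` marks intervals retained as
    normal sinus (NN) intervals.  Metrics operate on the NN subset only.
    """

    intervals: np.ndarray
    beat_times: np.ndarray | None = None
    normal_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and not np.all(self.intervals > 0):
            raise ValueError("RR intervals must be positive")
        if self.beat_times is None:
            # reconstruct a beat train starting at t = intervals[0]/1000
            self.beat_times = np.cumsum(self.intervals) / 1000.0
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size != self.intervals.size:
            raise ValueError("beat_times must match intervals in length")
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.normal_flags is None:
            self.normal_flags = np.ones(self.intervals.size, dtype=bool)
        else:
            self.normal_flags = np.asarray(self.normal_flags, dtype=bool)
        if self.normal_flags.size != self.intervals.size:
            raise ValueError("normal_flags must match intervals in length")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def nn(self) -> np.ndarray:
        """Normal-to-normal intervals (ms) — the flagged-in subset."""
        return self.intervals[self.normal_flags]

    @property
    def n_normal(self) -> int:
        return int(np.count_nonzero(self.normal_flags))

    @property
    def span(self) -> float:
        """Time covered by the beat train, in seconds (opening beat to last beat)."""
        if self.intervals.size == 0:
            return 0.0
        open_time = self.beat_times[0] - self.intervals[0] / 1000.0
        return float(self.beat_times[-1] - open_time)


@dataclass
class UniformSeries:
    """Interval signal (ms) resampled onto a fixed grid at ``fs_out`` Hz."""

    values: np.ndarray
    fs_out: float = 10.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.fs_out > 0:
            raise ValueError("fs_out must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs_out

    @property
    def span(self) -> float:
        return self.values.size / self.fs_out
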