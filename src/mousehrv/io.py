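"""File readers and writers for the pipeline's plain-text formats.

Formats: ECG as two-column CSV ``time_s,mv`` with ``# key = value`` header
lines (sampling rate, seed, preset); RR series as one ms value per line;
R-peak annotations as one time-in-seconds per line; tidy group tables as
CSV; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import EcgRecord, RPeakList, RRSeries

__all__ = [
    "write_ecg_csv", "read_ecg_csv",
    "write_rr_text", "read_rr_text",
    "write_peaks_text", "read_peaks_text",
    "write_json_report", "read_json_report",
]


def write_ecg_csv(path, record: EcgRecord, header: dict | None = None) -> None:
    meta = {"fs": record.fs, **record.meta, **(header or {})}
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("time_s,mv\n")
        t = record.times
        for ti, vi in zip(t, record.samples):
            fh.write(f"{ti:.6f},{vi:.6f}\n")


def read_ecg_csv(path, fs: float | None = None) -> EcgRecord:
    """Read two-column numeric text (time_s, mv).

    The sampling rate is taken from a ``# fs = ...`` header line unless
    overridden; with neither, it is inferred from the median time step.
    """
    meta: dict = {}
    with open(path) as fh:
        pos = 0
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = (s.strip() for s in body.split("=", 1))
                    meta[k] = v
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh)
    if df.shape[1] < 2:
        raise ValueError("ECG file must have two columns (time_s, mv)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        fs = float(meta["fs"]) if "fs" in meta else 1.0 / float(np.median(np.diff(t)))
    return EcgRecord(samples=x, fs=fs, start_time=float(t[0]), meta=meta)


def write_rr_text(path, rr: RRSeries) -> None:
    with open(path, "w") as fh:
        for v in rr.intervals:
            fh.write(f"{v:.6f}\n")


def read_rr_text(path) -> RRSeries:
    vals = np.loadtxt(path, dtype=float, ndmin=1)
    if vals.size == 0:
        raise ValueError(f"empty RR file: {path}")
    return RRSeries(intervals=vals)


def write_peaks_text(path, peaks: RPeakList | np.ndarray) -> None:
    times = peaks.times if isinstance(peaks, RPeakList) else np.asarray(peaks)
    with open(path, "w") as fh:
        for t in times:
            fh.write(f"{t:.6f}\n")


def read_peaks_text(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float, ndmin=1)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())
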