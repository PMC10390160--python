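"""Pipeline configuration: a flat, validated key-value bundle.

Every knob of the pipeline lives here with its murine default, is validated
against the owning module's preconditions at load time, and round-trips
through a flat ``key = value`` text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .detect import DetectorParams

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # acquisition / detection
    fs: float = 4000.0
    bandpass_low: float = 10.0
    bandpass_high: float = 100.0
    integration_window: float = 15.0
    refractory: float = 50.0
    searchback_factor: float = 1.66
    polarity_agnostic: bool = True
    # NN screening (off by default: no artifact criterion for synthetic data)
    nn_filter_enabled: bool = False
    nn_deviation_limit: float = 0.2
    nn_window: int = 11
    # resampling & spectrum
    resample_fs: float = 10.0
    welch_window: float = 60.0
    welch_overlap: float = 0.5
    # DFA
    dfa_range1: tuple[int, int] = (4, 11)
    dfa_range2: tuple[int, int] = (12, 64)
    # entropy
    entropy_m: int = 2
    entropy_r_frac: float = 0.2
    # time domain
    tinn_bin_width: float = 1.0
    # analysis domain: beat-domain NN series (conventional) or the 10 Hz
    # interpolated signal (the literal same-series reading)
    interpolated_domain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValueError("band-pass edges must satisfy 0 < low < high")
        if self.resample_fs <= 0 or self.fs <= 0:
            raise ValueError("sampling rates must be positive")
        if not 0 < self.nn_deviation_limit < 1:
            raise ValueError("nn_deviation_limit must lie in (0, 1)")
        if self.nn_window < 3 or self.nn_window % 2 == 0:
            raise ValueError("nn_window must be odd and >= 3")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must lie in [0, 1)")
        if self.entropy_m < 1:
            raise ValueError("entropy_m must be >= 1")
        if not 0 < self.entropy_r_frac:
            raise ValueError("entropy_r_frac must be positive")
        if self.tinn_bin_width <= 0:
            raise ValueError("tinn_bin_width must be positive")
        for rng in (self.dfa_range1, self.dfa_range2):
            if len(rng) != 2 or rng[0] >= rng[1] or rng[0] < 2:
                raise ValueError(f"invalid DFA range {rng}")

    @property
    def detector_params(self) -> DetectorParams:
        return DetectorParams(
            bandpass_low=self.bandpass_low,
            bandpass_high=self.bandpass_high,
            integration_window=self.integration_window,
            refractory=self.refractory,
            searchback_factor=self.searchback_factor,
            polarity_agnostic=self.polarity_agnostic,
        )

    def with_(self, **overrides) -> "PipelineConfig":
        return replace(self, **overrides)

    # -- flat key = value serialization -----------------------------------
    def to_file(self, path) -> None:
        Path(path).write_text(self.to_text())

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key: {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            elif isinstance(default, tuple):
                kwargs[key] = tuple(int(x) for x in val.split(","))
            else:
                kwargs[key] = val
        return cls(**kwargs)
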