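"""Subject-level analysis model.

:class:`HrvAnalysis` bundles the whole per-subject pipeline behind a
model/results pair: construct it from an ECG record (R-peak detection is
run for you), an RR tachogram, or a file, then call :meth:`HrvAnalysis.fit`
to obtain an :class:`HrvResults` carrying the time-domain, spectral, DFA,
Poincaré and entropy estimates, a text ``summary()``, JSON export and
diagnostic plots.  A metric family whose preconditions fail (e.g. a
too-short record for DFA) is marked missing with the reason, and the rest
of the report is still produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import numpy as np

from . import __version__ as _pkg_version
from .config import PipelineConfig
from .detect import berger_resample, nn_filter, pan_tompkins_detect, rr_from_peaks
from .frequency import band_powers, welch_psd
from .nonlinear import dfa, entropy_metrics, poincare
from .series import EcgRecord, RRSeries
from .timedomain import time_domain_metrics

__all__ = ["HrvAnalysis", "HrvResults"]


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


@dataclass
class _Family:
    value: object | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


class HrvAnalysis:
    """HRV analysis of one subject, configured by a :class:`PipelineConfig`.

    Parameters
    ----------
    rr : RRSeries
        Beat-to-beat tachogram (use a ``from_*`` constructor to start from
        raw ECG or files).
    config : PipelineConfig, optional
    subject_id : str, optional
    """

    def __init__(self, rr: RRSeries, config: PipelineConfig | None = None,
                 subject_id: str = "subject", meta: dict | None = None):
        self.config = config or PipelineConfig()
        self.subject_id = subject_id
        self.meta = dict(meta or {})
        if self.config.nn_filter_enabled:
            rr = nn_filter(rr, self.config.nn_deviation_limit, self.config.nn_window)
        self.rr = rr

    # ------------------------------------------------------------------
    @classmethod
    def from_ecg(cls, ecg: EcgRecord, config: PipelineConfig | None = None,
                 subject_id: str = "subject") -> "HrvAnalysis":
        """Run R-peak detection on a raw record and build the tachogram."""
        config = config or PipelineConfig()
        peaks = pan_tompkins_detect(ecg, config.detector_params)
        rr = rr_from_peaks(peaks)
        meta = {"fs": ecg.fs, "duration_s": ecg.duration, "n_peaks": len(peaks)}
        return cls(rr, config=config, subject_id=subject_id, meta=meta)

    @classmethod
    def from_ecg_file(cls, path, config: PipelineConfig | None = None,
                      fs: float | None = None, subject_id: str | None = None
                      ) -> "HrvAnalysis":
        from .io import read_ecg_csv

        ecg = read_ecg_csv(path, fs=fs)
        return cls.from_ecg(ecg, config=config, subject_id=subject_id or str(path))

    @classmethod
    def from_rr_file(cls, path, config: PipelineConfig | None = None,
                     subject_id: str | None = None) -> "HrvAnalysis":
        from .io import read_rr_text

        rr = read_rr_text(path)
        return cls(rr, config=config, subject_id=subject_id or str(path))

    # ------------------------------------------------------------------
    def fit(self) -> "HrvResults":
        """Compute every metric family; failures become missing markers."""
        cfg = self.config
        rr = self.rr

        uniform: _Family
        try:
            uniform = _Family(berger_resample(rr, fs_out=cfg.resample_fs))
        except (ValueError, IndexError) as exc:
            uniform = _Family(None, str(exc))

        # the conventional domain for beat-wise metrics is the NN tachogram;
        # the interpolated_domain flag applies the literal same-series reading
        if cfg.interpolated_domain and uniform.ok:
            beat_input: RRSeries | np.ndarray = uniform.value.values
        else:
            beat_input = rr

        def capture(fn, *args, **kwargs) -> _Family:
            try:
                return _Family(fn(*args, **kwargs))
            except (ValueError, IndexError) as exc:
                return _Family(None, str(exc))

        time_dom = capture(self._time_domain, beat_input)
        spectrum = _Family(None, uniform.error)
        bands = _Family(None, uniform.error)
        if uniform.ok:
            spectrum = capture(welch_psd, uniform.value,
                               window=cfg.welch_window, overlap=cfg.welch_overlap)
            if spectrum.ok:
                bands = capture(band_powers, spectrum.value)
            else:
                bands = _Family(None, spectrum.error)
        dfa_res = capture(dfa, beat_input, cfg.dfa_range1, cfg.dfa_range2)
        poin = capture(poincare, beat_input)
        entro = capture(entropy_metrics, beat_input,
                        m=cfg.entropy_m, r_frac=cfg.entropy_r_frac)

        return HrvResults(
            model=self,
            uniform=uniform,
            time_domain=time_dom,
            spectrum=spectrum,
            band_power=bands,
            dfa=dfa_res,
            poincare=poin,
            entropy=entro,
        )

    def _time_domain(self, beat_input):
        return time_domain_metrics(
            beat_input if isinstance(beat_input, RRSeries) else RRSeries(beat_input),
            bin_width=self.config.tinn_bin_width,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.config.to_text().encode()).hexdigest()[:12]


class HrvResults:
    """Fitted per-subject HRV report.

    Metric families are exposed as attributes (``time_domain``,
    ``band_power``, ``dfa``, ``poincare``, ``entropy``); a family that
    could not be computed is ``None`` with the reason in ``missing``.
    """

    def __init__(self, model: HrvAnalysis, uniform: _Family, time_domain: _Family,
                 spectrum: _Family, band_power: _Family, dfa: _Family,
                 poincare: _Family, entropy: _Family):
        self.model = model
        self._families = {
            "uniform": uniform,
            "time_domain": time_domain,
            "spectrum": spectrum,
            "band_power": band_power,
            "dfa": dfa,
            "poincare": poincare,
            "entropy": entropy,
        }

    def __getattr__(self, name):
        fams = object.__getattribute__(self, "_families")
        if name in fams:
            return fams[name].value
        raise AttributeError(name)

    @property
    def missing(self) -> dict[str, str]:
        """Families that could not be computed, with reasons."""
        return {k: f.error for k, f in self._families.items() if not f.ok}

    # ------------------------------------------------------------------
    def metric_values(self) -> dict[str, float]:
        """Flat scalar metric dictionary (NaN for missing)."""
        out: dict[str, float] = {}
        nan = float("nan")
        td = self.time_domain
        out["mean_hr_bpm"] = td.mean_hr if td else nan
        out["mean_nn_ms"] = td.mean_nn if td else nan
        out["sdnn_ms"] = td.sdnn if td else nan
        out["rmssd_ms"] = td.rmssd if td else nan
        out["tinn_ms"] = td.tinn if td else nan
        bp = self.band_power
        for k in ("vlf_abs", "lf_abs", "hf_abs", "total_power",
                  "vlf_rel", "lf_rel", "hf_rel", "lf_hf"):
            out[k] = getattr(bp, k) if bp else nan
        df = self.dfa
        out["dfa_alpha1"] = df.alpha1 if df else nan
        out["dfa_alpha2"] = df.alpha2 if df else nan
        pc = self.poincare
        out["sd1_ms"] = pc.sd1 if pc else nan
        out["sd2_ms"] = pc.sd2 if pc else nan
        out["sd2_sd1"] = pc.ratio_sd2_sd1 if pc else nan
        en = self.entropy
        out["apen"] = en.apen if en else nan
        out["sampen"] = en.sampen if en else nan
        return out

    def to_dict(self) -> dict:
        """Full report, JSON-serializable."""
        model = self.model
        report: dict = {
            "subject": model.subject_id,
            "provenance": {
                "software": f"mousehrv {_pkg_version}",
                "config_hash": model.config_hash(),
                "seed": model.config.seed,
            },
            "acquisition": {
                "n_intervals": len(model.rr),
                "n_normal": model.rr.n_normal,
                "span_s": model.rr.span,
                **model.meta,
            },
            "missing": self.missing,
        }
        for name in ("time_domain", "band_power", "poincare", "entropy"):
            fam = self._families[name]
            report[name] = _asdict(fam.value) if fam.ok else {"error": fam.error}
        fam = self._families["dfa"]
        if fam.ok:
            d = fam.value
            report["dfa"] = {
                "alpha1": d.alpha1, "alpha2": d.alpha2,
                "range1": list(d.range1), "range2": list(d.range2),
            }
        else:
            report["dfa"] = {"error": fam.error}
        return report

    def summary(self) -> str:
        """Human-readable per-subject report."""
        m = self.metric_values()
        lines = [
            f"HRV report - {self.model.subject_id}",
            "=" * 56,
            f"beats analyzed: {self.model.rr.n_normal}  "
            f"span: {self.model.rr.span:.1f} s",
            "",
            "Time domain",
            f"  mean HR {m['mean_hr_bpm']:8.2f} bpm    mean NN {m['mean_nn_ms']:7.2f} ms",
            f"  SDNN    {m['sdnn_ms']:8.3f} ms     RMSSD   {m['rmssd_ms']:7.3f} ms",
            f"  TINN    {m['tinn_ms']:8.2f} ms",
            "Frequency domain (VLF 0-0.15 / LF 0.15-1.5 / HF 1.5-5 Hz)",
            f"  relative  VLF {m['vlf_rel']:6.2f}%  LF {m['lf_rel']:6.2f}%  "
            f"HF {m['hf_rel']:6.2f}%",
            f"  total power {m['total_power']:.4g} ms^2    LF/HF {m['lf_hf']:.3f}",
            "Nonlinear",
            f"  DFA alpha1 {m['dfa_alpha1']:6.3f}   alpha2 {m['dfa_alpha2']:6.3f}",
            f"  SD1 {m['sd1_ms']:7.3f} ms   SD2 {m['sd2_ms']:7.3f} ms   "
            f"SD2/SD1 {m['sd2_sd1']:6.3f}",
            f"  ApEn {m['apen']:6.3f}   SampEn {m['sampen']:6.3f}",
        ]
        if self.missing:
            lines.append("Missing: " + "; ".join(f"{k}: {v}" for k, v in self.missing.items()))
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------
    def plot_poincare(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.model.rr.nn
        ax.plot(v[:-1], v[1:], ".", ms=3, alpha=0.5)
        lim = (v.min(), v.max())
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("RR(n) [ms]")
        ax.set_ylabel("RR(n+1) [ms]")
        ax.set_title(f"Poincaré plot - {self.model.subject_id}")
        return ax

    def plot_spectrum(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sp = self.spectrum
        if sp is None:
            raise ValueError("spectrum not available: " + self.missing.get("spectrum", ""))
        ax.semilogy(sp.frequencies, sp.density)
        for edge in (0.15, 1.5):
            ax.axvline(edge, color="gray", lw=0.8, ls=":")
        ax.set_xlabel("frequency [Hz]")
        ax.set_ylabel("PSD [ms$^2$/Hz]")
        return ax

    def plot_dfa(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.dfa
        if d is None:
            raise ValueError("DFA not available: " + self.missing.get("dfa", ""))
        ax.loglog(d.box_sizes, d.fluctuation, "o-", ms=3)
        ax.set_xlabel("box size n [beats]")
        ax.set_ylabel("F(n) [ms]")
        ax.set_title(f"alpha1={d.alpha1:.2f}, alpha2={d.alpha2:.2f}")
        return ax
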