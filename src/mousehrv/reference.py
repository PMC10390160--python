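"""Published murine group summaries used as calibration inputs.

Group means and standard deviations (n = 7 mice per group) for the three
anesthesia regimens — ketamine+xylazine (KX), pentobarbital (P) and
pentobarbital+fentanyl (PF) — as reported for 4-5 minute Lead II recordings.
The synthetic presets are calibrated to these levels, and the
summary-statistic inference helpers accept them directly.
"""

from __future__ import annotations

GROUPS = ("KX", "P", "PF")

GROUP_N = 7

# metric -> group -> (mean, sd)
REPORTED_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "mean_hr_bpm": {"KX": (253.81, 34.61), "P": (376.39, 23.62), "PF": (377.99, 42.94)},
    "sdnn_ms": {"KX": (8.57, 3.69), "P": (4.58, 2.78), "PF": (2.498, 1.00)},
    "rmssd_ms": {"KX": (9.27, 4.20), "P": (3.34, 3.19), "PF": (1.87, 0.58)},
    "tinn_ms": {"KX": (48.57, 17.72), "P": (26.42, 15.19), "PF": (12.14, 4.88)},
    "vlf_rel_pct": {"KX": (63.69, 21.84), "P": (67.61, 12.54), "PF": (20.43, 12.05)},
    "lf_rel_pct": {"KX": (14.34, 9.65), "P": (7.3, 3.74), "PF": (67.96, 17.05)},
    "hf_rel_pct": {"KX": (21.96, 17.85), "P": (25.09, 13.54), "PF": (11.60, 11.50)},
    "lf_hf": {"KX": (14.47, 13.69), "P": (1.03, 1.00), "PF": (0.48, 0.43)},
    "total_power": {"KX": (22.42, 14.18), "P": (2.86, 2.41), "PF": (60.71, 23.074)},
    "dfa_alpha1": {"KX": (0.28, 0.09), "P": (0.77, 0.31), "PF": (0.58, 0.25)},
    "dfa_alpha2": {"KX": (1.19, 0.21), "P": (0.76, 0.16), "PF": (0.76, 0.36)},
    "sd1_ms": {"KX": (13.28, 7.60), "P": (2.34, 1.25), "PF": (1.34, 0.42)},
    "sd2_ms": {"KX": (17.59, 6.23), "P": (3.14, 1.60), "PF": (2.63, 1.82)},
    "sd2_sd1": {"KX": (1.57, 0.39), "P": (3.19, 1.27), "PF": (2.63, 1.82)},
    "apen": {"KX": (1.46, 0.29), "P": (1.26, 0.22), "PF": (1.10, 0.13)},
    "sampen": {"KX": (1.66, 0.48), "P": (1.42, 0.31), "PF": (1.25, 0.17)},
}


def reported(metric: str, group: str) -> tuple[float, float]:
    """Return the published (mean, sd) for ``metric`` in ``group``."""
    try:
        return REPORTED_SUMMARIES[metric][group]
    except KeyError as exc:
        raise KeyError(f"no reported summary for metric={metric!r}, group={group!r}") from exc
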