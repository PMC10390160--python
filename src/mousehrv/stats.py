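"""Group-level inference: normality screening, t-tests, one-way ANOVA.

Matches the reporting conventions of small-animal HRV studies: per-group
mean +/- SD, Shapiro-Wilk normality screen, omnibus one-way ANOVA across
the three anesthesia groups, and pairwise two-sided t-tests (Welch by
default, since group SDs differ up to four-fold), with graded significance
marks at 0.05 / 0.01 / 0.001 and no multiplicity correction by default
(Holm available behind a flag).

``welch_t_from_summary`` performs the same Welch test from published
(mean, SD, n) triples, so printed group tables can be audited without the
raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "StatTestResult",
    "shapiro_wilk",
    "t_test_independent",
    "welch_t_from_summary",
    "anova_oneway",
    "significance_grade",
    "compare_groups",
    "GroupComparison",
    "GroupComparisonResults",
]

GROUP_LABELS = ("KX", "P", "PF")


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    df: float
    p_value: float
    group_summaries: tuple = field(default_factory=tuple)  # (mean, sd, n) per group

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p value must lie in [0, 1]")


def _summ(x: np.ndarray) -> tuple[float, float, int]:
    return float(np.mean(x)), float(np.std(x, ddof=1)), int(x.size)


def shapiro_wilk(values) -> StatTestResult:
    """Shapiro-Wilk normality test (scipy backend)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above 5000 observations")
    w, p = _stats.shapiro(x)
    return StatTestResult(test="shapiro-wilk", statistic=float(w), df=float(x.size),
                          p_value=float(p), group_summaries=(_summ(x),))


def t_test_independent(g1, g2, equal_var: bool = False) -> StatTestResult:
    """Two-sided independent-samples t-test; Welch by default."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        raise ValueError("zero variance in both groups with equal means")
    res = _stats.ttest_ind(a, b, equal_var=equal_var)
    name = "student-t" if equal_var else "welch-t"
    return StatTestResult(test=name, statistic=float(res.statistic),
                          df=float(res.df), p_value=float(res.pvalue),
                          group_summaries=(_summ(a), _summ(b)))


def welch_t_from_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int) -> StatTestResult:
    """Welch t-test from summary statistics (mean, SD, n) of two groups.

    t = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2) with Welch-Satterthwaite
    degrees of freedom and a two-sided p value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("at least one group must have positive SD")
    res = _stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatTestResult(test="welch-t-summary", statistic=float(res.statistic),
                          df=float(df), p_value=float(res.pvalue),
                          group_summaries=((mean1, sd1, n1), (mean2, sd2, n2)))


def anova_oneway(*groups) -> StatTestResult:
    """One-way ANOVA across three or more groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("one-way ANOVA requires at least 3 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 observations")
    res = _stats.f_oneway(*gs)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    return StatTestResult(test="anova-oneway", statistic=float(res.statistic),
                          df=float(k - 1), p_value=float(res.pvalue),
                          group_summaries=tuple(_summ(g) for g in gs))


def significance_grade(p: float) -> str:
    """Graded marks matching conventional reporting: *** / ** / * / ns."""
    if np.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def compare_groups(table: pd.DataFrame, holm: bool = False,
                   known_metrics: tuple[str, ...] | None = None) -> dict:
    """Per-metric group comparison from a tidy (subject, group, metric, value) table.

    For every metric: per-group mean +/- SD, per-group Shapiro-Wilk screen,
    omnibus one-way ANOVA (three or more groups), and all pairwise Welch
    t-tests with graded significance.  No multiplicity correction unless
    ``holm`` is set.
    """
    required = {"subject", "group", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    groups = sorted(table["group"].unique())
    sizes = table.groupby("group")["subject"].nunique()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 subjects: {small}")
    if len(groups) < 2:
        warnings.warn("single-group table: only summaries produced", stacklevel=2)

    if known_metrics is not None:
        unknown = set(table["metric"].unique()) - set(known_metrics)
        if unknown:
            warnings.warn(f"unrecognized metric names passed through: {sorted(unknown)}",
                          stacklevel=2)

    report: dict = {"groups": groups, "metrics": {}}
    for metric, sub in table.groupby("metric"):
        entry: dict = {"summaries": {}, "shapiro": {}, "anova": None, "pairwise": {}}
        vals = {}
        for g in groups:
            x = sub.loc[sub["group"] == g, "value"].dropna().to_numpy(dtype=float)
            vals[g] = x
            if x.size:
                entry["summaries"][g] = {"mean": float(np.mean(x)),
                                         "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                                         "n": int(x.size)}
            if x.size >= 3:
                try:
                    sw = shapiro_wilk(x)
                    entry["shapiro"][g] = {"W": sw.statistic, "p": sw.p_value}
                except ValueError:
                    entry["shapiro"][g] = None
        usable = [g for g in groups if vals[g].size >= 2]
        if len(usable) >= 3:
            try:
                an = anova_oneway(*[vals[g] for g in usable])
                entry["anova"] = {"F": an.statistic, "df": (len(usable) - 1,
                                  int(sum(vals[g].size for g in usable)) - len(usable)),
                                  "p": an.p_value, "grade": significance_grade(an.p_value)}
            except ValueError as exc:
                entry["anova"] = {"error": str(exc)}
        pair_keys, pair_ps = [], []
        for i, g1 in enumerate(usable):
            for g2 in usable[i + 1:]:
                try:
                    tt = t_test_independent(vals[g1], vals[g2], equal_var=False)
                    entry["pairwise"][f"{g1}_vs_{g2}"] = {
                        "t": tt.statistic, "df": tt.df, "p": tt.p_value,
                        "grade": significance_grade(tt.p_value),
                    }
                    pair_keys.append(f"{g1}_vs_{g2}")
                    pair_ps.append(tt.p_value)
                except ValueError as exc:
                    entry["pairwise"][f"{g1}_vs_{g2}"] = {"error": str(exc)}
        if holm and pair_ps:
            for k, p_adj in zip(pair_keys, _holm(pair_ps)):
                entry["pairwise"][k]["p_holm"] = p_adj
                entry["pairwise"][k]["grade_holm"] = significance_grade(p_adj)
        report["metrics"][metric] = entry
    return report


class GroupComparison:
    """Model-style wrapper around :func:`compare_groups`.

    Built from a tidy DataFrame of per-subject metric values with group
    labels; ``fit()`` runs the full comparison and returns a results object
    with a text ``summary()``.
    """

    def __init__(self, table: pd.DataFrame, holm: bool = False):
        required = {"subject", "group", "metric", "value"}
        if not required.issubset(table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        self.table = table.copy()
        self.holm = holm

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "GroupComparison":
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GroupComparison":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "GroupComparisonResults":
        report = compare_groups(self.table, holm=self.holm)
        return GroupComparisonResults(self, report)


class GroupComparisonResults:
    """Fitted group comparison: per-metric summaries, ANOVA and pairwise tests."""

    def __init__(self, model: GroupComparison, report: dict):
        self.model = model
        self.report = report

    @property
    def metrics(self) -> dict:
        return self.report["metrics"]

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for metric, entry in self.metrics.items():
            for pair, res in entry["pairwise"].items():
                if "error" in res:
                    continue
                rows.append({"metric": metric, "pair": pair, **res})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Group comparison"]
        lines.append("=" * 72)
        for metric, entry in self.metrics.items():
            summ = "  ".join(
                f"{g}: {s['mean']:.3g} +/- {s['sd']:.3g} (n={s['n']})"
                for g, s in entry["summaries"].items()
            )
            lines.append(f"{metric}")
            lines.append(f"  {summ}")
            if entry["anova"] and "F" in entry["anova"]:
                a = entry["anova"]
                lines.append(
                    f"  ANOVA F={a['F']:.3f} df={a['df']} p={a['p']:.4g} {a['grade']}"
                )
            for pair, res in entry["pairwise"].items():
                if "error" in res:
                    lines.append(f"  {pair}: {res['error']}")
                else:
                    lines.append(
                        f"  {pair}: t={res['t']:.3f} df={res['df']:.2f} "
                        f"p={res['p']:.4g} {res['grade']}"
                    )
        return "\n".join(lines)
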