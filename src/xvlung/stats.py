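"""Cohort-level statistics for ventilation and mechanics parameters.

The analysis mirrors standard small-cohort practice: for every parameter a
one-way linear model with a fixed treatment (group) effect is fitted;
estimated marginal means with confidence intervals and Tukey-adjusted
pairwise contrasts summarize group differences. Body weights are compared
with Welch t-tests, each parameter is correlated (Pearson) against
log10-transformed tumor counts, and boxplot five-number summaries use the
median/IQR with 1.5×IQR whiskers.

Missing cells are permitted and handled by pairwise deletion: each
parameter's model drops only the rows missing *that* parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "fit_group_model",
    "two_sample_ttest",
    "correlate_with_tumor_count",
    "boxplot_summary",
    "GROUP_ORDER",
]

GROUP_ORDER = ("control", "week2", "week3")


@dataclass
class GroupComparison:
    """Marginal means and pairwise contrasts for one parameter."""

    parameter: str
    groups: list[str]
    emmeans: dict[str, float]
    emmean_ci: dict[str, tuple[float, float]]
    contrasts: list[dict[str, float | str]] = field(default_factory=list)
    adjustment: str = "tukey"
    inference_available: bool = True

    def to_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for g in self.groups:
            lo, hi = self.emmean_ci[g]
            rows.append(
                {
                    "parameter": self.parameter,
                    "kind": "emmean",
                    "group": g,
                    "estimate": self.emmeans[g],
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "p_adj": math.nan,
                    "method": self.adjustment,
                }
            )
        for c in self.contrasts:
            rows.append(
                {
                    "parameter": self.parameter,
                    "kind": "contrast",
                    "group": c["contrast"],
                    "estimate": c["estimate"],
                    "ci_lo": c["ci_lo"],
                    "ci_hi": c["ci_hi"],
                    "p_adj": c["p_adj"],
                    "method": self.adjustment,
                }
            )
        return rows


@dataclass
class CorrelationResult:
    """Pearson correlation of one parameter against log10 tumor count."""

    parameter: str
    pearson_r: float
    p_value: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not -1.0000001 <= self.pearson_r <= 1.0000001:
            raise ValueError("|pearson_r| must be <= 1")


def _group_arrays(table: pd.DataFrame, parameter: str) -> dict[str, np.ndarray]:
    if parameter not in table.columns:
        raise KeyError(f"parameter {parameter!r} not in table")
    out: dict[str, np.ndarray] = {}
    for g, sub in table.groupby("group", sort=False, observed=True):
        vals = pd.to_numeric(sub[parameter], errors="coerce").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        out[str(g)] = vals
    order = [g for g in GROUP_ORDER if g in out] + [
        g for g in out if g not in GROUP_ORDER
    ]
    return {g: out[g] for g in order}


def fit_group_model(
    table: pd.DataFrame,
    parameter: str,
    adjustment: str = "tukey",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way linear model of ``parameter`` on group indicators.

    In this single-factor design the estimated marginal means equal the
    per-group sample means; their confidence intervals use the pooled
    residual variance from the model. Pairwise contrasts are adjusted with
    Tukey's HSD by default (``adjustment`` one of ``tukey``, ``bonferroni``,
    ``none``); the method used is always reported in the output.

    Rows missing this parameter are dropped for this model only. If the
    residual degrees of freedom are zero, estimates are still returned but
    inference (CIs, p-values) is marked unavailable (NaN).
    """
    if adjustment not in ("tukey", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    groups = _group_arrays(table, parameter)
    empty = [g for g, v in groups.items() if v.size == 0]
    if empty:
        raise ValueError(f"group(s) entirely missing for {parameter!r}: {empty}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    # one-way indicator design: the OLS coefficients are exactly the group
    # sample means and the residual variance pools within-group squares
    emmeans = {g: float(np.mean(v)) for g, v in groups.items()}
    k = len(groups)
    n = sum(v.size for v in groups.values())
    df_resid = n - k
    ss_res = sum(float(np.sum((v - emmeans[g]) ** 2)) for g, v in groups.items())
    mse = ss_res / df_resid if df_resid > 0 else math.nan
    inference = df_resid >= 1 and np.isfinite(mse)

    emmean_ci: dict[str, tuple[float, float]] = {}
    for g, v in groups.items():
        if inference:
            half = sps.t.ppf(1 - alpha / 2, df_resid) * math.sqrt(mse / v.size)
            emmean_ci[g] = (emmeans[g] - half, emmeans[g] + half)
        else:
            emmean_ci[g] = (math.nan, math.nan)

    contrasts = []
    for ga, gb in combinations(groups, 2):
        est = emmeans[gb] - emmeans[ga]
        row: dict[str, float | str] = {"contrast": f"{gb} - {ga}", "estimate": float(est)}
        if inference:
            se = math.sqrt(mse * (1 / groups[ga].size + 1 / groups[gb].size))
            if se == 0:
                p = 1.0 if est == 0 else 0.0
                half = 0.0
            elif adjustment == "tukey":
                q = abs(est) / se * math.sqrt(2)
                p = float(sps.studentized_range.sf(q, k, df_resid))
                q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df_resid))
                half = q_crit / math.sqrt(2) * se
            else:
                t = est / se
                p = 2 * float(sps.t.sf(abs(t), df_resid))
                n_comp = k * (k - 1) // 2
                if adjustment == "bonferroni":
                    p = min(1.0, p * n_comp)
                    t_crit = float(sps.t.ppf(1 - alpha / (2 * n_comp), df_resid))
                else:
                    t_crit = float(sps.t.ppf(1 - alpha / 2, df_resid))
                half = t_crit * se
            row.update(ci_lo=est - half, ci_hi=est + half, p_adj=min(1.0, max(0.0, p)))
        else:
            row.update(ci_lo=math.nan, ci_hi=math.nan, p_adj=math.nan)
        contrasts.append(row)

    return GroupComparison(
        parameter=parameter,
        groups=list(groups),
        emmeans=emmeans,
        emmean_ci=emmean_ci,
        contrasts=contrasts,
        adjustment=adjustment,
        inference_available=inference,
    )


def two_sample_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch (unequal-variance) two-sample t-test → ``(t, df, p)``.

    Swapping the samples negates t and preserves p. Degenerate case policy:
    if both samples have zero variance, p is 1 when the means agree and 0
    when they differ (t is 0 or ±inf accordingly) — the difference is then
    known without sampling error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), float(x.size + y.size - 2), 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlate_with_tumor_count(
    table: pd.DataFrame,
    parameter: str,
    zero_count_policy: str = "exclude",
) -> CorrelationResult:
    """Pearson correlation of ``parameter`` against log10(tumor count).

    ``zero_count_policy`` controls animals with zero tumors (controls):
    ``exclude`` (default) drops them before the log transform; ``log1p``
    keeps them using log10(count + 1). Rows missing the parameter are
    dropped pairwise. Requires >= 3 complete pairs and non-degenerate
    variance in both variables.
    """
    if zero_count_policy not in ("exclude", "log1p"):
        raise ValueError(f"unknown zero_count_policy {zero_count_policy!r}")
    counts = pd.to_numeric(table["tumor_count"], errors="coerce").to_numpy(dtype=float)
    vals = pd.to_numeric(table[parameter], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(counts) & np.isfinite(vals)
    if zero_count_policy == "exclude":
        keep &= counts > 0
        log_counts = np.log10(np.where(counts > 0, counts, 1.0))
    else:
        log_counts = np.log10(counts + 1.0)
    lc, v = log_counts[keep], vals[keep]
    if lc.size < 3:
        raise ValueError("need >= 3 complete (count, parameter) pairs")
    if np.allclose(lc.var(), 0) or np.allclose(v.var(), 0):
        raise ValueError("undefined correlation: zero variance")
    r, p = sps.pearsonr(lc, v)
    return CorrelationResult(parameter=parameter, pearson_r=float(r), p_value=float(p), n_pairs=int(lc.size))


def boxplot_summary(values: np.ndarray) -> dict[str, object]:
    """Median/IQR boxplot summary with 1.5×IQR whiskers.

    Whiskers sit at the most extreme data points inside
    ``[q1 − 1.5·IQR, q3 + 1.5·IQR]``; points beyond are listed as outliers.
    Quantiles use linear interpolation, the same convention as the
    ventilation-heterogeneity IQR.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": [float(o) for o in outliers],
    }
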