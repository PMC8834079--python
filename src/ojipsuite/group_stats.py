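"""Replicate summaries and WT-vs-MT significance testing.

Groups are compared by one-way ANOVA followed by Fisher's least significant
difference (LSD) test at alpha = 0.05: a pair of group means differs
significantly when the omnibus p-value is below alpha *and* the absolute mean
difference exceeds

    LSD = t_(1 - alpha/2, df_within) * sqrt(MSW * (1/n_i + 1/n_j)).

For two groups the ANOVA F equals the square of the pooled-variance t
statistic and the p-values coincide. No multiple-testing correction is
applied across parameters by default; a Benjamini-Hochberg option exists.

A summary-statistics entry point (per-group n, mean, SE) supports comparing
groups for which only published summaries are available; it offers a Welch
variant for unequal variances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicatesError, ValidationError

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize",
    "anova_lsd",
    "anova_lsd_from_summary",
    "compare_tables",
    "format_mean_se",
]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # reported instead of 0 when within-group variance vanishes


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    se: float  # sample SD / sqrt(n)


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one parameter's group comparison."""

    parameter: str
    groups: tuple  # of GroupSummary
    F_statistic: float
    p_value: float
    lsd_threshold: float  # for the first pair of groups
    significant: bool  # p < alpha and |mean diff| > LSD (first pair)
    alpha: float = 0.05


def summarize(values_by_group: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Per-group n, mean and standard error (sample SD / sqrt(n))."""
    out = []
    for label, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise InsufficientReplicatesError(f"group {label!r} has n={vals.size} < 2")
        out.append(GroupSummary(label, int(vals.size), float(np.mean(vals)),
                                float(np.std(vals, ddof=1) / math.sqrt(vals.size))))
    return out


def _lsd(msw: float, n_i: int, n_j: int, df_w: int, alpha: float) -> float:
    tcrit = stats.t.ppf(1 - alpha / 2, df_w)
    return float(tcrit * math.sqrt(msw * (1 / n_i + 1 / n_j)))


def anova_lsd(values_by_group: dict[str, np.ndarray], alpha: float = 0.05,
              parameter: str = "") -> GroupComparison:
    """One-way ANOVA with Fisher-LSD pairwise decision for the first pair.

    With zero within-group variance and unequal means the comparison is
    reported significant with ``p = P_FLOOR`` rather than NaN.
    """
    if len(values_by_group) < 2:
        raise ValidationError("need at least two groups")
    summaries = summarize(values_by_group)
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_w = n_total - k
    msw = sum((a.size - 1) * np.var(a, ddof=1) for a in arrays) / df_w
    means = [a.mean() for a in arrays]

    if msw == 0.0:
        if np.ptp(means) > 0:
            f_stat, p = math.inf, P_FLOOR
        else:
            f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)

    lsd = _lsd(msw, arrays[0].size, arrays[1].size, df_w, alpha) if msw > 0 else 0.0
    diff = abs(means[0] - means[1])
    significant = bool(p < alpha and diff > lsd)
    return GroupComparison(parameter, tuple(summaries), f_stat, p, lsd, significant, alpha)


def anova_lsd_from_summary(summaries: list[GroupSummary], alpha: float = 0.05,
                           parameter: str = "", welch: bool = False) -> GroupComparison:
    """Two-group comparison from published (n, mean, SE) summaries.

    Pooled-variance t by default (matching Fisher LSD); ``welch=True``
    uses the Welch-Satterthwaite correction.
    """
    if len(summaries) != 2:
        raise ValidationError("summary-statistics comparison supports exactly two groups")
    g1, g2 = summaries
    if g1.n < 2 or g2.n < 2:
        raise InsufficientReplicatesError("need n >= 2 in both groups")
    var1, var2 = (g1.se**2) * g1.n, (g2.se**2) * g2.n  # back to sample variances
    diff = abs(g1.mean - g2.mean)
    if welch:
        se2 = var1 / g1.n + var2 / g2.n
        if se2 == 0:
            t_stat, p, df = math.inf, (P_FLOOR if diff > 0 else 1.0), g1.n + g2.n - 2
            lsd = 0.0
        else:
            df = se2**2 / ((var1 / g1.n) ** 2 / (g1.n - 1) + (var2 / g2.n) ** 2 / (g2.n - 1))
            t_stat = diff / math.sqrt(se2)
            p = 2 * stats.t.sf(t_stat, df)
            lsd = stats.t.ppf(1 - alpha / 2, df) * math.sqrt(se2)
    else:
        df = g1.n + g2.n - 2
        msw = ((g1.n - 1) * var1 + (g2.n - 1) * var2) / df
        if msw == 0:
            t_stat, p, lsd = math.inf, (P_FLOOR if diff > 0 else 1.0), 0.0
        else:
            se_diff = math.sqrt(msw * (1 / g1.n + 1 / g2.n))
            t_stat = diff / se_diff
            p = 2 * stats.t.sf(t_stat, df)
            lsd = _lsd(msw, g1.n, g2.n, df, alpha)
    significant = bool(p < alpha and diff > lsd)
    return GroupComparison(parameter, (g1, g2), float(t_stat) ** 2 if np.isfinite(t_stat)
                           else math.inf, float(p), float(lsd), significant, alpha)


def compare_tables(parameter_table: pd.DataFrame, group_col: str = "group",
                   alpha: float = 0.05, fdr: bool = False) -> list[GroupComparison]:
    """One :class:`GroupComparison` per numeric column of a per-replicate
    table. Non-numeric columns are skipped with a log entry; ``fdr=True``
    applies Benjamini-Hochberg across parameters (off by default)."""
    if group_col not in parameter_table.columns:
        raise ValidationError(f"missing group column {group_col!r}")
    groups = parameter_table[group_col].astype(str)
    if groups.nunique() < 2:
        raise ValidationError("need at least two groups in the table")
    comparisons = []
    for col in parameter_table.columns:
        if col == group_col:
            continue
        series = parameter_table[col]
        if not pd.api.types.is_numeric_dtype(series) or pd.api.types.is_bool_dtype(series):
            logger.info("skipping non-numeric column %r", col)
            continue
        by_group = {g: series[groups == g].to_numpy(dtype=float)
                    for g in pd.unique(groups)}
        if any(np.isnan(v).any() for v in by_group.values()):
            logger.info("skipping column %r: missing values", col)
            continue
        comparisons.append(anova_lsd(by_group, alpha, parameter=str(col)))
    if fdr and comparisons:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests([c.p_value for c in comparisons],
                                            alpha=alpha, method="fdr_bh")
        comparisons = [
            GroupComparison(c.parameter, c.groups, c.F_statistic, float(pa),
                            c.lsd_threshold, bool(r and c.significant), alpha)
            for c, pa, r in zip(comparisons, p_adj, reject)
        ]
    return comparisons


def format_mean_se(comparisons: list[GroupComparison], decimals: int = 3) -> pd.DataFrame:
    """Render comparisons as a table of ``mean ± SE`` strings with a ``**``
    marker on significant parameters (second group), mirroring standard
    physiology tables."""
    rows = []
    for c in comparisons:
        row = {"parameter": c.parameter, "F": c.F_statistic, "p_value": c.p_value,
               "significant": c.significant}
        for i, g in enumerate(c.groups):
            marker = " **" if (c.significant and i > 0) else ""
            row[g.label] = f"{g.mean:.{decimals}f} ± {g.se:.{decimals}f}{marker}"
        rows.append(row)
    return pd.DataFrame(rows)
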