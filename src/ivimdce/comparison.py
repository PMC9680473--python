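"""Benign-vs-malignant group comparison with normality-driven test selection.

Each parameter is compared between groups following the standard clinical
recipe: Shapiro-Wilk normality per group; if both groups are consistent with
normality (alpha = 0.05), an independent-samples t-test (pooled or Welch,
chosen by Levene's test with mean centring) and a mean +/- SD presentation;
otherwise a Mann-Whitney U test and a median (Q1, Q3) presentation.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonRow",
    "assess_normality",
    "assess_variance_homogeneity",
    "compare_groups",
    "compare_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonRow:
    parameter: str
    benign_summary: str
    malignant_summary: str
    test_used: str          # "t_test" or "mann_whitney"
    statistic: float
    p_value: float
    normal_p: tuple[float, float]
    levene_p: float | None


def assess_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; a constant sample is treated as
    non-normal (statistic nan, p 0)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0.0:
        return float("nan"), 0.0
    stat, p = stats.shapiro(v)
    return float(stat), float(p)


def assess_variance_homogeneity(a, b) -> tuple[float, float]:
    """Levene's test with mean centring."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Levene's test needs n >= 2 per group")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 0.0, 1.0
    stat, p = stats.levene(a, b, center="mean")
    return float(stat), float(p)


def _fmt_normal(v: np.ndarray) -> str:
    return f"{np.mean(v):.2f} ± {np.std(v, ddof=1):.2f}"


def _fmt_skew(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear-interpolation quantiles
    return f"{med:.2f} ({q1:.2f},{q3:.2f})"


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, method="exact")
    else:
        res = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def compare_groups(a, b, parameter: str = "param") -> ComparisonRow:
    """Compare one parameter between two groups (a = benign, b = malignant).

    The branch taken is a pure function of the two Shapiro-Wilk p-values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations to compare")

    _, p_norm_a = assess_normality(a)
    _, p_norm_b = assess_normality(b)
    both_normal = (p_norm_a > ALPHA) and (p_norm_b > ALPHA)

    if both_normal:
        _, p_lev = assess_variance_homogeneity(a, b)
        stat, p = stats.ttest_ind(a, b, equal_var=p_lev >= ALPHA)
        return ComparisonRow(parameter=parameter,
                             benign_summary=_fmt_normal(a),
                             malignant_summary=_fmt_normal(b),
                             test_used="t_test", statistic=float(stat),
                             p_value=float(p),
                             normal_p=(p_norm_a, p_norm_b), levene_p=float(p_lev))
    stat, p = _mann_whitney(a, b)
    return ComparisonRow(parameter=parameter,
                         benign_summary=_fmt_skew(a),
                         malignant_summary=_fmt_skew(b),
                         test_used="mann_whitney", statistic=stat, p_value=p,
                         normal_p=(p_norm_a, p_norm_b), levene_p=None)


def compare_table(df: pd.DataFrame, parameters: list[str],
                  label_col: str = "group") -> pd.DataFrame:
    """Per-parameter comparison table for a lesion DataFrame with a
    benign/malignant label column."""
    benign = df[df[label_col] == "benign"]
    malignant = df[df[label_col] == "malignant"]
    rows = []
    for p in parameters:
        row = compare_groups(benign[p].to_numpy(), malignant[p].to_numpy(), p)
        rows.append({
            "parameter": p,
            "benign": row.benign_summary,
            "malignant": row.malignant_summary,
            "test": row.test_used,
            "p_value": row.p_value,
        })
    return pd.DataFrame(rows)
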