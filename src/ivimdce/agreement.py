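"""Inter-reader agreement (ICC) and reproducibility screening.

Agreement between the two readers' ROI measurements is quantified by the
intraclass correlation coefficient ICC(2,1): two-way random effects,
absolute agreement, single measurement.  Parameters whose ICC falls below a
retention cutoff are removed before any downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ICCReport", "icc_two_way_single", "icc_table", "screen_parameters"]


@dataclass(frozen=True)
class ICCReport:
    parameter: str
    icc: float
    retained: bool = True
    degenerate: bool = False


def _as_matrix(table) -> np.ndarray:
    m = np.asarray(table, dtype=float)
    if m.ndim != 2:
        raise ValueError("reader table must be 2-D (lesions x readers)")
    n, k = m.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 lesions")
    if k != 2:
        raise ValueError("expected exactly two readers")
    if not np.all(np.isfinite(m)):
        raise ValueError("reader table contains non-finite values")
    return m


def icc_two_way_single(table) -> tuple[float, bool]:
    """ICC(2,1) from the two-way ANOVA mean squares of a lesions-x-readers
    matrix.  Returns ``(icc, degenerate)``; a table with zero total variance
    has undefined ICC and is reported as (1.0, True).

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = _as_matrix(table)
    n, k = m.shape
    grand = m.mean()
    if np.allclose(m, grand):
        return 1.0, True
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0, True
    return float((msr - mse) / denom), False


def icc_table(reader_table: pd.DataFrame, cutoff: float = 0.75) -> list[ICCReport]:
    """Per-parameter ICC reports from a long reader table
    (lesion_id, reader, parameter, value)."""
    required = {"lesion_id", "reader", "parameter", "value"}
    missing = required - set(reader_table.columns)
    if missing:
        raise ValueError(f"reader table missing columns: {sorted(missing)}")
    reports = []
    for parameter, sub in reader_table.groupby("parameter", sort=False):
        wide = sub.pivot(index="lesion_id", columns="reader", values="value")
        if wide.isna().any().any():
            raise ValueError(f"both readers must measure every lesion ({parameter})")
        icc, degenerate = icc_two_way_single(wide.to_numpy())
        reports.append(ICCReport(parameter=str(parameter), icc=icc,
                                 retained=icc >= cutoff, degenerate=degenerate))
    return reports


def screen_parameters(reports: list[ICCReport], cutoff: float = 0.75,
                      log: list[str] | None = None) -> list[str]:
    """Return the parameters with ICC >= cutoff; removals are logged."""
    if not reports:
        raise ValueError("no ICC reports to screen")
    retained = []
    for r in reports:
        if r.icc >= cutoff:
            retained.append(r.parameter)
        elif log is not None:
            log.append(f"parameter {r.parameter} removed (ICC={r.icc:.3f} < {cutoff})")
    return retained
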