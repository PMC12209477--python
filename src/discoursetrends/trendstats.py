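"""Temporal trend and correlation statistics.

Trend estimation is ordinary least squares on the model
``Y_t = beta0 + beta1 * X_t + eps_t`` with ``X_t`` the 0-based time-unit
ordinal, so ``beta1`` is the change per time unit (per quarter for quarterly
series).  Association between two series uses the Pearson product-moment
correlation.  Both tests report classical two-sided p-values from the t
distribution with n - 2 degrees of freedom; no multiple-testing correction
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TrendResult",
    "CorrelationResult",
    "AlignedSeries",
    "ols_trend",
    "pearson_corr",
    "align_series",
    "aggregate_yearly",
    "format_p",
    "significance_report",
]


@dataclass
class TrendResult:
    beta0: float
    beta1: float
    r_squared: float
    p_value: float
    n: int
    resid_sd: float


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class AlignedSeries:
    """Two series aligned on a common time index, missing pairs dropped."""

    time_index: list
    x: np.ndarray
    y: np.ndarray
    aggregation: str = "none"  # "none" | "yearly_mean"
    n_dropped: int = 0


def ols_trend(y: Sequence[float]) -> TrendResult:
    """Least-squares linear trend of ``y`` against its 0-based index.

    A constant series is a defined degenerate case: slope 0, R-squared 0,
    p-value 1.  NaN entries are dropped with the index preserved.
    """
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y), dtype=float)
    keep = ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(y) == 0:
        return TrendResult(beta0=float(y[0]), beta1=0.0, r_squared=0.0, p_value=1.0, n=n, resid_sd=0.0)
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    sse = float(np.sum((y - fitted) ** 2))
    resid_sd = math.sqrt(sse / (n - 2))
    return TrendResult(
        beta0=float(res.intercept),
        beta1=float(res.slope),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        resid_sd=resid_sd,
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t test.

    Perfect correlation reports a p-value at the machine floor rather than
    exactly zero.  Zero variance in either series is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue)
    if abs(r) >= 1.0:
        p = max(p, np.finfo(float).tiny)
    return CorrelationResult(r=r, r_squared=r * r, p_value=p, n=n)


def align_series(
    time_index: Sequence, x: Sequence[float], y: Sequence[float], aggregation: str = "none"
) -> AlignedSeries:
    """Pair two series on a shared time index, dropping missing pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(time_index) == len(x) == len(y)):
        raise ValueError("time index and series lengths differ")
    keep = ~(np.isnan(x) | np.isnan(y))
    return AlignedSeries(
        time_index=[t for t, k in zip(time_index, keep) if k],
        x=x[keep],
        y=y[keep],
        aggregation=aggregation,
        n_dropped=int((~keep).sum()),
    )


def aggregate_yearly(quarterly: Sequence[float], quarters_per_year: int = 4) -> np.ndarray:
    """Arithmetic mean of each complete calendar year's quarterly values.

    The series must start at the first quarter of a year; a trailing
    incomplete year is dropped.
    """
    q = np.asarray(quarterly, dtype=float)
    n_years = len(q) // quarters_per_year
    if n_years == 0:
        raise ValueError("no complete year in series")
    trimmed = q[: n_years * quarters_per_year]
    return trimmed.reshape(n_years, quarters_per_year).mean(axis=1)


def format_p(p: float) -> str:
    """Render a p-value the way results tables print it: ``<.001`` below
    0.001, otherwise three decimals without a leading zero."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")


def significance_report(rows: Iterable[tuple[str, TrendResult | CorrelationResult]]):
    """Tidy table of regression/correlation results.

    One row per (series name, result): trend rows carry (beta0, beta1,
    R-squared); correlation rows carry (r, r-squared); both carry a formatted
    p-value and n.
    """
    import pandas as pd

    records = []
    for name, res in rows:
        if isinstance(res, TrendResult):
            records.append(
                {
                    "series": name,
                    "statistic": "trend",
                    "beta0": res.beta0,
                    "beta1": res.beta1,
                    "r": np.nan,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "p_formatted": format_p(res.p_value),
                    "n": res.n,
                }
            )
        elif isinstance(res, CorrelationResult):
            records.append(
                {
                    "series": name,
                    "statistic": "correlation",
                    "beta0": np.nan,
                    "beta1": np.nan,
                    "r": res.r,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "p_formatted": format_p(res.p_value),
                    "n": res.n,
                }
            )
        else:
            raise TypeError(f"unsupported result type {type(res)!r} for {name!r}")
    return pd.DataFrame.from_records(records)
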