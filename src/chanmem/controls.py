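"""Randomization controls and between-group statistics.

Shuffling a series destroys its temporal ordering while preserving the
value distribution, so any long-range memory measured on the shuffled
series is estimator baseline, not signal.  Group comparisons use the
Mann-Whitney U test (exact enumeration at the small per-condition patch
counts typical of patch-clamp studies, 3-7 patches per condition; normal
approximation with tie correction for larger samples), and exponents are
aggregated as medians per membrane type pooling all voltages and patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, shapiro

from .longmemory import FluctuationResult

__all__ = [
    "GroupComparison",
    "shuffle_series",
    "compare_groups",
    "aggregate_exponents",
    "shapiro_normality",
]

ALPHA_S = 0.05  # package-wide significance level
_EXACT_MAX_COMBINED = 20


def shuffle_series(series: np.ndarray, seed: int) -> np.ndarray:
    """Uniform random permutation of the series (multiset preserved)."""
    x = np.asarray(series)
    if x.size == 0:
        raise ValueError("cannot shuffle an empty series")
    return np.random.default_rng(seed).permutation(x)


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of two independent groups."""

    label_a: str
    label_b: str
    u_stat: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    significant: bool
    method: str  # 'exact' or 'asymptotic'
    alpha: float = ALPHA_S


def _u_statistic(ranks: np.ndarray, idx_a: Sequence[int], n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> tuple:
    """Two-sided exact Mann-Whitney p by enumerating all label
    assignments; ties handled through midranks."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n = a.size, pooled.size
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    u_lo = min(u_obs, a.size * b.size - u_obs)
    u_hi = a.size * b.size - u_lo
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        u = _u_statistic(ranks, idx, n_a)
        if u <= u_lo + 1e-9 or u >= u_hi - 1e-9:
            count += 1
        total += 1
    return u_obs, min(count / total, 1.0)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = ALPHA_S,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Exact enumeration of all label assignments for combined n <= 20
    (ties via midranks), normal approximation with tie correction
    otherwise.  All values tied across both groups yields p = 1 with a
    warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        u = a.size * b.size / 2.0
        return GroupComparison(label_a, label_b, u, 1.0,
                               float(np.median(a)), float(np.median(b)),
                               a.size, b.size, False, "degenerate", alpha)
    if a.size + b.size <= _EXACT_MAX_COMBINED:
        u, p = _exact_mw_p(a, b)
        method = "exact"
    else:
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return GroupComparison(label_a, label_b, u, p,
                           float(np.median(a)), float(np.median(b)),
                           a.size, b.size, bool(p < alpha), method, alpha)


def _box_outliers(values: np.ndarray) -> int:
    """Points beyond the 1.5 IQR whisker range (box-plot convention)."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return int(np.sum((values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)))


def aggregate_exponents(
    records: Iterable[dict],
) -> pd.DataFrame:
    """Median exponent per (membrane, method, signal_variant) cell.

    ``records`` are dicts with keys ``membrane``, ``method``,
    ``signal_variant``, ``exponent`` (e.g. serialized
    :class:`FluctuationResult` rows); all voltages and patches within a
    cell are pooled.  Empty cells are simply absent from the table.
    """
    rows = []
    for rec in records:
        if isinstance(rec, FluctuationResult):
            raise TypeError("pass dict records carrying membrane/method/"
                            "signal_variant tags, not bare FluctuationResult")
        rows.append({
            "membrane": rec["membrane"],
            "method": rec["method"],
            "signal_variant": rec.get("signal_variant", "all"),
            "exponent": float(rec["exponent"]),
        })
    if not rows:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["membrane", "method", "signal_variant"])["exponent"]
        .agg(median="median", n="size",
             outliers=lambda v: _box_outliers(np.asarray(v)))
        .reset_index()
    )
    return out


def shapiro_normality(values: Sequence[float]) -> tuple:
    """Pass-through Shapiro-Wilk normality screen; returns (W, p)."""
    res = shapiro(np.asarray(values, dtype=float))
    return float(res.statistic), float(res.pvalue)
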