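"""Long-range correlation exponents: rescaled-range (R/S) and DFA.

Both estimators tile the series into non-overlapping segments of
power-of-two length s, compute a per-segment fluctuation statistic, and
read the scaling exponent off an unweighted least-squares line through
(log2 s, log2 statistic).  R/S rescales the range of the cumulative
deviate by the segment standard deviation (Hurst's original procedure);
DFA removes a per-segment linear trend from the profile (order-1
detrending) and averages the residual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ScalePolicy",
    "RS_SCALES", "DFA_SCALES", "MFDFA_SCALES",
    "FluctuationResult",
    "build_scale_grid",
    "profile",
    "rs_hurst",
    "dfa",
    "chunk_series",
    "N_DWELL_ALL", "N_DWELL_SINGLE", "N_CURRENT", "N_MFDFA",
]

# standard analysis series lengths: dwell-time series of all states,
# open-only / closed-only dwell series, current series, and the longer
# current series required for multifractal analysis
N_DWELL_ALL = 2**12
N_DWELL_SINGLE = 2**11
N_CURRENT = 2**13
N_MFDFA = 2**15


@dataclass(frozen=True)
class ScalePolicy:
    """Power-of-two segment lengths s = 2^min_exp ... 2^floor(log2(N/max_divisor)).

    Short segments bias the rescaled range toward 0.5; long segments leave
    too few per scale for a stable average.  Each estimator carries its own
    default lower cutoff (R/S 2^5, DFA 2^3, MFDFA 2^4), calibrated on exact
    fractional Gaussian noise of known Hurst index.
    """

    min_exp: int = 3
    max_divisor: int = 4

    def grid(self, n: int) -> np.ndarray:
        max_exp = int(np.floor(np.log2(n / self.max_divisor)))
        if max_exp < self.min_exp + 1:
            raise ValueError(
                f"series of length {n} too short for scales "
                f"2^{self.min_exp}..2^{max_exp}"
            )
        return 2 ** np.arange(self.min_exp, max_exp + 1)


RS_SCALES = ScalePolicy(min_exp=5)
DFA_SCALES = ScalePolicy(min_exp=3)
MFDFA_SCALES = ScalePolicy(min_exp=4)


def build_scale_grid(
    n: int, policy: Optional[ScalePolicy] = None,
    default: ScalePolicy = DFA_SCALES,
) -> np.ndarray:
    return (policy or default).grid(n)


@dataclass(frozen=True)
class FluctuationResult:
    """Fitted scaling law of a fluctuation statistic.

    ``exponent`` is H for R/S or alpha for DFA; ``statistic[i]`` is
    <R/S>(s) or f(s) at ``scales[i]``; ``intercept`` is log2(c) of the
    fitted line; ``r2`` the coefficient of determination of the log-log
    fit.
    """

    method: str
    exponent: float
    intercept: float
    scales: np.ndarray
    statistic: np.ndarray
    r2: float
    series_length: int
    meta: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent):
            raise ValueError("exponent must be finite")
        if np.any(np.asarray(self.statistic) <= 0):
            raise ValueError("fluctuation statistic must be positive at every scale")


def _loglog_fit(scales: np.ndarray, stat: np.ndarray) -> tuple:
    x = np.log2(scales.astype(float))
    y = np.log2(stat)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss if ss > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def _validate_series(series: np.ndarray, min_len: int = 2**7) -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"series must have at least {min_len} samples")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no fluctuations to analyze")
    return x


def _segment(x: np.ndarray, s: int) -> np.ndarray:
    """Non-overlapping segments of length s tiled from the start; the tail
    shorter than s is ignored."""
    m = x.size // s
    return x[: m * s].reshape(m, s)


def rs_hurst(
    series: np.ndarray, scale_policy: Optional[ScalePolicy] = None,
) -> FluctuationResult:
    """Hurst exponent by rescaled-range analysis.

    Per segment: subtract the segment mean, cumulate, take the range
    R = max - min of the cumulative deviate and rescale by the segment
    standard deviation S (population normalization).  H is the slope of
    log<R/S> vs log s.  Zero-variance segments are dropped with a warning;
    a scale where all segments are degenerate is dropped.
    """
    x = _validate_series(series)
    scales = build_scale_grid(x.size, scale_policy, default=RS_SCALES)
    stats, kept = [], []
    dropped_segments = 0
    for s in scales:
        seg = _segment(x, s)
        dev = seg - seg.mean(axis=1, keepdims=True)
        cum = np.cumsum(dev, axis=1)
        r = cum.max(axis=1) - cum.min(axis=1)
        sd = seg.std(axis=1)  # population (1/s) normalization
        ok = sd > 0
        if not ok.all():
            dropped_segments += int((~ok).sum())
        if not ok.any():
            continue
        stats.append(np.mean(r[ok] / sd[ok]))
        kept.append(s)
    if dropped_segments:
        warnings.warn(f"dropped {dropped_segments} zero-variance segments in R/S",
                      stacklevel=2)
    if len(kept) < 2:
        raise ValueError("fewer than two usable scales for the R/S fit")
    kept = np.array(kept)
    stats = np.array(stats)
    h, intercept, r2 = _loglog_fit(kept, stats)
    return FluctuationResult(method="RS", exponent=h, intercept=intercept,
                             scales=kept, statistic=stats, r2=r2,
                             series_length=x.size,
                             meta={"dropped_segments": dropped_segments})


def profile(series: np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-subtracted series (the DFA profile)."""
    x = np.asarray(series, dtype=float)
    return np.cumsum(x - x.mean())


def _linear_detrend_variance(seg: np.ndarray) -> np.ndarray:
    """Residual variance of a per-row linear least-squares fit.

    Closed-form regression on the common abscissa t = 0..s-1, vectorized
    over segments (rows).
    """
    m, s = seg.shape
    t = np.arange(s, dtype=float)
    t_mean = t.mean()
    t_var = np.mean(t**2) - t_mean**2
    y_mean = seg.mean(axis=1)
    cov = seg @ t / s - y_mean * t_mean
    slope = cov / t_var
    resid = seg - (y_mean[:, None] + slope[:, None] * (t - t_mean))
    return np.mean(resid**2, axis=1)


def segment_variances(y: np.ndarray, s: int, two_sided: bool = False) -> np.ndarray:
    """Per-segment detrended variances F^2(s, v) of a profile.

    ``two_sided`` additionally tiles segments from the series end (2 n_s
    segments in total), the convention used by the multifractal analysis.
    """
    f2 = _linear_detrend_variance(_segment(y, s))
    if two_sided:
        m = y.size // s
        f2_back = _linear_detrend_variance(y[y.size - m * s:].reshape(m, s))
        f2 = np.concatenate([f2, f2_back])
    return f2


def dfa(
    series: np.ndarray,
    detrend_order: int = 1,
    scale_policy: Optional[ScalePolicy] = None,
) -> FluctuationResult:
    """Scaling exponent alpha by order-1 detrended fluctuation analysis.

    The profile (cumulative mean-subtracted sum) is tiled into segments of
    length s; each segment is detrended by a linear least-squares fit; the
    fluctuation function f(s) is the square root of the mean residual
    variance; alpha is the slope of log f(s) vs log s.
    """
    if detrend_order != 1:
        raise NotImplementedError("only order-1 (linear) detrending is supported")
    x = _validate_series(series)
    y = profile(x)
    scales = build_scale_grid(x.size, scale_policy, default=DFA_SCALES)
    stats = np.array([np.sqrt(np.mean(segment_variances(y, s))) for s in scales])
    ok = stats > 0
    if not ok.all():
        warnings.warn("dropped scales with zero fluctuation in DFA", stacklevel=2)
    if ok.sum() < 2:
        raise ValueError("fewer than two usable scales for the DFA fit")
    alpha, intercept, r2 = _loglog_fit(scales[ok], stats[ok])
    return FluctuationResult(method="DFA", exponent=alpha, intercept=intercept,
                             scales=scales[ok], statistic=stats[ok], r2=r2,
                             series_length=x.size, meta={"order": detrend_order})


def chunk_series(series: np.ndarray, target_length: int) -> list:
    """Split into floor(N/target) non-overlapping chunks from the start.

    The remainder is discarded; analyses on standard lengths (2^11..2^15)
    use this to cut long recordings into independently analyzed subseries.
    """
    x = np.asarray(series)
    if x.size < target_length:
        raise ValueError(
            f"series of length {x.size} is shorter than the requested "
            f"chunk length {target_length}"
        )
    m = x.size // target_length
    return [x[i * target_length:(i + 1) * target_length] for i in range(m)]
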