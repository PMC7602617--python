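"""Trace idealization via the threshold-current (TC) algorithm.

A noisy two-level current trace is reduced to a binary open/closed state
sequence.  The discriminating current is found from the kernel density
estimate of the current amplitudes: on log-log axes the inner flanks of the
two density modes follow approximate power laws, and the TC is the current
at which the two fitted power laws intersect.  Open probability and
Boltzmann activation-curve fitting live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks

from .core import CurrentTrace, StateSequence

__all__ = [
    "CurrentPDF",
    "ThresholdResult",
    "ActivationFit",
    "estimate_current_pdf",
    "detect_threshold",
    "idealize_trace",
    "open_probability",
    "fit_activation_curve",
]

_GRID_POINTS = 512
_MIN_FIT_POINTS = 5


@dataclass(frozen=True)
class CurrentPDF:
    """Kernel density estimate of the current amplitude distribution."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold current with the two flank power-law fits behind it."""

    tc: float
    left_fit: tuple  # (slope, intercept) in log10 space
    right_fit: tuple
    left_range: tuple  # current interval used for the fit (pA)
    right_range: tuple
    diagnostics: dict
    sign: float = 1.0  # +1 if open level > closed level in the raw trace

    @property
    def modes(self) -> tuple:
        return self.diagnostics["mode_closed"], self.diagnostics["mode_open"]


@dataclass(frozen=True)
class ActivationFit:
    """Boltzmann fit p(U) = p_max / (1 + exp(-(U - v_half)/slope_k))."""

    v_half: float
    slope_k: float
    p_max: float
    residuals: np.ndarray
    flagged: bool = False

    def predict(self, voltage: np.ndarray) -> np.ndarray:
        voltage = np.asarray(voltage, dtype=float)
        return self.p_max / (1.0 + np.exp(-(voltage - self.v_half) / self.slope_k))


def _epanechnikov_bandwidth(x: np.ndarray) -> float:
    # Silverman-type rule with the Epanechnikov-optimal constant 2.345
    n = x.size
    sd = x.std()
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 2.345 * scale * n ** (-0.2)


def estimate_current_pdf(
    trace: CurrentTrace, bandwidth: Optional[float] = None,
) -> CurrentPDF:
    """Epanechnikov-kernel density of the current values on a 512-point grid.

    The kernel is evaluated by binned convolution: the samples are
    histogrammed onto a fine grid and convolved with the Epanechnikov
    kernel, which is exact up to the grid resolution and fast for long
    traces.  Bandwidth defaults to a Silverman-type rule.
    """
    x = trace.samples
    if x.size < 1000:
        warnings.warn("fewer than 1000 samples; density estimate may be unstable",
                      stacklevel=2)
    if x.std() == 0:
        raise ValueError("zero-variance trace: density is degenerate")
    h = float(bandwidth) if bandwidth is not None else _epanechnikov_bandwidth(x)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    lo, hi = x.min() - h, x.max() + h
    grid = np.linspace(lo, hi, _GRID_POINTS)
    step = grid[1] - grid[0]
    counts, edges = np.histogram(x, bins=_GRID_POINTS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # Epanechnikov kernel K(u) = 0.75(1-u^2) on |u|<=1, evaluated on the grid
    half = int(np.ceil(h / step))
    u = np.arange(-half, half + 1) * step / h
    kernel = np.clip(0.75 * (1.0 - u**2), 0.0, None) / h
    density = np.convolve(counts / x.size, kernel, mode="same")
    # interpolate from bin centers onto the reporting grid
    density = np.interp(grid, centers, density)
    norm = np.trapezoid(density, grid)
    return CurrentPDF(grid=grid, density=density / norm, bandwidth=h)


def _find_two_modes(pdf: CurrentPDF) -> tuple:
    d = pdf.density
    prominence = 0.05 * d.max()
    peaks, _ = find_peaks(d, prominence=prominence)
    if peaks.size < 2:
        raise ValueError("density is not bimodal: threshold detection needs two modes")
    # keep the two most prominent peaks
    order = np.argsort(d[peaks])[::-1][:2]
    i, j = sorted(peaks[order])
    return int(i), int(j)


def _best_flank_fit(
    log_offset: np.ndarray, log_density: np.ndarray, min_points: int,
) -> tuple:
    """Slide windows of >= min_points over the flank and keep the fit with
    maximal R^2 among windows with negative slope (decaying flank)."""
    n = log_offset.size
    best = None
    for width in range(min_points, n + 1):
        for start in range(0, n - width + 1):
            xs = log_offset[start:start + width]
            ys = log_density[start:start + width]
            slope, intercept = np.polyfit(xs, ys, 1)
            if slope >= 0:
                continue
            resid = ys - (slope * xs + intercept)
            ss_tot = np.sum((ys - ys.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
            if best is None or r2 > best[0]:
                best = (r2, slope, intercept, start, start + width)
    if best is None:
        raise ValueError("no decaying power-law window found on the flank")
    return best


def detect_threshold(
    pdf: CurrentPDF,
    search_intervals: Optional[Sequence] = None,
) -> ThresholdResult:
    """Threshold current from intersecting power-law fits between the modes.

    On each inner flank of the bimodal density, log10(density) is regressed
    on log10(|current - mode|) over the sliding window that maximizes the
    fit R^2 (windows of >= 5 grid points, decaying slopes).  The TC is the
    current between the modes where the two fitted power laws cross.
    """
    i_lo, i_hi = _find_two_modes(pdf)
    grid, dens = pdf.grid, pdf.density
    m_lo, m_hi = grid[i_lo], grid[i_hi]
    valley = i_lo + int(np.argmin(dens[i_lo:i_hi + 1]))

    # inner flanks: strictly between each mode and the valley floor
    def flank(idx_from: int, idx_to: int, mode: float) -> tuple:
        sel = np.arange(min(idx_from, idx_to) + 1, max(idx_from, idx_to))
        offs = np.abs(grid[sel] - mode)
        ok = (offs > 0) & (dens[sel] > 0)
        sel, offs = sel[ok], offs[ok]
        if sel.size < _MIN_FIT_POINTS:
            raise ValueError("too few grid points between mode and valley")
        return sel, np.log10(offs), np.log10(dens[sel])

    if search_intervals is not None:
        lo_rng, hi_rng = search_intervals
        sel_l = np.where((grid >= lo_rng[0]) & (grid <= lo_rng[1]) & (dens > 0)
                         & (grid > m_lo))[0]
        sel_r = np.where((grid >= hi_rng[0]) & (grid <= hi_rng[1]) & (dens > 0)
                         & (grid < m_hi))[0]
        if sel_l.size < _MIN_FIT_POINTS or sel_r.size < _MIN_FIT_POINTS:
            raise ValueError("search interval spans fewer than 5 usable grid points")
        fits = []
        for sel, mode in ((sel_l, m_lo), (sel_r, m_hi)):
            xs = np.log10(np.abs(grid[sel] - mode))
            ys = np.log10(dens[sel])
            slope, intercept = np.polyfit(xs, ys, 1)
            resid = ys - (slope * xs + intercept)
            ss = np.sum((ys - ys.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss if ss > 0 else 0.0
            fits.append((r2, slope, intercept, sel[0], sel[-1] + 1))
        (r2_l, b_l, a_l, s_l, e_l), (r2_r, b_r, a_r, s_r, e_r) = fits
        rng_l = (grid[s_l], grid[e_l - 1])
        rng_r = (grid[s_r], grid[e_r - 1])
    else:
        sel_l, lx, ly = flank(i_lo, valley, m_lo)
        sel_r, rx, ry = flank(valley, i_hi, m_hi)
        r2_l, b_l, a_l, s_l, e_l = _best_flank_fit(lx, ly, _MIN_FIT_POINTS)
        r2_r, b_r, a_r, s_r, e_r = _best_flank_fit(rx, ry, _MIN_FIT_POINTS)
        rng_l = (grid[sel_l[s_l]], grid[sel_l[e_l - 1]])
        rng_r = (grid[sel_r[s_r]], grid[sel_r[e_r - 1]])

    def gap(c: float) -> float:
        return (a_l + b_l * np.log10(c - m_lo)) - (a_r + b_r * np.log10(m_hi - c))

    eps = 1e-6 * (m_hi - m_lo)
    lo_b, hi_b = m_lo + eps, m_hi - eps
    try:
        tc = brentq(gap, lo_b, hi_b)
    except ValueError as exc:
        raise ValueError(
            "power-law fits do not intersect between the modes "
            f"(modes at {m_lo:.3g}/{m_hi:.3g} pA, "
            f"flank R^2 {r2_l:.3f}/{r2_r:.3f})"
        ) from exc
    return ThresholdResult(
        tc=float(tc),
        left_fit=(float(b_l), float(a_l)),
        right_fit=(float(b_r), float(a_r)),
        left_range=rng_l,
        right_range=rng_r,
        diagnostics={
            "mode_closed": float(m_lo),
            "mode_open": float(m_hi),
            "r2_left": float(r2_l),
            "r2_right": float(r2_r),
            "bandwidth": float(pdf.bandwidth),
        },
    )


def infer_sign(pdf: CurrentPDF, open_fraction_hint: Optional[float] = None) -> float:
    """Sign convention: +1 means the conducting level is the larger current.

    At negative potentials single-channel currents are negative; the
    pipeline rectifies using the sign of (open level - closed level).  With
    only a bimodal density the open mode cannot be told from the closed one
    without extra information; by default the mode farther from zero is
    taken as the conducting level (the open channel carries the larger
    |current|), which ``open_fraction_hint`` can override.
    """
    i_lo, i_hi = _find_two_modes(pdf)
    m_lo, m_hi = pdf.grid[i_lo], pdf.grid[i_hi]
    if open_fraction_hint is not None:
        # weight under each mode decides which one is 'open'
        valley = 0.5 * (m_lo + m_hi)
        w_hi = np.trapezoid(pdf.density[pdf.grid >= valley], pdf.grid[pdf.grid >= valley])
        open_is_high = (w_hi >= 0.5) == (open_fraction_hint >= 0.5)
        return 1.0 if open_is_high else -1.0
    return 1.0 if abs(m_hi) >= abs(m_lo) else -1.0


def idealize_trace(trace: CurrentTrace, tc: float, sign: float = 1.0) -> StateSequence:
    """Binary idealization: open iff ``sign * current > sign * tc``.

    ``sign=+1`` when the conducting level lies above the threshold (outward
    current), ``sign=-1`` for the mirrored convention at negative
    potentials.
    """
    x = trace.samples
    if not (x.min() <= tc <= x.max()):
        raise ValueError("threshold lies outside the observed current range")
    if sign not in (1.0, -1.0, 1, -1):
        raise ValueError("sign must be +1 or -1")
    return StateSequence(states=sign * x > sign * tc, dt=trace.dt)


def open_probability(states: StateSequence) -> float:
    """Fraction of samples in the conducting state, in [0, 1]."""
    return float(np.mean(states.states))


def _boltzmann(u, v_half, slope_k, p_max):
    return p_max / (1.0 + np.exp(-(u - v_half) / slope_k))


def fit_activation_curve(
    points: Sequence, p_max: Optional[float] = 1.0,
) -> ActivationFit:
    """Least-squares Boltzmann fit of open probability vs voltage.

    ``points`` is a sequence of (voltage_mV, p_open).  ``p_max`` is fixed
    at 1.0 by default; pass ``None`` to fit it as a third parameter.  A
    non-monotone point set is fitted anyway but flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (voltage, p_open) points")
    order = np.argsort(pts[:, 0])
    u, p = pts[order, 0], pts[order, 1]
    flagged = bool(np.any(np.diff(p) < -0.05)) or np.ptp(p) < 0.05
    if flagged:
        warnings.warn("activation points are non-monotone or degenerate; "
                      "fit is flagged", stacklevel=2)
    v0 = u[np.argmin(np.abs(p - 0.5 * (p.min() + p.max())))]
    k0 = max(np.ptp(u) / 8.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if p_max is None:
            popt, _ = curve_fit(_boltzmann, u, p, p0=(v0, k0, max(p.max(), 0.5)),
                                maxfev=20000)
            v_half, slope_k, pm = popt
        else:
            popt, _ = curve_fit(lambda uu, v, k: _boltzmann(uu, v, k, p_max),
                                u, p, p0=(v0, k0), maxfev=20000)
            v_half, slope_k = popt
            pm = p_max
    resid = p - _boltzmann(u, v_half, slope_k, pm)
    return ActivationFit(v_half=float(v_half), slope_k=float(slope_k),
                         p_max=float(pm), residuals=resid, flagged=flagged)
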