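"""Focus-based multifractal detrended fluctuation analysis (MFDFA).

DFA is generalized over moment orders q: the scaling function G(q, s) is
the q-th order mean of the per-segment detrended variances (with segments
tiled from both the series start and end, 2 n_s per scale, and the
log-mean exponential form at q = 0).  The generalized Hurst exponents H(q)
are estimated with the focus-based regression scheme: all q-wise
log-log fits are constrained to pass through a single common point — the
focus — at s = N, with the focus value estimated jointly by least squares
across all q.  From H(q) follow the mass exponent tau(q) = qH(q) - 1, the
Hölder exponent h(q) = dtau/dq, the singularity spectrum
D(h) = q h(q) - tau(q), and the spectrum width Delta = max h - min h, a
proxy for the complexity of the gating signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .longmemory import (
    MFDFA_SCALES,
    ScalePolicy,
    build_scale_grid,
    profile,
    segment_variances,
)

__all__ = [
    "default_q_grid",
    "ScalingSurface",
    "MFSpectrum",
    "mfdfa_scaling",
    "focus_fit",
    "singularity_spectrum",
    "mfdfa",
]


def default_q_grid() -> np.ndarray:
    """Moment orders -5 ... +5 in steps of 0.5 (21 values, includes 0)."""
    return np.round(np.arange(-10, 11) * 0.5, 1)


def _validate_q_grid(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float).ravel()
    if q.size < 3 or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing with >= 3 values")
    if 0.0 not in q or q.min() >= 0 or q.max() <= 0:
        raise ValueError("q grid must contain 0 and span negative and positive orders")
    return q


@dataclass(frozen=True)
class ScalingSurface:
    """log2 of the scaling function G(q, s) on a (q, scale) grid.

    ``log2_g[i, j]`` is log2 G(q_i, s_j); ``series_length`` is N, the
    abscissa at which the focus-based fit anchors its common point.  As a
    power mean of order q/2 of the segment variances, G(q, s) is
    nondecreasing in q at fixed s.
    """

    q: np.ndarray
    scales: np.ndarray
    log2_g: np.ndarray
    series_length: int

    def __post_init__(self) -> None:
        if self.log2_g.shape != (self.q.size, self.scales.size):
            raise ValueError("log2_g must have shape (n_q, n_scales)")
        if not np.all(np.isfinite(self.log2_g)):
            raise ValueError("scaling function must be finite and positive")

    @property
    def g(self) -> np.ndarray:
        return 2.0**self.log2_g


@dataclass(frozen=True)
class MFSpectrum:
    """Multifractal spectrum: H(q), tau(q), h(q), D(h) and width Delta."""

    q: np.ndarray
    hq: np.ndarray
    tau: np.ndarray
    holder: np.ndarray  # h(q)
    dims: np.ndarray    # D(h(q))
    delta: float
    focus: float        # log2 of the scaling function at s = N
    r2_per_q: np.ndarray
    concave: bool

    @property
    def width(self) -> float:
        return self.delta


def mfdfa_scaling(
    series: np.ndarray,
    q_grid: Optional[np.ndarray] = None,
    scale_policy: Optional[ScalePolicy] = None,
) -> ScalingSurface:
    """Scaling function G(q, s) of a series.

    Per scale s, detrended variances F^2(s, v) are computed over segments
    tiled from both the start and the end of the profile (2 n_s segments).
    For q != 0, G = (mean [F^2]^(q/2))^(1/q); at q = 0 the limiting
    log-mean exponential form is used.  All q-th order means are evaluated
    in log space so large |q| stays numerically stable.  Zero-variance
    segments (flat stretches of profile) are dropped with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2**9:
        raise ValueError("series too short for a stable multifractal analysis")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no fluctuations to analyze")
    q = _validate_q_grid(default_q_grid() if q_grid is None else q_grid)
    y = profile(x)
    scales = build_scale_grid(x.size, scale_policy, default=MFDFA_SCALES)
    log2e = np.log2(np.e)
    rows = []
    dropped = 0
    for s in scales:
        f2 = segment_variances(y, s, two_sided=True)
        ok = f2 > 0
        dropped += int((~ok).sum())
        if not ok.any():
            raise ValueError(f"all segments degenerate at scale {s}")
        log_f2 = np.log(f2[ok])
        n_seg = log_f2.size
        col = np.empty(q.size)
        for i, qq in enumerate(q):
            if qq == 0.0:
                col[i] = 0.5 * log_f2.mean() * log2e
            else:
                # (1/q) log2 mean exp(q/2 * log F2)
                col[i] = (logsumexp(0.5 * qq * log_f2) - np.log(n_seg)) / qq * log2e
        rows.append(col)
    if dropped:
        warnings.warn(f"dropped {dropped} zero-variance segments in MFDFA",
                      stacklevel=2)
    log2_g = np.column_stack(rows)
    return ScalingSurface(q=q, scales=scales, log2_g=log2_g, series_length=x.size)


def focus_fit(surface: ScalingSurface) -> tuple:
    """Generalized Hurst exponents by the focus-based regression.

    Solves the joint least-squares problem
    ``log2 G(q, s) ~ focus + H(q) * (log2 s - log2 N)`` over all (q, s)
    pairs, i.e. every q-wise regression is forced through one common point
    at s = N.  Returns ``(hq, focus, r2_per_q)``.  Falls back to
    independent per-q fits (focus = NaN, with a warning) if the joint
    system is singular.
    """
    if surface.scales.size < 4:
        raise ValueError("need at least 4 scales for the focus-based fit")
    q, scales, y = surface.q, surface.scales, surface.log2_g
    x = np.log2(scales.astype(float)) - np.log2(surface.series_length)
    nq, ns = y.shape
    # design: columns = [focus, H(q_1) ... H(q_nq)]
    a = np.zeros((nq * ns, nq + 1))
    a[:, 0] = 1.0
    for i in range(nq):
        a[i * ns:(i + 1) * ns, 1 + i] = x
    b = y.ravel()
    sol, residuals, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < nq + 1:
        warnings.warn("focus-based joint fit is singular; falling back to "
                      "independent per-q fits", stacklevel=2)
        hq = np.array([np.polyfit(x, y[i], 1)[0] for i in range(nq)])
        focus = float("nan")
        fitted = np.array([np.polyval(np.polyfit(x, y[i], 1), x) for i in range(nq)])
    else:
        focus, hq = float(sol[0]), sol[1:]
        fitted = focus + hq[:, None] * x[None, :]
    ss_res = np.sum((y - fitted) ** 2, axis=1)
    ss_tot = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return hq, focus, r2


def singularity_spectrum(
    hq: np.ndarray,
    q_grid: np.ndarray,
    focus: float = float("nan"),
    r2_per_q: Optional[np.ndarray] = None,
    concavity_tol: float = 1e-6,
) -> MFSpectrum:
    """Multifractal spectrum from the generalized Hurst exponents.

    tau(q) = qH(q) - 1; h(q) = dtau/dq by central finite differences
    (one-sided at the grid ends); D(h) = q h(q) - tau(q);
    Delta = max h - min h.  tau(0) = -1 and D(h(0)) = 1 hold by
    construction.  A convexity violation of tau beyond tolerance flags the
    spectrum as inverted (warning, not an error).
    """
    q = _validate_q_grid(q_grid)
    hq = np.asarray(hq, dtype=float)
    if hq.shape != q.shape or not np.all(np.isfinite(hq)):
        raise ValueError("hq must be finite and match the q grid")
    tau = q * hq - 1.0
    holder = np.gradient(tau, q)
    dims = q * holder - tau
    # concavity: finite-difference slopes of tau nonincreasing
    slopes = np.diff(tau) / np.diff(q)
    concave = bool(np.all(np.diff(slopes) <= concavity_tol))
    if not concave:
        warnings.warn("mass exponent tau(q) is not concave: inverted or "
                      "unreliable spectrum", stacklevel=2)
    delta = float(holder.max() - holder.min())
    if r2_per_q is None:
        r2_per_q = np.full(q.size, np.nan)
    return MFSpectrum(q=q, hq=hq, tau=tau, holder=holder, dims=dims,
                      delta=delta, focus=float(focus),
                      r2_per_q=np.asarray(r2_per_q, dtype=float),
                      concave=concave)


def mfdfa(
    series: np.ndarray,
    q_grid: Optional[np.ndarray] = None,
    scale_policy: Optional[ScalePolicy] = None,
) -> MFSpectrum:
    """Full multifractal analysis: scaling surface -> focus fit -> spectrum."""
    surface = mfdfa_scaling(series, q_grid=q_grid, scale_policy=scale_policy)
    hq, focus, r2 = focus_fit(surface)
    return singularity_spectrum(hq, surface.q, focus=focus, r2_per_q=r2)
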