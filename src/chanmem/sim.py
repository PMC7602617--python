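"""Synthetic single-channel recordings and reference stochastic series.

The generators here stand in for patch-clamp recordings: continuous-time
Markov-chain (CTMC) gating schemes rendered to noisy two-level current
traces, optionally with slowly rate-modulated kinetics that induce
long-range memory in the dwell-time series, plus two reference series with
known scaling behaviour — exact fractional Gaussian noise (circulant
embedding) and the binomial multiplicative cascade, used as oracles for the
long-memory and multifractal estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .core import CLOSED, OPEN, CurrentTrace

__all__ = [
    "GatingScheme",
    "ModulationSpec",
    "SimulationConfig",
    "StateTrajectory",
    "two_state_scheme",
    "loop_scheme",
    "bk_scheme",
    "simulate_markov_gating",
    "simulate_modulated_gating",
    "render_current",
    "generate_fgn",
    "generate_cascade",
]


# ---------------------------------------------------------------------------
# scheme / config containers


@dataclass(frozen=True)
class GatingScheme:
    """A CTMC gating scheme: states, classes and a transition-rate matrix.

    ``rates`` is the generator matrix Q in 1/s: off-diagonal entries are
    transition rates (>= 0), each diagonal entry equals minus its row sum.
    Every state must be reachable from every other (irreducible chain) and
    at least one open and one closed state must be present.
    """

    state_ids: tuple
    state_class: tuple
    rates: np.ndarray
    open_current: float = 10.0
    closed_current: float = 0.0

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "state_ids", tuple(self.state_ids))
        object.__setattr__(self, "state_class", tuple(self.state_class))
        n = len(self.state_ids)
        if rates.shape != (n, n):
            raise ValueError("rates must be a square matrix matching state_ids")
        if len(self.state_class) != n:
            raise ValueError("state_class must match state_ids")
        for c in self.state_class:
            if c not in (OPEN, CLOSED):
                raise ValueError(f"state_class entries must be 'open'/'closed', got {c!r}")
        if OPEN not in self.state_class or CLOSED not in self.state_class:
            raise ValueError("scheme needs at least one open and one closed state")
        off = rates.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(np.diag(rates), -off.sum(axis=1), rtol=1e-8, atol=1e-10):
            raise ValueError("diagonal must equal the negative off-diagonal row sum")
        if np.any(off.sum(axis=1) <= 0):
            raise ValueError("absorbing state detected (zero exit rate)")
        n_comp, _ = connected_components(off > 0, directed=True, connection="strong")
        if n_comp != 1:
            raise ValueError("scheme is not irreducible (unreachable states)")

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @property
    def is_open(self) -> np.ndarray:
        return np.array([c == OPEN for c in self.state_class], dtype=bool)

    @property
    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.rates)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution pi with pi Q = 0, sum(pi) = 1."""
        q = self.rates
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def stationary_open_probability(self) -> float:
        return float(self.stationary_distribution()[self.is_open].sum())

    def level_of(self, state_index: int) -> float:
        return self.open_current if self.is_open[state_index] else self.closed_current


def _generator_from_offdiag(off: np.ndarray) -> np.ndarray:
    q = np.asarray(off, dtype=float).copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def two_state_scheme(
    k_closed_to_open: float = 50.0,
    k_open_to_closed: float = 50.0,
    open_current: float = 10.0,
    closed_current: float = 0.0,
) -> GatingScheme:
    """Minimal C <-> O scheme (memoryless gating; defaults give 20 ms mean
    dwells in either state, typical of BK gating at mid-range potentials)."""
    off = np.array([[0.0, k_closed_to_open], [k_open_to_closed, 0.0]])
    return GatingScheme(
        state_ids=("C", "O"),
        state_class=(CLOSED, OPEN),
        rates=_generator_from_offdiag(off),
        open_current=open_current,
        closed_current=closed_current,
    )


def loop_scheme(
    long_mean: float = 0.05,
    short_mean: float = 0.005,
    bias: float = 10.0,
    open_current: float = 10.0,
) -> GatingScheme:
    """Four-state cyclic scheme producing adjacent dwell-time correlations.

    States O_long -> C_short -> O_short -> C_long -> O_long form a biased
    cycle: a long-lived open state is preferentially followed by a
    short-lived closed state and vice versa.  Correlations between adjacent
    open/closed dwell times require at least two substates per class with
    contrasting lifetimes connected in a loop; a cycle with a net
    probability flux (broken detailed balance) is the simplest such scheme.
    """
    k_long, k_short = 1.0 / long_mean, 1.0 / short_mean
    fwd, back = bias / (1.0 + bias), 1.0 / (1.0 + bias)
    # order: O_long, C_short, O_short, C_long
    exit_rate = np.array([k_long, k_short, k_short, k_long])
    off = np.zeros((4, 4))
    for i in range(4):
        off[i, (i + 1) % 4] = fwd * exit_rate[i]
        off[i, (i - 1) % 4] = back * exit_rate[i]
    return GatingScheme(
        state_ids=("O_long", "C_short", "O_short", "C_long"),
        state_class=(OPEN, CLOSED, OPEN, CLOSED),
        rates=_generator_from_offdiag(off),
        open_current=open_current,
    )


def bk_scheme(open_current: float = 10.0) -> GatingScheme:
    """A plausible 3-open / 5-closed BK-type gating scheme with loops.

    Lifetimes span ~1 ms to ~100 ms across the two manifolds; the loops
    connecting long-lived open with short-lived closed substates (and vice
    versa) generate short-range dwell-time correlations.  The rate values
    are illustrative, not fitted to any recording.
    """
    ids = ("O1", "O2", "O3", "C1", "C2", "C3", "C4", "C5")
    cls = (OPEN, OPEN, OPEN, CLOSED, CLOSED, CLOSED, CLOSED, CLOSED)
    off = np.zeros((8, 8))

    def setr(a: str, b: str, rate: float) -> None:
        off[ids.index(a), ids.index(b)] = rate

    # open manifold: O1 long-lived, O3 brief
    setr("O1", "C1", 15.0)
    setr("O2", "C2", 80.0)
    setr("O2", "C3", 40.0)
    setr("O3", "C4", 600.0)
    setr("O3", "C5", 200.0)
    # closed manifold: C1/C2 brief, C5 long-lived
    setr("C1", "O1", 300.0)
    setr("C1", "C2", 100.0)
    setr("C2", "O2", 250.0)
    setr("C2", "C1", 60.0)
    setr("C3", "O2", 50.0)
    setr("C3", "C4", 30.0)
    setr("C4", "O3", 20.0)
    setr("C4", "C3", 15.0)
    setr("C4", "C5", 8.0)
    setr("C5", "O3", 6.0)
    setr("C5", "C4", 4.0)
    return GatingScheme(state_ids=ids, state_class=cls,
                        rates=_generator_from_offdiag(off),
                        open_current=open_current)


@dataclass(frozen=True)
class ModulationSpec:
    """Slow stochastic modulation of all transition rates.

    A smoothed, variance-normalized fractional-Gaussian-noise path z(t)
    with Hurst index ``hurst_target`` multiplies every rate by
    ``exp(amplitude * z(t))`` — a strictly positive, long-range-correlated
    rate multiplier emulating a slow side-process (e.g. membrane-thickness
    fluctuations) that biases gating kinetics.

    Parameters
    ----------
    hurst_target : float
        Fractal index of the modulating process, in (0, 1).
    amplitude : float
        Spread of the log rate multiplier (dimensionless, >= 0); 0 recovers
        the homogeneous chain.
    correlation_time : float
        Smoothing scale of the modulator in seconds; should exceed the mean
        dwell time so the modulation is slow relative to gating.
    """

    hurst_target: float = 0.8
    amplitude: float = 0.5
    correlation_time: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst_target < 1.0:
            raise ValueError("hurst_target must lie in (0, 1)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.correlation_time > 0:
            raise ValueError("correlation_time must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling/rendering parameters for turning a state path into a trace."""

    n_samples: int = 2**13
    dt: float = 250e-6
    noise_sigma: float = 1.0
    seed: int = 0
    filter_corner: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.filter_corner is not None and not 0 < self.filter_corner < 0.5 / self.dt:
            raise ValueError("filter_corner must lie in (0, Nyquist)")


@dataclass(frozen=True)
class StateTrajectory:
    """Event-driven CTMC sample path.

    ``event_times[k]`` is the start of the k-th sojourn (first entry 0),
    ``event_states[k]`` the state index occupied during it.
    """

    event_times: np.ndarray
    event_states: np.ndarray
    total_duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        s = np.asarray(self.event_states, dtype=int)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "event_states", s)
        if t.size != s.size or t.size == 0:
            raise ValueError("event_times and event_states must be nonempty, same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(s[1:] == s[:-1]):
            raise ValueError("consecutive states must differ")
        if self.total_duration < t[-1]:
            raise ValueError("total_duration must cover the last jump time")

    @property
    def n_events(self) -> int:
        return int(self.event_states.size)

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """State index occupied at each query time (right-continuous)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.event_times, times, side="right") - 1
        return self.event_states[np.clip(idx, 0, self.n_events - 1)]

    def sojourns(self) -> tuple:
        """(durations, state indices) of completed sojourns plus the final
        censored one truncated at total_duration."""
        ends = np.append(self.event_times[1:], self.total_duration)
        return ends - self.event_times, self.event_states


# ---------------------------------------------------------------------------
# CTMC simulation


def _draw_initial_state(scheme: GatingScheme, rng: np.random.Generator) -> int:
    return int(rng.choice(scheme.n_states, p=scheme.stationary_distribution()))


def simulate_markov_gating(
    scheme: GatingScheme, duration: float, seed: int,
    start_state: Optional[int] = None,
) -> StateTrajectory:
    """Exact event-driven (Gillespie) sample path of the gating CTMC.

    Sojourn times are exponential with the state's exit rate; jumps follow
    the embedded-chain probabilities.  The initial state is drawn from the
    stationary distribution unless ``start_state`` is given.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    exit_rates = scheme.exit_rates
    # embedded-chain jump probabilities per state
    jump_p = scheme.rates.copy()
    np.fill_diagonal(jump_p, 0.0)
    jump_p /= jump_p.sum(axis=1, keepdims=True)

    state = _draw_initial_state(scheme, rng) if start_state is None else int(start_state)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        t += rng.exponential(1.0 / exit_rates[state])
        if t >= duration:
            break
        state = int(rng.choice(scheme.n_states, p=jump_p[state]))
        times.append(t)
        states.append(state)
    return StateTrajectory(np.array(times), np.array(states), float(duration))


def _modulation_path(
    mod: ModulationSpec, duration: float, rng: np.random.Generator,
) -> tuple:
    """Piecewise-constant rate-multiplier path on a grid of step
    correlation_time/4; returns (grid_dt, multipliers)."""
    grid_dt = mod.correlation_time / 4.0
    n_grid = max(int(math.ceil(duration / grid_dt)) + 2, 16)
    z = generate_fgn(n_grid, mod.hurst_target, seed=int(rng.integers(2**31)))
    # boxcar smoothing over one correlation time, then standardize
    win = max(int(round(mod.correlation_time / grid_dt)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        z = np.convolve(z, kernel, mode="same")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    m = np.exp(mod.amplitude * z)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("modulation amplitude produced non-finite rate multipliers")
    return grid_dt, m


def simulate_modulated_gating(
    scheme: GatingScheme, mod: ModulationSpec, duration: float, seed: int,
    start_state: Optional[int] = None,
) -> StateTrajectory:
    """Time-inhomogeneous CTMC path with all rates scaled by a slow
    long-range-correlated multiplier, sampled exactly by thinning.

    Because the multiplier m(t) scales every rate, the embedded-chain jump
    probabilities are unchanged; only the waiting times are modulated.
    Candidate jumps are proposed at the upper-bound rate
    ``exit_rate * max(m)`` over the realized path and accepted with
    probability ``m(t)/max(m)`` (rejection/thinning), which is exact for a
    piecewise-constant modulator.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    grid_dt, m = _modulation_path(mod, duration, rng)
    m_max = float(m.max())

    exit_rates = scheme.exit_rates
    jump_p = scheme.rates.copy()
    np.fill_diagonal(jump_p, 0.0)
    jump_p /= jump_p.sum(axis=1, keepdims=True)

    state = _draw_initial_state(scheme, rng) if start_state is None else int(start_state)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        bound = exit_rates[state] * m_max
        t += rng.exponential(1.0 / bound)
        if t >= duration:
            break
        m_t = m[min(int(t / grid_dt), m.size - 1)]
        if rng.random() < m_t / m_max:  # accepted jump
            state = int(rng.choice(scheme.n_states, p=jump_p[state]))
            times.append(t)
            states.append(state)
    return StateTrajectory(np.array(times), np.array(states), float(duration))


# ---------------------------------------------------------------------------
# rendering


def render_current(
    traj: StateTrajectory, scheme: GatingScheme, config: SimulationConfig,
) -> CurrentTrace:
    """Sample the state path at ``config.dt`` and add Gaussian noise.

    All open states share ``open_current`` and all closed states
    ``closed_current`` (binary rendering, matching the binary
    idealization).  An optional 4-pole Bessel-style low-pass emulating the
    recording filter is applied after the noise.
    """
    t_samp = np.arange(config.n_samples) * config.dt
    if traj.total_duration < t_samp[-1]:
        raise ValueError(
            f"trajectory covers {traj.total_duration:.4f} s but "
            f"{t_samp[-1]:.4f} s are required for {config.n_samples} samples"
        )
    idx = traj.state_at(t_samp)
    levels = np.where(scheme.is_open[idx], scheme.open_current, scheme.closed_current)
    rng = np.random.default_rng(config.seed)
    samples = levels + rng.normal(0.0, config.noise_sigma, size=config.n_samples) \
        if config.noise_sigma > 0 else levels.astype(float)
    if config.filter_corner is not None:
        from scipy.signal import bessel, lfilter
        b, a = bessel(4, config.filter_corner, fs=1.0 / config.dt, norm="mag")
        samples = lfilter(b, a, samples)
    return CurrentTrace(samples=samples, dt=config.dt)


# ---------------------------------------------------------------------------
# reference series


def fgn_autocovariance(lags: Sequence[int], hurst: float) -> np.ndarray:
    """Closed-form fGn autocovariance
    gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H), unit variance."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def generate_fgn(n: int, hurst: float, seed: int) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies-Harte).

    Returns a stationary, unit-variance Gaussian series whose
    autocovariance matches the fGn closed form for the requested Hurst
    index.  Raises if the circulant embedding is not positive
    semi-definite for the requested (n, hurst) combination.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    gamma = fgn_autocovariance(np.arange(n), hurst)
    # first row of the 2(n-1) circulant
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.any(eig < -1e-8 * eig.max()):
        raise ValueError("circulant embedding not positive semi-definite "
                         f"for n={n}, hurst={hurst}")
    eig = np.clip(eig, 0.0, None)
    m = row.size
    # complex Gaussian spectral weights with Hermitian symmetry handled by irfft
    w = rng.normal(size=eig.size) + 1j * rng.normal(size=eig.size)
    w[0] = rng.normal() * np.sqrt(2)
    if m % 2 == 0:
        w[-1] = rng.normal() * np.sqrt(2)
    spec = w * np.sqrt(eig * m / 2.0)
    x = np.fft.irfft(spec, n=m)
    return x[:n]


def generate_cascade(levels: int, weight: float, seed: int) -> np.ndarray:
    """Binomial multiplicative cascade of length 2**levels.

    At each of ``levels`` dyadic refinements every interval's mass is split
    into fractions (weight, 1-weight), the order randomized per node.  The
    resulting series has the exact mass exponent
    tau(q) = -log2(weight**q + (1-weight)**q); weight 0.5 degenerates to a
    uniform (monofractal) series.
    """
    if levels < 8:
        raise ValueError("levels must be >= 8")
    if not 0.5 <= weight < 1.0:
        raise ValueError("weight must lie in [0.5, 1)")
    rng = np.random.default_rng(seed)
    x = np.ones(1)
    for lev in range(levels):
        flip = rng.random(x.size) < 0.5
        left = np.where(flip, 1.0 - weight, weight)
        pair = np.empty(2 * x.size)
        pair[0::2] = x * left
        pair[1::2] = x * (1.0 - left)
        x = pair
    # normalize to unit mean so the scale is independent of `levels`
    return x * (2.0**levels / x.sum() if x.sum() > 0 else 1.0)
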