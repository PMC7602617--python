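"""Dwell-time series and conditional mean dwell-time arrays.

A dwell-time series is the run-length encoding of an idealized state
sequence: alternating open/closed sojourn durations.  The conditional mean
dwell-time array bins each sojourn by the duration of the immediately
preceding opposite-state sojourn (5 ms bins by default) and reports the
mean following-state duration per bin — flat for a memoryless two-state
channel, structured when substates of contrasting lifetime are connected
in loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
from scipy.stats import spearmanr

from .core import CLOSED, OPEN, DwellTimeSeries, StateSequence

__all__ = [
    "ConditionalDwellArray",
    "extract_dwell_times",
    "split_by_state",
    "conditional_mean_dwell",
    "merge_conditional_arrays",
    "adjacent_dwell_correlation",
]

SENTINEL = -1.0
DEFAULT_BIN_WIDTH = 0.005  # 5 ms resolution of the conditional arrays


@dataclass(frozen=True)
class ConditionalDwellArray:
    """Mean next-state duration binned by preceding opposite-state duration.

    Internally empty bins carry count 0 and mean/SEM NaN; the exported
    representation (:meth:`export`) marks empty bins with the sentinel -1.
    ``bin_sums``/``bin_sq_sums`` keep the raw accumulators so arrays from
    several patches can be merged by pooling events.
    """

    target: str  # which state's duration is averaged: 'open' or 'closed'
    bin_width: float
    bin_counts: np.ndarray
    bin_sums: np.ndarray
    bin_sq_sums: np.ndarray
    overflow_pooled: bool = False

    def __post_init__(self) -> None:
        if self.target not in (OPEN, CLOSED):
            raise ValueError("target must be 'open' or 'closed'")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.bin_counts.size)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width

    @property
    def bin_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.bin_counts > 0,
                            self.bin_sums / self.bin_counts, np.nan)

    @property
    def bin_sems(self) -> np.ndarray:
        """SEM per bin from the pooled event set (std/sqrt(count))."""
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = self.bin_sums / self.bin_counts
            var = self.bin_sq_sums / self.bin_counts - mean**2
            var = np.clip(var, 0.0, None)
            sem = np.sqrt(var / self.bin_counts)
        return np.where(self.bin_counts > 0, sem, np.nan)

    def export(self) -> np.ndarray:
        """(n_bins, 4) array: bin_start_s, mean_s, sem_s, count; empty bins
        carry the -1 sentinel in the mean/sem columns."""
        means = np.where(self.bin_counts > 0, self.bin_means, SENTINEL)
        sems = np.where(self.bin_counts > 0, self.bin_sems, SENTINEL)
        return np.column_stack([self.bin_starts, means, sems,
                                self.bin_counts.astype(float)])

    def global_mean(self) -> float:
        """Count-weighted mean over bins == pooled mean target duration."""
        total = self.bin_counts.sum()
        if total == 0:
            return float("nan")
        return float(self.bin_sums.sum() / total)


def extract_dwell_times(states: StateSequence) -> DwellTimeSeries:
    """Run-length encode a state sequence into alternating sojourns.

    Durations are run length x dt.  The first and last sojourns are
    boundary-censored (flagged, excluded from distribution statistics via
    ``DwellTimeSeries.uncensored``).
    """
    s = states.states
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [s.size]])
    durations = (ends - starts) * states.dt
    labels = np.where(s[starts], OPEN, CLOSED).astype(object)
    censored = np.zeros(durations.size, dtype=bool)
    censored[0] = True
    censored[-1] = True
    return DwellTimeSeries(durations=durations, labels=labels,
                          dt=states.dt, censored=censored)


def split_by_state(dwells: DwellTimeSeries) -> Tuple[DwellTimeSeries, DwellTimeSeries]:
    """Order-preserving split into open-only and closed-only sub-series.

    Either part may be empty for degenerate (single-state) inputs.
    Single-state sub-series trivially satisfy alternation.
    """
    if len(dwells) == 0:
        raise ValueError("empty dwell series")
    out = []
    for lab in (OPEN, CLOSED):
        mask = dwells.labels == lab
        out.append(DwellTimeSeries(
            durations=dwells.durations[mask],
            labels=np.array([lab] * int(mask.sum()), dtype=object),
            dt=dwells.dt,
            censored=dwells.censored[mask],
        ))
    return out[0], out[1]


def _adjacent_pairs(dwells: DwellTimeSeries, target: str) -> Tuple[np.ndarray, np.ndarray]:
    """(preceding opposite-state durations, target durations) for every
    target-state sojourn with an uncensored predecessor."""
    d, lab, cen = dwells.durations, dwells.labels, dwells.censored
    idx = np.flatnonzero(lab[1:] == target) + 1
    ok = ~cen[idx - 1] & ~cen[idx]
    idx = idx[ok]
    return d[idx - 1], d[idx]


def conditional_mean_dwell(
    dwells: DwellTimeSeries,
    target: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int | None = None,
) -> ConditionalDwellArray:
    """Conditional mean dwell-time array for ``target`` sojourns.

    Each target-state sojourn contributes its duration to the bin
    ``floor(t_prev / bin_width)`` of the preceding opposite-state duration
    ``t_prev``; bin means are the accumulated durations divided by the
    event counts.  The array extends to the 99.5th percentile of preceding
    durations unless ``n_bins`` is given; overflow events are pooled into
    the last bin and the array flagged.
    """
    if len(dwells) < 2:
        raise ValueError("need at least two sojourns")
    prev, tgt = _adjacent_pairs(dwells, target)
    if prev.size == 0:
        raise ValueError(f"no uncensored pairs ending in a {target} sojourn")
    idx = np.floor(prev / bin_width).astype(int)
    if n_bins is None:
        extent = np.quantile(prev, 0.995)
        n_bins = max(int(np.floor(extent / bin_width)) + 1, 1)
    overflow = idx >= n_bins
    idx = np.minimum(idx, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    sums = np.bincount(idx, weights=tgt, minlength=n_bins)
    sq_sums = np.bincount(idx, weights=tgt**2, minlength=n_bins)
    return ConditionalDwellArray(
        target=target, bin_width=bin_width, bin_counts=counts,
        bin_sums=sums, bin_sq_sums=sq_sums,
        overflow_pooled=bool(overflow.any()),
    )


def merge_conditional_arrays(
    arrays: Iterable[ConditionalDwellArray],
) -> ConditionalDwellArray:
    """Pool conditional arrays from several patches by summing event
    accumulators (count-weighted merge; identical to pooling the events)."""
    arrays = list(arrays)
    if not arrays:
        raise ValueError("nothing to merge")
    first = arrays[0]
    if any(a.target != first.target or a.bin_width != first.bin_width for a in arrays):
        raise ValueError("arrays must share target and bin_width")
    n = max(a.n_bins for a in arrays)

    def pad(v: np.ndarray) -> np.ndarray:
        return np.pad(v, (0, n - v.size))

    return ConditionalDwellArray(
        target=first.target,
        bin_width=first.bin_width,
        bin_counts=sum(pad(a.bin_counts) for a in arrays),
        bin_sums=sum(pad(a.bin_sums) for a in arrays),
        bin_sq_sums=sum(pad(a.bin_sq_sums) for a in arrays),
        overflow_pooled=any(a.overflow_pooled for a in arrays),
    )


def adjacent_dwell_correlation(
    dwells: DwellTimeSeries, target: str = OPEN,
) -> Tuple[float, float]:
    """Spearman rank correlation between each opposite-state duration and
    the immediately following ``target`` duration; returns (rho, p).

    Zero for a two-state Markov chain (adjacent sojourns are independent);
    significantly nonzero when contrasting-lifetime substates are coupled
    in a loop.
    """
    prev, tgt = _adjacent_pairs(dwells, target)
    if prev.size < 30:
        raise ValueError("need at least 30 adjacent pairs")
    rho, p = spearmanr(prev, tgt)
    return float(rho), float(p)
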