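"""Core data containers shared across the analysis pipeline.

Package-wide conventions: time in seconds, current in pA, membrane potential
in mV; sample indices are 0-based; dwell-time bins are half-open
``[k*w, (k+1)*w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

OPEN = "open"
CLOSED = "closed"

MEMBRANE_LABELS = ("mitochondrial", "cellular")


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled single-channel current recording.

    Parameters
    ----------
    samples : ndarray
        Current values in pA.
    dt : float
        Sampling interval in seconds (250 us at a 4 kHz acquisition rate).
    voltage : float, optional
        Membrane potential in mV at which the trace was recorded.
    membrane : str, optional
        ``"mitochondrial"`` or ``"cellular"``.
    patch_id : str, optional
        Identifier of the membrane patch.
    """

    samples: np.ndarray
    dt: float
    voltage: Optional[float] = None
    membrane: Optional[str] = None
    patch_id: Optional[str] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.membrane is not None and self.membrane not in MEMBRANE_LABELS:
            raise ValueError(
                f"membrane must be one of {MEMBRANE_LABELS}, got {self.membrane!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Total trace duration in seconds (n_samples * dt)."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def with_samples(self, samples: np.ndarray) -> "CurrentTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class StateSequence:
    """Per-sample binary open/closed labels from idealizing a trace.

    ``states`` is a boolean array, True for the conducting (open) state.
    """

    states: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=bool)
        object.__setattr__(self, "states", states)
        if states.ndim != 1 or states.size == 0:
            raise ValueError("states must be a nonempty 1-D array")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.states.size)


@dataclass(frozen=True)
class DwellTimeSeries:
    """Alternating open/closed sojourn durations from a state sequence.

    ``durations`` are in seconds; ``labels`` holds ``"open"``/``"closed"``
    per sojourn and strictly alternates.  The first and last sojourns of a
    finite recording are boundary-censored (their true length is unknown);
    ``censored`` flags them so distribution statistics can exclude them.
    """

    durations: np.ndarray
    labels: np.ndarray
    dt: float
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        durations = np.asarray(self.durations, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "labels", labels)
        if durations.shape != labels.shape:
            raise ValueError("durations and labels must have the same shape")
        if durations.size and not np.all(durations > 0):
            raise ValueError("durations must be positive")
        # full series must alternate; single-state sub-series (from
        # split_by_state) are homogeneous and exempt
        if durations.size > 1 and len(set(labels)) > 1 and np.any(
            labels[1:] == labels[:-1]
        ):
            raise ValueError("labels must strictly alternate")
        if self.censored is None:
            censored = np.zeros(durations.size, dtype=bool)
        else:
            censored = np.asarray(self.censored, dtype=bool)
        object.__setattr__(self, "censored", censored)

    def __len__(self) -> int:
        return int(self.durations.size)

    @property
    def uncensored(self) -> "DwellTimeSeries":
        """Sub-series without the boundary-censored first/last sojourns.

        Dropping the ends keeps strict alternation, so the result is a
        valid series.
        """
        keep = ~self.censored
        return DwellTimeSeries(
            durations=self.durations[keep],
            labels=self.labels[keep],
            dt=self.dt,
            censored=np.zeros(int(keep.sum()), dtype=bool),
        )

    def total_duration(self) -> float:
        return float(self.durations.sum())
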