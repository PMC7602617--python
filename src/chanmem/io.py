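"""Readers and writers for traces, schemes, events and result records.

Traces travel as two-column CSV (``time_s, current_pA``) with a JSON
sidecar for metadata (dt, voltage, membrane, patch id), or as a compact
``.npy`` binary with the same sidecar.  Gating schemes are YAML.  All
result records are JSON/CSV so every number carries its provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import CurrentTrace, DwellTimeSeries, StateSequence
from .dwell import ConditionalDwellArray
from .longmemory import FluctuationResult
from .mfdfa import MFSpectrum
from .sim import GatingScheme

__all__ = [
    "UnsupportedFormatError",
    "read_trace",
    "write_trace",
    "read_scheme",
    "write_scheme",
    "write_states",
    "write_events",
    "write_conditional_array",
    "fluctuation_record",
    "spectrum_record",
    "write_json",
]

_DT_TOLERANCE = 1e-6  # 1 ppm relative tolerance on timestamp uniformity


class UnsupportedFormatError(ValueError):
    """Raised for trace formats this package cannot read."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_trace(
    path, format: str = "csv",
    dt: Optional[float] = None,
    voltage: Optional[float] = None,
    membrane: Optional[str] = None,
    patch_id: Optional[str] = None,
) -> CurrentTrace:
    """Read a current trace with metadata from sidecar JSON or arguments.

    CSV traces need columns ``time_s`` and ``current_pA``; timestamps must
    be uniform to 1 ppm.  Explicit arguments override sidecar values.
    """
    path = Path(path)
    if format == "abf":
        raise UnsupportedFormatError(
            "Axon Binary Format input is not supported by this build; "
            "export the recording to CSV (time_s, current_pA)"
        )
    if format not in ("csv", "npy"):
        raise UnsupportedFormatError(f"unknown trace format {format!r}")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if format == "npy":
        samples = np.load(path)
        dt_file = meta.get("dt")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("time_s", "current_pA"):
            if col not in df.columns:
                raise ValueError(f"CSV trace must have a {col!r} column")
        t = df["time_s"].to_numpy(dtype=float)
        samples = df["current_pA"].to_numpy(dtype=float)
        steps = np.diff(t)
        dt_file = float(np.median(steps))
        if np.any(np.abs(steps - dt_file) > _DT_TOLERANCE * dt_file):
            raise ValueError("nonuniform timestamps (tolerance 1 ppm): gap or "
                             "jitter in the time_s column")
    dt_final = dt if dt is not None else (dt_file if dt_file else meta.get("dt"))
    if dt_final is None:
        raise ValueError("missing metadata: dt (sampling interval in seconds) "
                         "is required via sidecar, CSV timestamps or argument")
    return CurrentTrace(
        samples=samples,
        dt=float(dt_final),
        voltage=voltage if voltage is not None else meta.get("voltage_mV"),
        membrane=membrane if membrane is not None else meta.get("membrane"),
        patch_id=patch_id if patch_id is not None else meta.get("patch_id"),
    )


def write_trace(trace: CurrentTrace, path, format: str = "csv",
                extra_meta: Optional[dict] = None) -> Path:
    """Write a trace as CSV or .npy plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        pd.DataFrame({
            "time_s": trace.times,
            "current_pA": trace.samples,
        }).to_csv(path, index=False, float_format="%.17g")  # bit-exact round-trip
    elif format == "npy":
        np.save(path, trace.samples)
    else:
        raise UnsupportedFormatError(f"unknown trace format {format!r}")
    meta = {
        "dt": trace.dt,
        "voltage_mV": trace.voltage,
        "membrane": trace.membrane,
        "patch_id": trace.patch_id,
        "n_samples": trace.n_samples,
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def write_scheme(scheme: GatingScheme, path) -> Path:
    path = Path(path)
    payload = {
        "state_ids": list(scheme.state_ids),
        "state_class": list(scheme.state_class),
        "rates": np.asarray(scheme.rates).tolist(),
        "open_current": scheme.open_current,
        "closed_current": scheme.closed_current,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_scheme(path) -> GatingScheme:
    """Load a gating scheme (rate matrix, state classes, levels) from YAML."""
    payload = yaml.safe_load(Path(path).read_text())
    return GatingScheme(
        state_ids=tuple(payload["state_ids"]),
        state_class=tuple(payload["state_class"]),
        rates=np.asarray(payload["rates"], dtype=float),
        open_current=float(payload.get("open_current", 10.0)),
        closed_current=float(payload.get("closed_current", 0.0)),
    )


def write_states(states: StateSequence, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "sample_index": np.arange(states.n_samples),
        "state": np.where(states.states, "open", "closed"),
    }).to_csv(path, index=False)
    return path


def write_events(dwells: DwellTimeSeries, path) -> Path:
    """Events CSV: state, start_s, duration_s (censored sojourns flagged)."""
    starts = np.concatenate([[0.0], np.cumsum(dwells.durations)[:-1]])
    pd.DataFrame({
        "state": dwells.labels,
        "start_s": starts,
        "duration_s": dwells.durations,
        "censored": dwells.censored,
    }).to_csv(Path(path), index=False)
    return Path(path)


def write_conditional_array(array: ConditionalDwellArray, path) -> Path:
    exported = array.export()
    pd.DataFrame(exported, columns=["bin_start_s", "mean_s", "sem_s", "count"]) \
        .to_csv(Path(path), index=False)
    return Path(path)


def fluctuation_record(result: FluctuationResult, **tags) -> dict:
    """JSON-ready record of a fluctuation analysis with provenance tags."""
    rec = {
        "method": result.method,
        "exponent": result.exponent,
        "intercept": result.intercept,
        "r2": result.r2,
        "scales": result.scales.tolist(),
        "statistic": result.statistic.tolist(),
        "series_length": result.series_length,
    }
    rec.update(tags)
    return rec


def spectrum_record(spectrum: MFSpectrum, **tags) -> dict:
    rec = {
        "q": spectrum.q.tolist(),
        "Hq": spectrum.hq.tolist(),
        "tau": spectrum.tau.tolist(),
        "h": spectrum.holder.tolist(),
        "D": spectrum.dims.tolist(),
        "delta": spectrum.delta,
        "focus": spectrum.focus,
        "r2_per_q": spectrum.r2_per_q.tolist(),
        "concave": spectrum.concave,
    }
    rec.update(tags)
    return rec


def write_json(payload, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    path.write_text(json.dumps(payload, indent=1, default=default))
    return path
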