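"""Shared definition of the synthetic patch cohort used by the numbered
analysis scripts.

Two simulated membrane populations differ only in the strength of the
slow rate modulation (the hypothesized memory-inducing side-process):
'mitochondrial' patches carry a weaker modulation than 'cellular' ones,
so the cellular population should exhibit the larger dwell-time memory
effect.  Per-voltage gating rates follow a Boltzmann law with
half-activation at 0 mV and slope 25 mV, spanning open probabilities
from below 0.1 at -60 mV to above 0.9 at +60 mV; within each voltage the
rates are constants.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from chanmem.sim import (
    ModulationSpec,
    SimulationConfig,
    render_current,
    simulate_modulated_gating,
    two_state_scheme,
)

VOLTAGES = (-60.0, -30.0, 0.0, 30.0, 60.0)   # mV
N_PATCHES = 4
MEMBRANES = {"mitochondrial": 0.3, "cellular": 0.6}  # modulation amplitude
K0 = 50.0        # 1/s, symmetric rate at 0 mV
SLOPE_MV = 25.0  # Boltzmann slope of the activation curve
N_RENDER = 2**15          # samples per rendered trace (8.19 s at 4 kHz)
TARGET_EVENTS = 4600      # sojourns per recording (> 2^12 + margin)
DT = 250e-6
NOISE_SIGMA = 1.0

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def scheme_at(voltage: float):
    k_co = K0 * np.exp(voltage / (2 * SLOPE_MV))
    k_oc = K0 * np.exp(-voltage / (2 * SLOPE_MV))
    return two_state_scheme(k_closed_to_open=k_co, k_open_to_closed=k_oc)


def patch_seed(membrane: str, voltage: float, patch: int) -> int:
    mi = list(MEMBRANES).index(membrane)
    vi = VOLTAGES.index(voltage)
    return 7000 + (mi * len(VOLTAGES) + vi) * N_PATCHES + patch


def simulate_patch(membrane: str, voltage: float, patch: int):
    """Returns (trace, dwell_durations, dwell_open_mask, scheme)."""
    scheme = scheme_at(voltage)
    amp = MEMBRANES[membrane]
    mod = ModulationSpec(hurst_target=0.8, amplitude=amp)
    events_per_s = 2.0 / (1.0 / scheme.exit_rates[0] + 1.0 / scheme.exit_rates[1])
    duration = TARGET_EVENTS / events_per_s
    seed = patch_seed(membrane, voltage, patch)
    traj = simulate_modulated_gating(scheme, mod, duration, seed=seed)
    cfg = SimulationConfig(n_samples=N_RENDER, dt=DT,
                           noise_sigma=NOISE_SIGMA, seed=seed + 1)
    trace = render_current(traj, scheme, cfg)
    durations, states = traj.sojourns()
    return trace, durations, scheme.is_open[states], scheme


def iter_conditions():
    for membrane in MEMBRANES:
        for voltage in VOLTAGES:
            for patch in range(N_PATCHES):
                yield membrane, voltage, patch
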