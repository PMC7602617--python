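import numpy as np
import pytest

from chanmem.core import CurrentTrace
from chanmem.sim import (
    SimulationConfig,
    render_current,
    simulate_markov_gating,
    two_state_scheme,
)


@pytest.fixture(scope="session")
def symmetric_scheme():
    return two_state_scheme(50.0, 50.0)


@pytest.fixture(scope="session")
def asymmetric_scheme():
    # stationary p_open = 90/(90+10) = 0.9
    return two_state_scheme(k_closed_to_open=90.0, k_open_to_closed=10.0)


@pytest.fixture(scope="session")
def simulated_trace(symmetric_scheme):
    """Noisy two-level trace with its ground-truth per-sample labels."""
    traj = simulate_markov_gating(symmetric_scheme, 3.0, seed=42)
    cfg = SimulationConfig(n_samples=2**13, dt=250e-6, noise_sigma=1.0, seed=43)
    trace = render_current(traj, symmetric_scheme, cfg)
    truth = symmetric_scheme.is_open[
        traj.state_at(np.arange(cfg.n_samples) * cfg.dt)
    ]
    return trace, truth


@pytest.fixture(scope="session")
def bimodal_trace():
    """Balanced two-Gaussian mixture at 0 and 10 pA."""
    rng = np.random.default_rng(7)
    x = rng.permutation(np.concatenate([
        rng.normal(0.0, 1.0, 30000), rng.normal(10.0, 1.0, 30000),
    ]))
    return CurrentTrace(samples=x, dt=250e-6)
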