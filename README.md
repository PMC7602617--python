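# chanmem

Short- and long-range correlation analysis of single ion-channel gating.

Single-channel patch-clamp recordings of large-conductance Ca²⁺- and
voltage-activated potassium (BK) channels switch stochastically between a
conducting (open) and a non-conducting (closed) level. Beyond the classical
kinetic summaries (open probability, dwell-time distributions), the *ordering*
of the signal carries information about the gating machinery: whether long
sojourns tend to follow long ones, and whether that tendency persists across
time scales. `chanmem` implements the full analysis chain used to quantify
such memory effects, together with gating simulators that provide ground
truth, so every estimator can be validated without access to recordings:

- **Idealization** by the threshold-current (TC) algorithm: an Epanechnikov
  kernel density of the current amplitudes is bimodal; on log-log axes the
  inner flanks of the two modes follow power laws, and the TC is the current
  at which the fitted power laws intersect. Samples above/below the TC (with
  an explicit sign convention for negative potentials) become the binary
  open/closed state sequence.
- **Conditional mean dwell-times**: the mean duration of a state binned by
  the duration of the immediately preceding opposite state (5 ms bins,
  empty bins exported as −1) — flat for a memoryless two-state channel,
  structured when substates of contrasting lifetime are coupled in loops.
- **Rescaled-range (R/S) analysis**: per segment of length *s*, the range
  *R* of the cumulative mean-adjusted series rescaled by the segment SD *S*;
  the Hurst exponent *H* is the slope of log⟨R/S⟩(s) = H log s + log c over
  power-of-two scales. H = 0.5 is memoryless, H > 0.5 persistent.
- **Detrended fluctuation analysis (DFA)**: profile
  y_i = Σ_{j≤i}(x_j − ⟨x⟩), per-segment linear detrending, fluctuation
  function f(s) = √(mean F²(s,v)); the scaling exponent α is the log-log
  slope. α ≈ H for stationary series; α > 1 flags nonstationarity.
- **Focus-based multifractal DFA (MFDFA)**: the q-th order scaling function
  G(q,s) (two-sided segmentation, log-mean exponential form at q = 0) is
  regressed on log s with all q-wise fits constrained through a common
  focus at s = N. From H(q): τ(q) = qH(q) − 1, h(q) = dτ/dq,
  D(h) = qh(q) − τ(q), and the spectrum width Δ = h_max − h_min, a proxy
  for gating complexity.
- **Controls and statistics**: shuffling (permutation) controls that must
  drive H and α to the uncorrelated baseline and narrow Δ; exact
  Mann–Whitney U tests for the small per-condition patch counts typical of
  patch-clamp work; median aggregation per membrane type.
- **Simulators**: exact (Gillespie) continuous-time Markov gating for
  arbitrary schemes; a time-inhomogeneous variant whose rates are modulated
  by a slow long-range-correlated side-process (sampled exactly by
  thinning), which induces Hurst-type memory in the dwell-time series;
  exact fractional Gaussian noise (circulant embedding) and binomial
  multiplicative cascades as estimator oracles with closed-form exponents.

## Worked example

```python
import numpy as np
from chanmem.sim import (two_state_scheme, ModulationSpec, SimulationConfig,
                         simulate_modulated_gating, render_current)
from chanmem.idealize import (estimate_current_pdf, detect_threshold,
                              idealize_trace, open_probability)
from chanmem.longmemory import rs_hurst, dfa
from chanmem.controls import shuffle_series

scheme = two_state_scheme()                      # C <-> O, 20 ms mean dwells
mod = ModulationSpec(hurst_target=0.8, amplitude=0.5)
traj = simulate_modulated_gating(scheme, mod, duration=130.0, seed=1)

cfg = SimulationConfig(n_samples=2**13, dt=250e-6, noise_sigma=1.0, seed=2)
trace = render_current(traj, scheme, cfg)        # 2.05 s of noisy current

pdf = estimate_current_pdf(trace)
thr = detect_threshold(pdf)
states = idealize_trace(trace, thr.tc)
print(f"threshold current: {thr.tc:.2f} pA, p_open = {open_probability(states):.3f}")

dwells = traj.sojourns()[0][1:-1][:2**12]        # dwell-time series, N = 2^12
for name, x in [("current", trace.samples), ("dwell", dwells)]:
    h, a = rs_hurst(x).exponent, dfa(x).exponent
    hs = rs_hurst(shuffle_series(x, seed=3)).exponent
    print(f"{name:8s} H_RS = {h:.3f}  alpha_DFA = {a:.3f}  shuffled H_RS = {hs:.3f}")
```

prints

```
threshold current: 5.02 pA, p_open = 0.453
current  H_RS = 0.953  alpha_DFA = 1.083  shuffled H_RS = 0.538
dwell    H_RS = 0.767  alpha_DFA = 0.724  shuffled H_RS = 0.485
```

The threshold lands midway between the 0 and 10 pA levels. The slowly
modulated channel produces strongly persistent current series (α > 1:
nonstationary at this length) and persistent dwell-time series
(H, α ≈ 0.72–0.77 ≫ 0.5), while shuffling collapses both to the
uncorrelated baseline — the signature that the memory lives in the
ordering, not the amplitude distribution.

## The analysis scripts

`analysis/01…06` run a complete synthetic study over a cohort of simulated
patches (two membrane populations differing in modulation strength, five
voltages, four patches each): simulation, idealization + activation-curve
fits, conditional dwell-time arrays, R/S + DFA exponent tables with
Mann–Whitney membrane comparisons, MFDFA spectrum widths, and shuffling
controls. Each script prints its findings and writes tidy CSV tables under
`results/` (traces live under `scratch/`, which is not part of the
repository). A `chanmem` command-line tool exposes the same stages for
single files (`chanmem simulate`, `idealize`, `dwell`, `conditional`, `rs`,
`dfa`, `mfdfa`, `shuffle-control`, `compare`, `pipeline`).

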