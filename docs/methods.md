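# Methods

This note records the models, conventions and numerical choices behind
`chanmem`, in the order of the analysis chain.

## Gating simulators

**Homogeneous gating.** A gating scheme is a continuous-time Markov chain
(CTMC) given by its generator matrix Q (rates in 1/s), a class label
(open/closed) per state, and two conductance levels. Simulation is exact
and event-driven (Gillespie): sojourn times are exponential with the
state's exit rate, jumps follow the embedded-chain probabilities, and the
initial state is drawn from the stationary distribution so sample paths
are stationary from t = 0. Discretization happens only at rendering time,
so dwell-time distributions are exact. Schemes are validated for
irreducibility (strong connectivity of the rate graph) and absence of
absorbing states. Three presets cover the cases of interest: a symmetric
two-state scheme C ⇌ O with 20 ms mean dwells (memoryless reference), a
four-state biased cycle O_long → C_short → O_short → C_long → O_long in
which contrasting-lifetime substates are coupled in a loop (the minimal
scheme with adjacent dwell-time correlations — a cycle with broken
detailed balance), and an illustrative 3-open/5-closed BK-type scheme
with lifetimes spanning 1–100 ms.

**Rate-modulated gating.** Long-range memory in dwell-time series cannot
arise from a finite homogeneous Markov scheme; it is modelled here as a
slow side-process multiplying *all* rates by m(t) = exp(a·z(t)), where
z(t) is a boxcar-smoothed, variance-normalized fractional Gaussian noise
path of Hurst index H_mod on a grid of step (correlation time)/4. The
defaults — H_mod = 0.8, log-amplitude a = 0.5, correlation time 0.1 s —
make the modulator slow relative to the 20 ms mean dwell while leaving
thousands of correlation times inside a 130 s recording. Because m(t)
scales every rate, the embedded-chain jump probabilities are unchanged and
the path can be sampled exactly by thinning: candidate events are proposed
at the bounding rate (exit rate × max m over the realized path) and
accepted with probability m(t)/max m. The multiplier is strictly positive
by construction; a = 0 recovers the homogeneous chain exactly. The
mechanism (e.g. membrane-thickness fluctuations near the channel) is a
hypothesis, and the modulation parameters are a modelling choice, not
values constrained by data.

**Rendering.** All open states share one conductance level (binary
rendering, matching the binary idealization; per-state levels would be
collapsed by thresholding anyway). Samples at 4 kHz (dt = 250 µs) receive
i.i.d. Gaussian noise of SD 1 pA — one tenth of the 10 pA single-channel
amplitude. A 4-pole Bessel-style low-pass emulating the recording filter
is available but off by default, since filtering interacts with event
detection and is a user choice.

**Reference series.** Fractional Gaussian noise is synthesized exactly by
circulant embedding of the closed-form autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) (an error is raised if the
embedding is not positive semi-definite). The binomial multiplicative
cascade splits mass (a, 1−a) at each of L dyadic refinements in random
order; its mass exponent is analytically τ(q) = −log₂(a^q + (1−a)^q),
which makes it the oracle for the multifractal pipeline. Weight a = 0.5
is allowed as the degenerate monofractal (uniform) case.

## Idealization

The current-amplitude density is estimated with an Epanechnikov kernel by
binned convolution on a 512-point grid (exact up to grid resolution,
O(N + grid) for long traces), bandwidth by a Silverman-type rule with the
Epanechnikov constant 2.345·min(SD, IQR/1.349)·n^{−1/5}. The two modes
are the most prominent density peaks; on each inner flank (between mode
and valley) log₁₀(density) is regressed on log₁₀|I − mode| over the
sliding window (≥ 5 grid points) that maximizes R², restricted to
decaying slopes; user-supplied search intervals override the automatic
windows. The threshold current is the root of the difference of the two
fitted power laws between the modes (Brent bracketing). Sign convention:
at negative potentials currents are negative; the pipeline rectifies
using the sign of (open level − closed level), by default taking the mode
farther from zero as the conducting level. No missed-event correction is
applied; the minimum event duration is one sample.

Activation curves are least-squares Boltzmann fits
p(U) = p_max / (1 + exp(−(U − V½)/k)) with p_max fixed at 1 by default;
non-monotone point sets are fitted but flagged.

## Dwell-time statistics

Dwell-time series are the run-length encoding of the state sequence
(duration = run length × dt). The first and last sojourns of a finite
recording are boundary-censored — their true length is unknown — and are
flagged and excluded from distribution statistics by default.
Conditional mean dwell-time arrays use half-open 5 ms bins indexed by
⌊t_prev/5 ms⌋; each target-state sojourn contributes its duration to the
bin of the preceding opposite-state duration; means are accumulated sums
over counts, and the per-bin uncertainty is the SEM of the pooled event
set. Arrays extend to the 99.5th percentile of preceding durations;
overflow events pool into the last bin and flag the array. Cross-patch
aggregation sums the raw accumulators (identical to pooling events).
Empty bins carry the sentinel −1 only in exported tables; internally
counts are kept separate. Adjacent-state memory is summarized by the
Spearman correlation between each sojourn and its successor.

## R/S and DFA

Both estimators tile the series into non-overlapping power-of-two
segments from the series start (the tail shorter than s is dropped) and
fit an unweighted ordinary least-squares line to (log₂ s, log₂ statistic).
R/S uses the population (1/s) segment SD, drops zero-variance segments
with a warning, and errors on constant input. DFA subtracts a per-segment
linear trend from the profile (order-1 only; higher orders are out of
scope) and averages residual variances. Dwell-time series are analyzed in
seconds as-is (no log transform); their non-normality is expected and is
why shuffled dwell series need not land exactly on the Gaussian baseline.

**Scale range.** The fitted scale range is a free parameter of both
estimators and the main driver of their small-sample bias. Calibration on
exact fGn (N = 2¹³, 50 seeds, H ∈ {0.3, 0.5, 0.7, 0.9}) shows DFA is
essentially unbiased with scales 2³…N/4 (≤ 0.01 error at every H), while
R/S with s_min = 2³ is biased toward 0.5 by up to 0.08 at H = 0.3; raising
s_min to 2⁵ halves that bias without losing stability. The defaults are
therefore: R/S 2⁵…N/4, DFA 2³…N/4, MFDFA 2⁴…N/4 (short segments are
unstable at large |q|). No Anis–Lloyd-type analytic correction is applied
to the R/S statistic itself.

**Standard lengths.** Analyses run on non-overlapping chunks of fixed
lengths — 2¹² for all-states dwell series, 2¹¹ for single-state dwell
series, 2¹³ for current series, 2¹⁵ for MFDFA — so exponents from
different recordings are comparable; longer recordings contribute several
independent chunks.

## Focus-based MFDFA

Segment variances are computed over segments tiled from both the series
start and end (2·n_s segments per scale). The scaling function is the
q/2-order power mean of the variances, G(q,s) = (mean [F²]^{q/2})^{1/q},
with the log-mean exponential form exp(½·mean ln F²) at q = 0; all means
are evaluated in log space (log-sum-exp) so |q| = 5 stays stable. Note
G(q,s) is *nondecreasing* in q at fixed s, by the power-mean inequality.
The default q grid is −5…+5 in steps of 0.5; moderate |q| avoids moment
divergence on heavy-tailed inputs.

H(q) comes from the focus-based regression: all q-wise lines
log₂ G(q,s) = focus + H(q)(log₂ s − log₂ N) share one intercept — the
focus — at s = N, estimated jointly by linear least squares over all
(q, s) pairs (a (n_q·n_s) × (n_q+1) system). If the joint system is
singular the fit falls back, flagged, to independent per-q lines. The
spectrum follows as τ(q) = qH(q) − 1, h(q) = dτ/dq by central finite
differences (one-sided at the ends; no parametric form is imposed on τ),
D(h) = qh(q) − τ(q), and Δ = h_max − h_min over the q grid. τ(0) = −1 and
D(h(0)) = 1 hold identically; a convexity violation of τ flags the
spectrum as inverted rather than erroring. Δ depends on both the q range
and the scale range, so widths are only comparable within one
configuration.

On weight-0.75 cascades of length 2¹⁵ the pipeline recovers τ(2) within
±0.05 of −log₂(0.625) and Δ within ±0.15 of the analytic h(−5) − h(5);
on monofractal fGn the apparent width stays below 0.2 — the finite-sample
width floor of the estimator at this length.

## Controls and statistics

Shuffling draws a uniform permutation (seeded, multiset preserved
exactly). For any estimator-consistency claim the shuffled series is the
null reference: H and α must return to the uncorrelated baseline and Δ
must shrink. The Mann–Whitney U test is exact by enumeration of all
label assignments (ties via midranks; two-sided p as the probability of a
U at least as extreme as observed) for combined n ≤ 20 — patch-clamp
group sizes are typically 3–7 per condition — and uses the normal
approximation with tie correction above that. The package-wide
significance level is 0.05 with no multiple-testing correction; exponent
tables aggregate medians per (membrane, method, signal variant) pooling
voltages and patches, with outliers counted by the 1.5·IQR box-plot
convention. Shapiro–Wilk normality screening is exposed as a pass-through
diagnostic only.

## Synthetic study conditions

The acceptance computation and the analysis scripts run under fixed
conditions defined in `chanmem.study`: symmetric two-state scheme, slow
modulation (H_mod = 0.8, a = 0.5), 4 kHz sampling, 1 pA noise, 20 patches,
current series of 2¹³ samples and dwell series of 2¹² sojourns (~130 s of
gating per patch). The cohort in `analysis/` adds two membrane
populations that differ only in modulation amplitude (0.3 vs 0.6) and
per-voltage Boltzmann rates (V½ = 0 mV, k = 25 mV) spanning open
probabilities from below 0.1 at −60 mV to above 0.9 at +60 mV.

## What the synthetic data does and does not show

The generator reproduces the features the estimators rely on: two-level
currents with Gaussian noise, exponential-mixture dwell distributions,
voltage-dependent open probability, and tunable long-range memory with
known ground truth. It does not reproduce open-channel noise in excess of
baseline noise, filter rise-time distortion of brief events, baseline
drift, sub-conductance levels, or multi-channel patches. Passing tests
therefore validate the estimator chain, not any claim about real
recordings; conclusions about actual mitochondrial vs plasma-membrane
channels require data.

## Known limitations

- R/S retains a residual small-sample bias toward 0.5 at |H − 0.5| ≳ 0.3
  even with the calibrated scale range; DFA is the more accurate of the
  two, consistent with its use as the primary estimator.
- The modulated simulator's dwell-series exponent depends on the
  interplay of modulation amplitude and intrinsic exponential
  variability; it approaches H_mod only asymptotically in amplitude.
- Idealization assumes exactly two conductance levels and a stationary
  baseline.
- ABF (Axon Binary Format) input is not supported; recordings must be
  exported to CSV.
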