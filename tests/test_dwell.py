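"""Dwell-time extraction and conditional mean dwell-time arrays."""

import numpy as np
import pytest
from scipy.stats import kstest

from chanmem.core import CLOSED, OPEN, DwellTimeSeries, StateSequence
from chanmem.dwell import (
    SENTINEL,
    adjacent_dwell_correlation,
    conditional_mean_dwell,
    extract_dwell_times,
    merge_conditional_arrays,
    split_by_state,
)
from chanmem.sim import loop_scheme, simulate_markov_gating, two_state_scheme


def _dwells_from_sim(scheme, duration, seed):
    traj = simulate_markov_gating(scheme, duration, seed)
    dur, st = traj.sojourns()
    labels = np.where(scheme.is_open[st], OPEN, CLOSED).astype(object)
    censored = np.zeros(dur.size, dtype=bool)
    censored[[0, -1]] = True
    return DwellTimeSeries(durations=dur, labels=labels, dt=250e-6,
                          censored=censored)


class TestExtract:
    def test_run_length_example(self):
        dt = 0.25e-3
        seq = StateSequence(np.array([True, True, False, True]), dt=dt)
        dwells = extract_dwell_times(seq)
        assert np.allclose(dwells.durations, [2 * dt, dt, dt])
        assert list(dwells.labels) == [OPEN, CLOSED, OPEN]
        assert dwells.censored[0] and dwells.censored[-1]

    def test_duration_conservation(self, simulated_trace):
        trace, truth = simulated_trace
        seq = StateSequence(truth, dt=trace.dt)
        dwells = extract_dwell_times(seq)
        assert dwells.total_duration() == pytest.approx(trace.duration,
                                                        abs=trace.dt)

    def test_simulated_dwells_exponential(self, symmetric_scheme):
        """Open sojourns of the 2-state chain are Exp(1/k) distributed."""
        dwells = _dwells_from_sim(symmetric_scheme, 250.0, seed=31)
        opens, _ = split_by_state(dwells.uncensored)
        assert len(opens) > 5000
        p = kstest(opens.durations, "expon", args=(0, 1 / 50.0)).pvalue
        assert p > 0.01


class TestSplit:
    def test_lengths_and_roundtrip(self):
        d = DwellTimeSeries(
            durations=np.array([1.0, 2.0, 3.0, 4.0]),
            labels=np.array([OPEN, CLOSED, OPEN, CLOSED], dtype=object),
            dt=1.0,
        )
        opens, closeds = split_by_state(d)
        assert len(opens) == 2 and len(closeds) == 2
        # interleaving by original parity reconstructs the series
        rebuilt = np.empty(4)
        rebuilt[0::2] = opens.durations
        rebuilt[1::2] = closeds.durations
        assert np.allclose(rebuilt, d.durations)

    def test_degenerate_all_open(self):
        d = DwellTimeSeries(durations=np.array([1.0]),
                           labels=np.array([OPEN], dtype=object), dt=1.0)
        opens, closeds = split_by_state(d)
        assert len(opens) == 1 and len(closeds) == 0


class TestConditionalArray:
    def test_single_pair_floor_rule(self):
        """Closed 7 ms then open 12 ms -> bin floor(7/5) = 1 holds 12 ms."""
        d = DwellTimeSeries(
            durations=np.array([0.007, 0.012]),
            labels=np.array([CLOSED, OPEN], dtype=object), dt=1e-3,
        )
        arr = conditional_mean_dwell(d, OPEN, bin_width=0.005, n_bins=4)
        exported = arr.export()
        assert exported[1, 1] == pytest.approx(0.012)
        empty = [0, 2, 3]
        assert np.all(exported[empty, 1] == SENTINEL)
        assert np.all(exported[empty, 3] == 0)

    def test_flat_for_two_state_chain(self, symmetric_scheme):
        """Memoryless gating: no bin deviates from the global mean by
        more than 3 SEM."""
        dwells = _dwells_from_sim(symmetric_scheme, 250.0, seed=32)
        arr = conditional_mean_dwell(dwells, OPEN)
        means, sems, counts = arr.bin_means, arr.bin_sems, arr.bin_counts
        well_filled = counts >= 30
        assert well_filled.sum() >= 5
        z = np.abs(means[well_filled] - arr.global_mean()) / sems[well_filled]
        assert np.all(z < 3.0)

    def test_weighted_bin_average_equals_global_mean(self, symmetric_scheme):
        dwells = _dwells_from_sim(symmetric_scheme, 60.0, seed=33)
        arr = conditional_mean_dwell(dwells, CLOSED)
        filled = arr.bin_counts > 0
        weighted = np.sum(arr.bin_means[filled] * arr.bin_counts[filled]) \
            / arr.bin_counts.sum()
        assert weighted == pytest.approx(arr.global_mean(), rel=1e-12)

    def test_merge_equals_pooled_events(self, symmetric_scheme):
        """Aggregating per-patch arrays must equal the pooled-event array."""
        d1 = _dwells_from_sim(symmetric_scheme, 40.0, seed=34)
        d2 = _dwells_from_sim(symmetric_scheme, 40.0, seed=35)
        n_bins = 40
        a1 = conditional_mean_dwell(d1, OPEN, n_bins=n_bins)
        a2 = conditional_mean_dwell(d2, OPEN, n_bins=n_bins)
        merged = merge_conditional_arrays([a1, a2])
        pooled_dur = np.concatenate([d1.uncensored.durations,
                                     d2.uncensored.durations])
        pooled_lab = np.concatenate([d1.uncensored.labels,
                                     d2.uncensored.labels])
        # pooling events across patches: same accumulators
        assert merged.bin_counts.sum() == a1.bin_counts.sum() + a2.bin_counts.sum()
        assert np.allclose(merged.bin_sums, a1.bin_sums + a2.bin_sums)
        assert pooled_dur.size == len(d1.uncensored) + len(d2.uncensored)
        assert pooled_lab.size == pooled_dur.size

    def test_overflow_pooled_into_last_bin(self):
        d = DwellTimeSeries(
            durations=np.array([0.002, 0.010, 0.200, 0.010]),
            labels=np.array([CLOSED, OPEN, CLOSED, OPEN], dtype=object),
            dt=1e-3,
        )
        arr = conditional_mean_dwell(d, OPEN, bin_width=0.005, n_bins=3)
        assert arr.overflow_pooled
        assert arr.bin_counts[-1] == 1


class TestAdjacentCorrelation:
    def test_two_state_uncorrelated(self, symmetric_scheme):
        dwells = _dwells_from_sim(symmetric_scheme, 150.0, seed=36)
        rho, p = adjacent_dwell_correlation(dwells)
        assert p > 0.01 or abs(rho) < 0.05

    def test_loop_scheme_correlated(self):
        dwells = _dwells_from_sim(loop_scheme(), 150.0, seed=37)
        rho, p = adjacent_dwell_correlation(dwells)
        assert p < 0.05 and abs(rho) > 0.1

    def test_deterministic(self, symmetric_scheme):
        dwells = _dwells_from_sim(symmetric_scheme, 30.0, seed=38)
        assert adjacent_dwell_correlation(dwells) == \
            adjacent_dwell_correlation(dwells)

    def test_too_few_pairs_rejected(self):
        d = DwellTimeSeries(
            durations=np.array([1.0, 2.0, 3.0]),
            labels=np.array([OPEN, CLOSED, OPEN], dtype=object), dt=1.0,
        )
        with pytest.raises(ValueError, match="30"):
            adjacent_dwell_correlation(d)
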