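"""Gating simulators and reference series against closed-form laws."""

import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from chanmem.core import CLOSED, OPEN
from chanmem.sim import (
    GatingScheme,
    ModulationSpec,
    SimulationConfig,
    fgn_autocovariance,
    generate_cascade,
    generate_fgn,
    loop_scheme,
    render_current,
    simulate_markov_gating,
    simulate_modulated_gating,
    two_state_scheme,
)


def _occupied_fraction(traj, scheme):
    dur, st = traj.sojourns()
    return dur[scheme.is_open[st]].sum() / traj.total_duration


class TestSchemeValidation:
    def test_absorbing_state_rejected(self):
        rates = np.array([[-1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="absorbing"):
            GatingScheme(("C", "O"), (CLOSED, OPEN), rates)

    def test_non_irreducible_rejected(self):
        # two disconnected pairs
        off = np.zeros((4, 4))
        off[0, 1] = off[1, 0] = off[2, 3] = off[3, 2] = 1.0
        rates = off - np.diag(off.sum(axis=1))
        with pytest.raises(ValueError, match="irreducible"):
            GatingScheme(("C1", "O1", "C2", "O2"),
                         (CLOSED, OPEN, CLOSED, OPEN), rates)

    def test_needs_both_classes(self):
        off = np.array([[0.0, 1.0], [1.0, 0.0]])
        rates = off - np.diag(off.sum(axis=1))
        with pytest.raises(ValueError, match="open and one closed"):
            GatingScheme(("O1", "O2"), (OPEN, OPEN), rates)

    def test_bad_diagonal_rejected(self):
        rates = np.array([[-2.0, 1.0], [1.0, -1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            GatingScheme(("C", "O"), (CLOSED, OPEN), rates)


class TestMarkovGating:
    @pytest.mark.parametrize("k_co,k_oc,duration,expected,tol", [
        (50.0, 50.0, 200.0, 0.5, 0.02),   # symmetric rates
        (90.0, 10.0, 500.0, 0.9, 0.02),   # stationary k_co/(k_co+k_oc)
    ])
    def test_time_fraction_open_matches_stationary(self, k_co, k_oc,
                                                   duration, expected, tol):
        scheme = two_state_scheme(k_co, k_oc)
        traj = simulate_markov_gating(scheme, duration, seed=11)
        assert _occupied_fraction(traj, scheme) == pytest.approx(expected,
                                                                 abs=tol)

    def test_sojourns_exponential(self, symmetric_scheme):
        """CTMC sojourn law: open dwells ~ Exp(k_open_to_closed)."""
        traj = simulate_markov_gating(symmetric_scheme, 250.0, seed=12)
        dur, st = traj.sojourns()
        open_d = dur[:-1][symmetric_scheme.is_open[st[:-1]]]
        assert open_d.size > 5000
        assert np.mean(open_d) == pytest.approx(1 / 50.0, rel=0.05)
        p = kstest(open_d, "expon", args=(0, 1 / 50.0)).pvalue
        assert p > 0.01

    def test_stationary_occupancy_within_3se(self):
        scheme = loop_scheme()
        pi = scheme.stationary_distribution()
        traj = simulate_markov_gating(scheme, 400.0, seed=13)
        dur, st = traj.sojourns()
        occ = np.bincount(st, weights=dur, minlength=4) / traj.total_duration
        # SE of an occupancy fraction from n_eff ~ number of sojourns
        se = np.sqrt(pi * (1 - pi) / traj.n_events) * 2.0
        assert np.all(np.abs(occ - pi) < 3 * np.maximum(se, 1e-3))

    def test_deterministic_for_fixed_seed(self, symmetric_scheme):
        a = simulate_markov_gating(symmetric_scheme, 5.0, seed=99)
        b = simulate_markov_gating(symmetric_scheme, 5.0, seed=99)
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.event_states, b.event_states)

    def test_two_state_adjacent_dwells_uncorrelated(self, symmetric_scheme):
        traj = simulate_markov_gating(symmetric_scheme, 150.0, seed=14)
        dur, _ = traj.sojourns()
        rho, p = spearmanr(dur[1:-2], dur[2:-1])
        assert p > 0.01 or abs(rho) < 0.05

    def test_loop_scheme_adjacent_dwells_correlated(self):
        traj = simulate_markov_gating(loop_scheme(), 150.0, seed=15)
        dur, st = traj.sojourns()
        is_open = loop_scheme().is_open[st]
        # closed duration -> following open duration
        idx = np.flatnonzero(is_open[1:-1]) + 1
        rho, p = spearmanr(dur[idx - 1], dur[idx])
        assert p < 0.05 and abs(rho) > 0.1


class TestModulatedGating:
    def test_zero_amplitude_behaves_like_markov(self, symmetric_scheme):
        mod = ModulationSpec(hurst_target=0.8, amplitude=0.0)
        traj = simulate_modulated_gating(symmetric_scheme, mod, 150.0, seed=16)
        frac = _occupied_fraction(traj, symmetric_scheme)
        assert frac == pytest.approx(0.5, abs=0.03)
        dur, _ = traj.sojourns()
        assert np.mean(dur[1:-1]) == pytest.approx(0.02, rel=0.1)

    def test_modulation_induces_persistent_dwells(self, symmetric_scheme):
        from chanmem.longmemory import dfa
        mod = ModulationSpec(hurst_target=0.8, amplitude=0.5)
        traj = simulate_modulated_gating(symmetric_scheme, mod, 110.0, seed=17)
        dur, _ = traj.sojourns()
        dw = dur[1:-1][:2**12]
        assert dw.size == 2**12
        assert dfa(dw).exponent > 0.55

    def test_deterministic_for_fixed_seed(self, symmetric_scheme):
        mod = ModulationSpec()
        a = simulate_modulated_gating(symmetric_scheme, mod, 5.0, seed=18)
        b = simulate_modulated_gating(symmetric_scheme, mod, 5.0, seed=18)
        assert np.array_equal(a.event_times, b.event_times)


class TestRenderCurrent:
    def test_noiseless_two_level(self, symmetric_scheme):
        traj = simulate_markov_gating(symmetric_scheme, 1.0, seed=19)
        cfg = SimulationConfig(n_samples=2048, dt=250e-6, noise_sigma=0.0)
        trace = render_current(traj, symmetric_scheme, cfg)
        assert set(np.unique(trace.samples)) <= {0.0, 10.0}

    def test_noisy_histogram_bimodal(self, symmetric_scheme):
        traj = simulate_markov_gating(symmetric_scheme, 3.0, seed=20)
        cfg = SimulationConfig(n_samples=2**13, dt=250e-6, noise_sigma=1.0,
                               seed=21)
        trace = render_current(traj, symmetric_scheme, cfg)
        counts, edges = np.histogram(trace.samples, bins=60)
        centers = 0.5 * (edges[1:] + edges[:-1])
        near0 = counts[np.abs(centers - 0.0) < 1.0].max()
        near10 = counts[np.abs(centers - 10.0) < 1.0].max()
        mid = counts[np.abs(centers - 5.0) < 1.5].max()
        assert near0 > 3 * mid and near10 > 3 * mid

    def test_all_open_mean_near_open_level(self, asymmetric_scheme):
        traj = simulate_markov_gating(asymmetric_scheme, 1.0, seed=22,
                                      start_state=1)
        cfg = SimulationConfig(n_samples=512, dt=1e-5, noise_sigma=0.1, seed=23)
        trace = render_current(traj, asymmetric_scheme, cfg)
        assert trace.samples.mean() == pytest.approx(10.0, abs=0.5)

    def test_short_trajectory_rejected(self, symmetric_scheme):
        traj = simulate_markov_gating(symmetric_scheme, 0.1, seed=24)
        cfg = SimulationConfig(n_samples=2**13, dt=250e-6)
        with pytest.raises(ValueError, match="covers"):
            render_current(traj, symmetric_scheme, cfg)


class TestFgn:
    def test_white_noise_limit(self):
        x = generate_fgn(2**12, 0.5, seed=30)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(x.size)

    def test_lag1_autocorrelation_h08(self):
        # gamma(1) = 2^1.6/2 - 1 ~ 0.5157 at H = 0.8
        vals = []
        for seed in range(10):
            x = generate_fgn(2**13, 0.8, seed=seed)
            vals.append(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert np.mean(vals) == pytest.approx(2**1.6 / 2 - 1, abs=0.03)

    def test_autocovariance_matches_closed_form(self):
        """Sample autocovariance at lags 0-5 within 3 SE over 100 seeds.

        The process is synthesized with exact zero mean, so the uncentered
        estimator applies; centering at the sample mean would introduce
        the well-known O(n^(2H-2)) long-range-dependence bias.
        """
        lags = np.arange(6)
        target = fgn_autocovariance(lags, 0.7)
        n = 2**11
        est = np.empty((100, lags.size))
        for seed in range(100):
            x = generate_fgn(n, 0.7, seed=seed)
            est[seed] = [np.dot(x[:n - k], x[k:]) / n for k in lags]
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / 10.0
        assert np.all(np.abs(mean - target) < 3 * se)

    def test_deterministic_and_bounds(self):
        assert np.array_equal(generate_fgn(64, 0.6, seed=1),
                              generate_fgn(64, 0.6, seed=1))
        with pytest.raises(ValueError):
            generate_fgn(8, 0.5, seed=0)
        with pytest.raises(ValueError):
            generate_fgn(64, 1.5, seed=0)


class TestCascade:
    def test_weight_half_is_uniform(self):
        x = generate_cascade(10, 0.5, seed=0)
        assert np.allclose(x, 1.0)

    def test_weight_bounds(self):
        with pytest.raises(ValueError):
            generate_cascade(10, 0.4, seed=0)
        with pytest.raises(ValueError):
            generate_cascade(10, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_cascade(4, 0.75, seed=0)

    def test_partition_function_mass_exponent(self):
        """Direct box-counting on the cascade recovers
        tau(q) = -log2(a^q + (1-a)^q)."""
        a = 0.75
        levels = 14
        x = generate_cascade(levels, a, seed=3)
        mu = x / x.sum()
        qs = np.array([-3.0, -1.0, 1.0, 2.0, 3.0])
        taus = []
        box_exps = np.arange(2, 9)
        for q in qs:
            log_z = []
            for be in box_exps:
                boxes = mu.reshape(-1, 2**be).sum(axis=1)
                log_z.append(np.log2(np.sum(boxes**q)))
            slope = np.polyfit(box_exps - levels, log_z, 1)[0]
            taus.append(slope)
        target = -np.log2(a**qs + (1 - a) ** qs)
        assert np.allclose(taus, target, atol=0.1)

    def test_deterministic(self):
        assert np.array_equal(generate_cascade(10, 0.7, seed=5),
                              generate_cascade(10, 0.7, seed=5))
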