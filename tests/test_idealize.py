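"""Threshold-current idealization and activation-curve fitting."""

import numpy as np
import pytest

from chanmem.core import CurrentTrace
from chanmem.idealize import (
    detect_threshold,
    estimate_current_pdf,
    fit_activation_curve,
    idealize_trace,
    infer_sign,
    open_probability,
)


class TestCurrentPdf:
    def test_constant_trace_rejected(self):
        trace = CurrentTrace(np.full(5000, 3.0), dt=1e-3)
        with pytest.raises(ValueError, match="zero-variance"):
            estimate_current_pdf(trace)

    def test_density_normalized(self, bimodal_trace):
        pdf = estimate_current_pdf(bimodal_trace)
        assert pdf.integral() == pytest.approx(1.0, abs=0.01)
        assert np.all(pdf.density >= 0)

    def test_two_modes_near_levels(self, bimodal_trace):
        from chanmem.idealize import _find_two_modes
        pdf = estimate_current_pdf(bimodal_trace)
        i, j = _find_two_modes(pdf)
        assert pdf.grid[i] == pytest.approx(0.0, abs=0.5)
        assert pdf.grid[j] == pytest.approx(10.0, abs=0.5)

    def test_short_trace_warns(self):
        rng = np.random.default_rng(1)
        trace = CurrentTrace(rng.normal(size=500), dt=1e-3)
        with pytest.warns(UserWarning, match="fewer than 1000"):
            estimate_current_pdf(trace)


class TestDetectThreshold:
    def test_symmetric_mixture_midpoint(self, bimodal_trace):
        pdf = estimate_current_pdf(bimodal_trace)
        res = detect_threshold(pdf)
        assert res.tc == pytest.approx(5.0, abs=0.5)
        m_lo, m_hi = res.modes
        assert m_lo < res.tc < m_hi
        assert res.diagnostics["r2_left"] > 0.9
        assert res.diagnostics["r2_right"] > 0.9

    def test_agrees_with_density_minimum(self, bimodal_trace):
        """Brute-force check: for a symmetric mixture the TC sits at the
        density valley between the modes."""
        pdf = estimate_current_pdf(bimodal_trace)
        res = detect_threshold(pdf)
        between = (pdf.grid > 2.0) & (pdf.grid < 8.0)
        valley = pdf.grid[between][np.argmin(pdf.density[between])]
        assert res.tc == pytest.approx(valley, abs=0.75)

    def test_unimodal_rejected(self):
        rng = np.random.default_rng(2)
        trace = CurrentTrace(rng.normal(5.0, 1.0, 20000), dt=1e-3)
        pdf = estimate_current_pdf(trace)
        with pytest.raises(ValueError, match="bimodal"):
            detect_threshold(pdf)

    def test_user_supplied_intervals(self, bimodal_trace):
        pdf = estimate_current_pdf(bimodal_trace)
        res = detect_threshold(pdf, search_intervals=((1.5, 4.0), (6.0, 8.5)))
        assert res.tc == pytest.approx(5.0, abs=0.7)


class TestIdealize:
    def test_recovers_ground_truth(self, simulated_trace):
        """>= 99% per-sample accuracy at 10 sigma level separation."""
        trace, truth = simulated_trace
        pdf = estimate_current_pdf(trace)
        res = detect_threshold(pdf)
        states = idealize_trace(trace, res.tc, sign=infer_sign(pdf))
        assert np.mean(states.states == truth) >= 0.99

    def test_all_above_threshold_all_open(self):
        trace = CurrentTrace(np.linspace(6.0, 9.0, 100), dt=1e-3)
        states = idealize_trace(trace, 6.0)
        # first sample equals tc and is not strictly above it
        assert states.states[1:].all()

    def test_sign_flip_invariance(self, simulated_trace):
        trace, _ = simulated_trace
        pdf = estimate_current_pdf(trace)
        res = detect_threshold(pdf)
        labels = idealize_trace(trace, res.tc, sign=infer_sign(pdf)).states

        neg = trace.with_samples(-trace.samples)
        pdf_n = estimate_current_pdf(neg)
        res_n = detect_threshold(pdf_n)
        sign_n = infer_sign(pdf_n)
        assert sign_n == -1.0
        labels_n = idealize_trace(neg, res_n.tc, sign=sign_n).states
        assert np.array_equal(labels, labels_n)

    def test_threshold_outside_range_rejected(self):
        trace = CurrentTrace(np.array([0.0, 1.0, 2.0]), dt=1e-3)
        with pytest.raises(ValueError, match="outside"):
            idealize_trace(trace, 5.0)

    def test_open_probability(self, simulated_trace):
        trace, truth = simulated_trace
        pdf = estimate_current_pdf(trace)
        states = idealize_trace(trace, detect_threshold(pdf).tc)
        assert open_probability(states) == pytest.approx(truth.mean(),
                                                         abs=0.01)
        assert open_probability(
            idealize_trace(trace, trace.samples.min())) == pytest.approx(
                1.0, abs=0.01)


class TestActivationCurve:
    @staticmethod
    def _points(v_half, k, voltages=np.arange(-60, 61, 20)):
        p = 1.0 / (1.0 + np.exp(-(voltages - v_half) / k))
        return np.column_stack([voltages, p])

    def test_noiseless_self_consistency(self):
        fit = fit_activation_curve(self._points(0.0, 15.0))
        assert fit.v_half == pytest.approx(0.0, abs=0.5)
        assert fit.slope_k == pytest.approx(15.0, rel=0.05)
        assert not fit.flagged

    def test_activation_range_spans_low_to_high(self):
        """Open probability rises from below 0.1 to above 0.9 across
        -60..+60 mV, the physiological activation span."""
        pts = self._points(0.0, 15.0)
        fit = fit_activation_curve(pts)
        pred = fit.predict(np.array([-60.0, 60.0]))
        assert pred[0] < 0.1 and pred[1] > 0.9

    def test_symmetric_points_give_zero_vhalf(self):
        pts = np.array([[-30, 0.1], [-10, 0.35], [10, 0.65], [30, 0.9]])
        fit = fit_activation_curve(pts)
        assert fit.v_half == pytest.approx(0.0, abs=1.0)

    def test_non_monotone_points_flagged(self):
        pts = np.array([[-30, 0.2], [-10, 0.7], [10, 0.4], [30, 0.9]])
        with pytest.warns(UserWarning, match="non-monotone"):
            fit = fit_activation_curve(pts)
        assert fit.flagged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_activation_curve([(0, 0.5), (10, 0.6), (20, 0.8)])
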