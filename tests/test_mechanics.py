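"""Transpulmonary pressure, equation-of-motion fitting and pressure maxima."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peepflow.breaths import BreathSegment, detect_breaths, integrate_volume, select_breaths
from peepflow.errors import ConditioningError
from peepflow.mechanics import (
    analyze_breath,
    fit_equation_of_motion,
    ptp_max_summary,
    transpulmonary_series,
)
from peepflow.simulate import make_mechanics_breath, simulate_breath_dynamics

from conftest import neutral_animal  # noqa: F401  (fixtures via conftest)


class TestTranspulmonary:
    def test_difference(self):
        assert transpulmonary_series(np.array([10.0]), np.array([-3.0]))[0] == 13.0

    def test_identical_channels_zero(self):
        x = np.linspace(0, 5, 50)
        np.testing.assert_array_equal(transpulmonary_series(x, x), 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            transpulmonary_series(np.zeros(5), np.zeros(4))


class TestEquationOfMotionFit:
    def test_exact_recovery_on_noise_free_breath(self):
        p_tp, flow, vol, seg = make_mechanics_breath(20.0, 10.0, 2.0)
        fit = fit_equation_of_motion(p_tp, flow, vol, seg)
        assert fit.compliance_c == pytest.approx(20.0, rel=1e-6)
        assert fit.resistance_rrs == pytest.approx(10.0, rel=1e-6)
        assert fit.p0 == pytest.approx(2.0, rel=1e-6)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert not fit.rejected

    def test_noisy_fit_equals_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        p_tp, flow, vol, seg = make_mechanics_breath(
            25.0, 8.0, 1.5, noise_sigma=0.5, rng=rng
        )
        fit = fit_equation_of_motion(p_tp, flow, vol, seg)
        # independent oracle: explicit normal equations
        x = np.column_stack([vol / 1000.0, flow, np.ones(flow.size)])
        beta = np.linalg.solve(x.T @ x, x.T @ p_tp)
        assert fit.compliance_c == pytest.approx(1000.0 / beta[0], rel=1e-9)
        assert fit.resistance_rrs == pytest.approx(beta[1], rel=1e-9)
        assert fit.p0 == pytest.approx(beta[2], rel=1e-9)

    def test_collinear_design_raises(self):
        n = 400
        vol = np.linspace(0, 200, n)
        flow = vol / 1000.0  # flow proportional to volume
        p_tp = vol / 20.0 + 2.0
        seg = BreathSegment(0, n // 2, n, 200.0)
        with pytest.raises(ConditioningError):
            fit_equation_of_motion(p_tp, flow, vol, seg)

    def test_negative_compliance_flagged_not_raised(self):
        p_tp, flow, vol, seg = make_mechanics_breath(20.0, 10.0, 2.0)
        fit = fit_equation_of_motion(-p_tp, flow, vol, seg)
        assert fit.rejected
        assert fit.compliance_c < 0

    def test_recovery_within_1pct_on_passive_simulated_breath(self, quiet_config):
        """Passive breath (no muscle pressure): the pipeline fit recovers the
        generator's lung compliance and airway resistance to <= 1%."""
        record, truth = simulate_breath_dynamics(
            quiet_config, peep=6.0, rr=40.0, edi_amplitude=4.0, k_edi=0.0,
            c_lung=20.0, r_aw=8.0, duration=10.0,
        )
        seg = select_breaths(detect_breaths(record.flow, record.sample_rate), 3)[1]
        mech = analyze_breath(record, seg)
        assert mech.compliance_c == pytest.approx(truth["c_lung"], rel=0.01)
        assert mech.resistance_rrs == pytest.approx(truth["r_aw"], rel=0.01)


class TestPtpMaxSummary:
    def _breath(self, p_ao, p_eso, flow):
        n = p_ao.size
        return BreathSegment(1, n // 2, n, 200.0)

    def test_formula_arithmetic(self):
        # plateau breath: p_ao 15, eso swing -6, R 8, flow at max 0.5
        n = 40
        p_eso = np.full(n, -2.0)
        p_eso[10:30] = -8.0  # swing of -6 at the P_TP maximum
        p_ao = np.full(n, 15.0)
        flow = np.full(n, 0.5)
        p_tp = p_ao - p_eso
        seg = BreathSegment(1, 20, n, 200.0)
        delta_peso, p_tp_max, p_tp_true_max, idx, flow_at = ptp_max_summary(
            p_ao, p_eso, p_tp, flow, seg, end_exp_idx=0, resistance_rrs=8.0
        )
        assert delta_peso == pytest.approx(-6.0)
        assert p_tp_max == pytest.approx(21.0)
        assert p_tp_true_max == pytest.approx(17.0)
        assert flow_at == pytest.approx(0.5)

    def test_zero_flow_no_resistive_correction(self):
        n = 40
        p_eso = np.linspace(-2, -6, n)
        p_ao = np.full(n, 12.0)
        flow = np.zeros(n)
        p_tp = p_ao - p_eso
        seg = BreathSegment(1, 20, n, 200.0)
        _, p_tp_max, p_tp_true_max, _, _ = ptp_max_summary(
            p_ao, p_eso, p_tp, flow, seg, end_exp_idx=0, resistance_rrs=8.0
        )
        assert p_tp_true_max == p_tp_max

    def test_far_end_exp_idx_rejected(self):
        n = 400
        seg = BreathSegment(200, 250, 390, 200.0)
        arrays = [np.zeros(n)] * 4
        with pytest.raises(ValueError):
            ptp_max_summary(*arrays, seg, end_exp_idx=2, resistance_rrs=1.0)

    @given(
        resistance=st.floats(0.0, 30.0),
        flow_at_max=st.floats(0.0, 2.0),
    )
    def test_true_max_never_exceeds_max(self, resistance, flow_at_max):
        """With non-negative resistance and inspiratory flow, the resistive
        correction can only lower the maximum."""
        n = 40
        p_ao = np.linspace(5, 15, n)
        p_eso = np.linspace(-2, -5, n)
        flow = np.full(n, flow_at_max)
        p_tp = p_ao - p_eso
        seg = BreathSegment(1, 20, n, 200.0)
        _, p_tp_max, p_tp_true_max, _, _ = ptp_max_summary(
            p_ao, p_eso, p_tp, flow, seg, end_exp_idx=0, resistance_rrs=resistance
        )
        assert p_tp_true_max <= p_tp_max + 1e-12


class TestSimulatedCohortPressures:
    def test_peep15_true_max_calibration(self, quiet_acquisition_peep15):
        record = quiet_acquisition_peep15.waveforms
        segs = select_breaths(detect_breaths(record.flow, record.sample_rate), 3)
        vals = [analyze_breath(record, s).p_tp_true_max for s in segs]
        assert np.mean(vals) == pytest.approx(23.7, abs=1.0)

    def test_negative_esophageal_swings(self, quiet_acquisition_peep0):
        record = quiet_acquisition_peep0.waveforms
        segs = select_breaths(detect_breaths(record.flow, record.sample_rate), 3)
        for s in segs:
            assert analyze_breath(record, s).delta_peso < 0
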