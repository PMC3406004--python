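"""AUC, peak, half-life extraction and the half-life-vs-dose line."""

import numpy as np
import pytest

from cocainepk import (
    ENZYME_PANEL,
    EnzymeKinetics,
    SimulationSpec,
    TimeCourse,
    auc_infinity,
    half_life,
    half_life_vs_dose,
    peak,
    simulate,
    summarize_scenario,
    trapezoid_auc,
)


def exp_decay_tc(a=2.0, k=0.3, t_end=40.0, n=4001):
    """Analytic mono-exponential 'brain' curve (no dense interpolant)."""
    t = np.linspace(0.0, t_end, n)
    c = a * np.exp(-k * t)
    return TimeCourse(t=t, C1=c.copy(), C2=c.copy())


class TestTrapezoidAuc:
    def test_constant_series(self):
        t = np.linspace(0, 10, 101)
        tc = TimeCourse(t=t, C1=np.full_like(t, 3.0), C2=np.full_like(t, 3.0))
        assert trapezoid_auc(tc, "plasma", 10.0) == pytest.approx(30.0)
        assert trapezoid_auc(tc, "brain", 4.05) == pytest.approx(12.15)

    def test_exponential_converges_to_closed_form(self):
        tc = exp_decay_tc(a=2.0, k=0.5, t_end=60.0, n=60001)
        assert trapezoid_auc(tc, "brain", 60.0) == pytest.approx(2.0 / 0.5, rel=1e-4)

    def test_additivity(self, ref_params, wtbche):
        tc = simulate(SimulationSpec(C1_0=1.0, t_end=50.0), ref_params, wtbche)
        whole = trapezoid_auc(tc, "brain", 50.0)
        a = trapezoid_auc(tc, "brain", 17.3)
        # segment via difference of cumulative sums must close exactly
        assert a <= whole
        t2 = trapezoid_auc(tc, "brain", 50.0) - trapezoid_auc(tc, "brain", 17.3)
        assert a + t2 == pytest.approx(whole, rel=1e-12)

    def test_beyond_horizon_rejected(self, ref_params, wtbche):
        tc = simulate(SimulationSpec(C1_0=1.0, t_end=10.0), ref_params, wtbche)
        with pytest.raises(ValueError):
            trapezoid_auc(tc, "brain", 11.0)


class TestAucInfinity:
    def test_linear_regime_ratio_is_kpb_over_kbp(self, ref_params, wtbche):
        spec = SimulationSpec(C1_0=0.01, t_end=300.0)  # C1 << K_M
        a1 = auc_infinity(spec, ref_params, wtbche, "plasma")
        a2 = auc_infinity(spec, ref_params, wtbche, "brain")
        assert a2 / a1 == pytest.approx(ref_params.K_pb / ref_params.K_bp, rel=0.01)

    def test_linear_regime_plasma_closed_form(self, ref_params, wtbche):
        # mass balance to infinity: C1_0 = (V_max/K_M)*AUC1 exactly when
        # exchange nets to zero, so AUC1 = C1_0*K_M/V_max
        c1_0 = 0.003
        spec = SimulationSpec(C1_0=c1_0, t_end=300.0)
        a1 = auc_infinity(spec, ref_params, wtbche, "plasma")
        assert a1 == pytest.approx(c1_0 * wtbche.K_M / wtbche.v_max, rel=0.01)

    def test_divergence_without_elimination(self, ref_params, no_enzyme):
        with pytest.raises(RuntimeError):
            auc_infinity(
                SimulationSpec(C1_0=1.0, t_end=100.0), ref_params, no_enzyme
            )

    def test_zero_dose(self, ref_params, wtbche):
        assert auc_infinity(SimulationSpec(C1_0=0.0, t_end=10.0),
                            ref_params, wtbche) == 0.0


class TestPeak:
    def test_monotone_decay_peaks_at_origin(self):
        tc = exp_decay_tc()
        val, t = peak(tc, "plasma")
        assert val == pytest.approx(2.0) and t == 0.0

    def test_plasma_peak_is_initial_value(self, ref_params, wtbche):
        tc = simulate(SimulationSpec(C1_0=5.0, t_end=60.0), ref_params, wtbche)
        val, t = peak(tc, "plasma")
        assert val == pytest.approx(5.0, rel=1e-9) and t == 0.0

    def test_quadratic_refinement_without_dense(self):
        # coarse parabola-topped curve: refinement must beat the grid
        t = np.linspace(0, 10, 11)
        c = 1.0 - (t - 4.6) ** 2 / 50.0
        tc = TimeCourse(t=t, C1=c, C2=c.copy())
        val, tp = peak(tc, "brain")
        assert tp == pytest.approx(4.6, abs=1e-6)
        assert val == pytest.approx(1.0, abs=1e-9)


class TestHalfLife:
    def test_pure_exponential_both_conventions(self):
        k = 0.21
        tc = exp_decay_tc(a=1.0, k=k, t_end=30.0, n=30001)
        for conv in ("absolute", "from_peak"):
            assert half_life(tc, "brain", conv) == pytest.approx(
                np.log(2) / k, rel=1e-4
            )

    def test_convention_offset_equals_peak_time(self, ref_params, wtbche):
        tc = simulate(SimulationSpec(C1_0=1.0, t_end=200.0), ref_params, wtbche)
        t_abs = half_life(tc, "brain", "absolute")
        t_rel = half_life(tc, "brain", "from_peak")
        _, tp = peak(tc, "brain")
        assert t_abs - t_rel == pytest.approx(tp, abs=1e-3)

    def test_horizon_too_short(self, ref_params, wtbche):
        tc = simulate(SimulationSpec(C1_0=1.0, t_end=10.0), ref_params, wtbche)
        with pytest.raises(ValueError, match="extend"):
            half_life(tc, "brain")


class TestHalfLifeVsDose:
    def test_saturated_regime_line(self, ref_params, wtbche):
        """Once wtBChE is saturated the brain half-life is affine in dose.

        Zero-order elimination predicts slope ~ 1/(2*v_max).
        """
        fit = half_life_vs_dose(
            ref_params, wtbche, dose_grid=(50.0, 100.0, 150.0, 200.0)
        )
        assert fit.r > 0.999
        assert fit.slope == pytest.approx(1.0 / (2 * wtbche.v_max), rel=0.1)

    def test_degenerate_grid_rejected(self, ref_params, wtbche):
        with pytest.raises(ValueError):
            half_life_vs_dose(ref_params, wtbche, dose_grid=(5.0, 5.0, 5.0))
        with pytest.raises(ValueError):
            half_life_vs_dose(ref_params, wtbche, dose_grid=(1.0, 2.0))


class TestMonotonicity:
    def test_enzyme_activity_never_increases_exposure(self, ref_params):
        """More enzyme -> lower brain peak, AUC and half-life (fixed dose)."""
        peaks, aucs, halves = [], [], []
        for econc in (0.035, 0.1, 0.5):
            enz = ENZYME_PANEL["CocH1"].at_concentration(econc)
            m = summarize_scenario(ref_params, enz, 50.0)
            peaks.append(m.peak_C2)
            aucs.append(m.AUC2_inf)
            halves.append(m.t_b_half)
        assert peaks == sorted(peaks, reverse=True)
        assert aucs == sorted(aucs, reverse=True)
        assert halves == sorted(halves, reverse=True)

    def test_dose_monotonicity(self, ref_params, coch3):
        peaks, aucs = [], []
        for d in (1.0, 10.0, 100.0):
            m = summarize_scenario(ref_params, coch3, d)
            peaks.append(m.peak_C2)
            aucs.append(m.AUC2_inf)
        assert peaks == sorted(peaks)
        assert aucs == sorted(aucs)
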