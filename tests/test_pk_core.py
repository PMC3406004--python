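"""Model state, derivatives, integration, and conservation structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocainepk import (
    EnzymeKinetics,
    PKParameters,
    SimulationSpec,
    TimeCourse,
    mass_balance_residual,
    rhs,
    simulate,
)

from conftest import rk4_simulate


class TestTypes:
    def test_vmax_is_kcat_times_econc(self):
        e = EnzymeKinetics("x", k_cat=5700.0, K_M=3.1, E_conc=0.035)
        assert e.v_max == 5700.0 * 0.035

    @pytest.mark.parametrize(
        "kw",
        [
            dict(k_cat=0.0, K_M=1.0, E_conc=0.1),
            dict(k_cat=1.0, K_M=0.0, E_conc=0.1),
            dict(k_cat=1.0, K_M=1.0, E_conc=-0.1),
        ],
    )
    def test_enzyme_invariants(self, kw):
        with pytest.raises(ValueError):
            EnzymeKinetics("bad", **kw)

    @pytest.mark.parametrize("field", ["V_p", "V_b", "K_pb", "K_bp"])
    def test_pk_parameters_positive(self, ref_params, field):
        kw = {
            "V_p": ref_params.V_p,
            "V_b": ref_params.V_b,
            "K_pb": ref_params.K_pb,
            "K_bp": ref_params.K_bp,
        }
        kw[field] = 0.0
        with pytest.raises(ValueError):
            PKParameters(**kw)

    def test_vb_plausibility_flag(self, ref_params):
        assert ref_params.v_b_plausible
        big = PKParameters(V_p=11.89, V_b=5.0, K_pb=0.02, K_bp=0.02)
        assert not big.v_b_plausible

    def test_timecourse_validation(self):
        with pytest.raises(ValueError):
            TimeCourse(t=[0, 1], C1=[1, 0.5, 0.2], C2=[0, 0.1, 0.2])
        with pytest.raises(ValueError):
            TimeCourse(t=[0, 1, 1], C1=[1, 1, 1], C2=[0, 0, 0])
        with pytest.raises(ValueError):
            TimeCourse(t=[0, 1], C1=[1, -0.1], C2=[0, 0])

    def test_spec_from_dose(self, ref_params):
        spec = SimulationSpec.from_dose(11.0, ref_params)
        assert spec.C1_0 == pytest.approx(11.0 / (303.35 * 11.89))


class TestRhs:
    def test_zero_state_is_fixed_point(self, ref_params, wtbche):
        assert rhs(0.0, 0.0, ref_params, wtbche) == (0.0, 0.0)

    def test_exchange_equilibrium_ratio(self, ref_params, no_enzyme):
        # at C2/C1 = K_pb/K_bp the brain derivative vanishes (v_max = 0)
        c1 = 2.0
        c2 = c1 * ref_params.K_pb / ref_params.K_bp
        d1, d2 = rhs(c1, c2, ref_params, no_enzyme)
        assert d2 == pytest.approx(0.0, abs=1e-14)
        assert d1 == pytest.approx(0.0, abs=1e-14)

    def test_direct_substitution_high_dose(self, ref_params, coch3):
        # hand-computed derivative at C1=200, C2=0 for CocH3 at 0.035 µM
        vmax = 5700.0 * 0.035  # 199.5 µM/min
        d1, d2 = rhs(200.0, 0.0, ref_params, coch3)
        assert d1 == pytest.approx(-(vmax * 200 / 203.1) - 0.01898 * 200, rel=1e-12)
        assert d2 == pytest.approx((11.89 / 0.3292) * 0.01898 * 200, rel=1e-12)

    def test_exchange_conserves_amount(self, ref_params, no_enzyme):
        d1, d2 = rhs(3.0, 0.5, ref_params, no_enzyme)
        assert ref_params.V_p * d1 + ref_params.V_b * d2 == pytest.approx(
            0.0, abs=1e-12
        )

    def test_elimination_term_bounded(self, ref_params, coch3):
        # elimination never exceeds v_max even far above K_M
        d1_sat, _ = rhs(1e6, 0.0, ref_params, coch3)
        assert d1_sat >= -(coch3.v_max + ref_params.K_pb * 1e6) - 1e-9

    def test_negative_input_rejected(self, ref_params, wtbche):
        with pytest.raises(ValueError):
            rhs(-1.0, 0.0, ref_params, wtbche)

    positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)

    @settings(derandomize=True, max_examples=50)
    @given(c1=positive, c2=positive, v_p=positive, v_b=positive,
           k_pb=st.floats(1e-4, 1.0), k_bp=st.floats(1e-4, 1.0),
           k_cat=positive, k_m=positive, e_conc=st.floats(0.0, 10.0))
    def test_structure_properties_hold_everywhere(
        self, c1, c2, v_p, v_b, k_pb, k_bp, k_cat, k_m, e_conc
    ):
        """Exchange conserves amount; elimination is bounded by v_max."""
        params = PKParameters(V_p=v_p, V_b=v_b, K_pb=k_pb, K_bp=k_bp)
        enzyme = EnzymeKinetics("e", k_cat=k_cat, K_M=k_m, E_conc=e_conc)
        d1, d2 = rhs(c1, c2, params, enzyme)
        elim = d1 + params.K_pb * c1 - params.K_bp * c2
        tol = 1e-9 * max(abs(d1), params.K_pb * c1, params.K_bp * c2, 1.0)
        assert -enzyme.v_max - tol <= elim <= tol
        exchange_balance = v_p * (d1 - elim) + v_b * d2
        assert abs(exchange_balance) <= 1e-9 * max(v_p * c1, v_b * c2, 1.0)


class TestSimulate:
    def test_zero_dose_gives_zero_trajectories(self, ref_params, wtbche):
        tc = simulate(SimulationSpec(C1_0=0.0, t_end=10.0), ref_params, wtbche)
        assert np.all(tc.C1 == 0) and np.all(tc.C2 == 0)

    def test_conservation_without_elimination(self, ref_params, no_enzyme):
        c1_0 = 3.0
        tc = simulate(SimulationSpec(C1_0=c1_0, t_end=500.0), ref_params, no_enzyme)
        total = ref_params.V_p * tc.C1 + ref_params.V_b * tc.C2
        assert np.max(np.abs(total - ref_params.V_p * c1_0)) < 1e-6 * (
            ref_params.V_p * c1_0
        )

    def test_equilibrium_ratio_reached(self, ref_params, no_enzyme):
        tc = simulate(SimulationSpec(C1_0=1.0, t_end=2000.0), ref_params, no_enzyme)
        ratio = tc.C2[-1] / tc.C1[-1]
        assert ratio == pytest.approx(ref_params.K_pb / ref_params.K_bp, rel=1e-6)

    def test_nonnegative_trajectories(self, ref_params, coch3):
        tc = simulate(SimulationSpec(C1_0=200.0, t_end=200.0), ref_params, coch3)
        assert np.all(tc.C1 >= 0) and np.all(tc.C2 >= 0)

    @pytest.mark.parametrize(
        "enzyme_name,c1_0,t_end",
        [("wtBChE", 1.0, 30.0), ("CocH3", 200.0, 10.0), ("CocE", 50.0, 10.0)],
    )
    def test_adaptive_matches_fixed_step_oracle(
        self, ref_params, enzyme_name, c1_0, t_end
    ):
        from cocainepk import ENZYME_PANEL

        enzyme = ENZYME_PANEL[enzyme_name]
        t, c1o, c2o = rk4_simulate(ref_params, enzyme, c1_0, t_end, dt=0.001)
        tc = simulate(SimulationSpec(C1_0=c1_0, t_end=t_end), ref_params, enzyme)
        sub = slice(None, None, 100)  # compare every 0.1 min
        c1a, c2a = tc.evaluate(t[sub])
        assert np.max(np.abs(c1a - c1o[sub])) < 0.005 * c1o.max()
        assert np.max(np.abs(c2a - c2o[sub])) < 0.005 * c2o.max()

    def test_roundtrip_csv(self, tmp_path, ref_params, wtbche):
        tc = simulate(SimulationSpec(C1_0=1.0, t_end=30.0, dt=1.0), ref_params, wtbche)
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        assert path.read_text().splitlines()[0] == "t_min,C1_uM,C2_uM"
        back = TimeCourse.from_csv(path)
        np.testing.assert_allclose(back.t, tc.t)
        np.testing.assert_allclose(back.C1, tc.C1, rtol=1e-9)
        np.testing.assert_allclose(back.C2, tc.C2, rtol=1e-9)


class TestMassBalance:
    def test_zero_residual_without_elimination(self, ref_params, no_enzyme):
        tc = simulate(SimulationSpec(C1_0=2.0, t_end=100.0), ref_params, no_enzyme)
        res = mass_balance_residual(tc, ref_params, no_enzyme)
        assert np.max(np.abs(res)) < 1e-6 * 2.0

    @pytest.mark.parametrize(
        "enzyme_name,c1_0,t_end",
        [("wtBChE", 5.0, 120.0), ("CocH3", 200.0, 60.0)],
    )
    def test_residual_bounded_with_elimination(
        self, ref_params, enzyme_name, c1_0, t_end
    ):
        from cocainepk import ENZYME_PANEL

        spec = SimulationSpec(C1_0=c1_0, t_end=t_end, n_points=20001)
        tc = simulate(spec, ref_params, ENZYME_PANEL[enzyme_name])
        res = mass_balance_residual(tc, ref_params, ENZYME_PANEL[enzyme_name])
        assert np.max(np.abs(res)) / c1_0 < 1e-6

    def test_shape_mismatch_rejected(self, ref_params, wtbche):
        with pytest.raises(ValueError):
            TimeCourse(t=[0.0, 1.0], C1=[1.0], C2=[0.0, 0.1])
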