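"""Unit and property tests for the 1D five-element steady state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytomech import (
    CellParameters,
    MatrixModel,
    ParameterError,
    Perturbation,
    StabilityError,
    WT_DEFAULT,
    actin_stiffness,
    apply_perturbation,
    closed_form_linear,
    parallel_branch_stiffness,
    series_branch_stiffness,
    solve_steady_state,
)


class TestActinStiffness:
    @pytest.mark.parametrize(
        "sigma, fields, expected",
        [
            (0.0, dict(c_i=0.7, beta=3.0, sigma_sat=2.0), 0.7),   # no tension, no stiffening
            (-5.0, dict(c_i=1.0, beta=3.0, sigma_sat=2.0), 1.0),  # compression never stiffens
            (1.0, dict(c_i=1.0, beta=2.0, sigma_sat=1.0), 2.0),   # saturating law midpoint
        ],
    )
    def test_pointwise_values(self, sigma, fields, expected):
        p = CellParameters(**fields)
        assert actin_stiffness(sigma, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        p = WT_DEFAULT
        sig = np.linspace(-2, 50, 400)
        vals = np.array([actin_stiffness(s, p) for s in sig])
        assert np.all(np.diff(vals) >= 0)
        assert np.all(vals <= p.c_i + p.beta * p.sigma_sat + 1e-12)
        assert np.all(vals[sig <= 0] == p.c_i)


class TestBranchStiffness:
    def test_series_is_actin_plus_vimentin(self):
        p = CellParameters(c_i=0.5, c_v2=0.5, beta=0.0)
        assert series_branch_stiffness(3.0, p) == pytest.approx(1.0)
        p2 = CellParameters(c_i=1.0, c_v2=0.5, beta=2.0, sigma_sat=1.0)
        assert series_branch_stiffness(1.0, p2) == pytest.approx(2.5)

    def test_vimentin_null_series_reduces_to_actin(self):
        p = apply_perturbation(WT_DEFAULT, Perturbation("vimentin_null"))
        assert series_branch_stiffness(0.0, p) == pytest.approx(p.c_i)

    def test_parallel_sum(self):
        assert parallel_branch_stiffness(CellParameters(c_mt=1.0, c_v1=1.0)) == 2.0
        assert parallel_branch_stiffness(CellParameters(c_mt=0.0, c_v1=0.0)) == 0.0
        ko = apply_perturbation(WT_DEFAULT, Perturbation("vimentin_null"))
        assert parallel_branch_stiffness(ko) == WT_DEFAULT.c_mt


class TestSteadyState:
    def test_no_resistance_no_feedback(self):
        p = CellParameters(c_mt=0.0, c_v1=0.0, f_m=0.0, beta=0.0, c_i=1.0,
                          c_v2=0.0, f0_rho0=2.0)
        st_ = solve_steady_state(p, MatrixModel(k_m=4.0))
        assert st_.sigma == pytest.approx(2.0, rel=1e-10)
        assert st_.eps_m == pytest.approx(0.5, rel=1e-10)

    def test_worked_linear_point(self):
        # f0_rho0 = 1, C_p = C_s = k_m = 1, f_m = 0.3
        p = CellParameters(c_mt=1.0, c_v1=0.0, c_i=1.0, beta=0.0, c_v2=0.0,
                          f_m=0.3, f0_rho0=1.0)
        st_ = solve_steady_state(p, MatrixModel(k_m=1.0))
        assert st_.sigma == pytest.approx(1.0 / 2.7, rel=1e-10)
        assert st_.rho == pytest.approx(1.0 / 0.9, rel=1e-10)
        assert st_.eps_p == pytest.approx(-2.0 / 2.7, rel=1e-10)
        rigid = solve_steady_state(p, MatrixModel(k_m=1e9))
        assert rigid.sigma == pytest.approx(1.0 / 1.7, rel=1e-6)

    def test_balance_feedback_and_compatibility_invariants(self):
        st_ = solve_steady_state(WT_DEFAULT, MatrixModel(k_m=3.0))
        p = WT_DEFAULT
        c_p = parallel_branch_stiffness(p)
        assert st_.rho == pytest.approx(-c_p * st_.eps_p + st_.sigma, abs=1e-9)
        assert st_.rho == pytest.approx(p.f_m * st_.sigma + p.f0_rho0, abs=1e-12)
        assert -st_.eps_p == pytest.approx(st_.eps_s + st_.eps_m, abs=1e-12)
        assert 0 <= st_.sigma <= p.f0_rho0 / (1 - p.f_m)
        assert st_.eps_p <= 0 <= st_.eps_s

    def test_degenerate_series_branch_transmits_nothing(self):
        p = CellParameters(c_i=0.0, c_v2=0.0, beta=0.0)
        st_ = solve_steady_state(p, MatrixModel(k_m=1.0))
        assert st_.sigma == 0.0
        assert st_.eps_m == 0.0

    def test_feedback_instability_raises(self):
        with pytest.raises(ParameterError):
            CellParameters(f_m=1.2)
        # force the bound check inside the solver too
        p = CellParameters(f_m=0.0)
        object.__setattr__(p, "f_m", 1.0)
        with pytest.raises(StabilityError):
            solve_steady_state(p, MatrixModel(k_m=1.0))

    def test_monotone_in_matrix_stiffness_with_plateau(self):
        grid = np.logspace(-2, 3, 40)
        sig = [solve_steady_state(WT_DEFAULT, MatrixModel(k_m=k)).sigma for k in grid]
        assert np.all(np.diff(sig) >= -1e-14)
        rigid = solve_steady_state(WT_DEFAULT, MatrixModel(k_m=1e9)).sigma
        assert sig[-1] == pytest.approx(rigid, rel=0.01)


@st.composite
def linear_param_draws(draw):
    return CellParameters(
        c_mt=draw(st.floats(0.0, 10.0)),
        c_v1=draw(st.floats(0.0, 5.0)),
        c_i=draw(st.floats(0.01, 5.0)),
        beta=0.0,
        sigma_sat=1.0,
        c_v2=draw(st.floats(0.0, 5.0)),
        f_m=draw(st.floats(0.0, 0.95)),
        f0_rho0=draw(st.floats(0.0, 10.0)),
    )


class TestLinearOracle:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=linear_param_draws(), k_m=st.floats(1e-3, 1e6))
    def test_solver_matches_closed_form(self, p, k_m):
        mat = MatrixModel(k_m=k_m)
        num = solve_steady_state(p, mat)
        ana = closed_form_linear(p, mat)
        scale = max(abs(ana.sigma), 1e-30)
        assert abs(num.sigma - ana.sigma) / scale <= 1e-10

    def test_closed_form_rejects_nonlinear(self):
        with pytest.raises(ParameterError):
            closed_form_linear(WT_DEFAULT, MatrixModel(k_m=1.0))

    def test_closed_form_limits(self):
        p = CellParameters(c_mt=0.0, c_v1=0.0, beta=0.0, c_i=1.0, c_v2=0.0,
                          f_m=0.4, f0_rho0=2.0)
        assert closed_form_linear(p, MatrixModel(1.0)).sigma == pytest.approx(2.0 / 0.6)
        p2 = CellParameters(c_mt=1.0, c_v1=0.0, beta=0.0, c_i=1.0, c_v2=0.0,
                           f_m=0.0, f0_rho0=1.0)
        assert closed_form_linear(p2, MatrixModel(1.0)).sigma == pytest.approx(1.0 / 3.0)


class TestPerturbations:
    def test_control_is_identity_and_input_unmodified(self):
        before = WT_DEFAULT.to_dict()
        out = apply_perturbation(WT_DEFAULT, Perturbation("control", 0.3))
        assert out == WT_DEFAULT
        assert WT_DEFAULT.to_dict() == before

    def test_vimentin_null_zeroes_both_elements_only(self):
        out = apply_perturbation(WT_DEFAULT, Perturbation("vimentin_null"))
        assert out.c_v1 == 0.0 and out.c_v2 == 0.0
        for f in ("c_mt", "c_i", "beta", "sigma_sat", "f_m", "f0_rho0", "g_gef"):
            assert getattr(out, f) == getattr(WT_DEFAULT, f)

    def test_mt_depoly_gef_boost(self):
        p = WT_DEFAULT.replace(g_gef=0.5)
        out = apply_perturbation(p, Perturbation("mt_depoly", 0.0))
        assert out.c_mt == 0.0
        assert out.f0_rho0 == pytest.approx(1.5 * p.f0_rho0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            Perturbation("caffeine", 0.5)
        with pytest.raises(ParameterError):
            Perturbation("mt_depoly", 1.5)

    @pytest.mark.parametrize("k_m", [0.5, 10.0, 300.0])
    def test_perturbation_signs_on_transmitted_stress(self, k_m):
        """Disruption phenotypes at fixed matrix stiffness.

        Microtubule depolymerisation raises stress, contractility and matrix
        strain; actin disruption and myosin inhibition lower stress; deleting
        the series (force-transmitting) vimentin lowers stress; deleting the
        parallel (microtubule-reinforcing) vimentin raises it.
        """
        mat = MatrixModel(k_m=k_m)
        base = solve_steady_state(WT_DEFAULT, mat)
        mt = solve_steady_state(
            apply_perturbation(WT_DEFAULT, Perturbation("mt_depoly", 0.5)), mat)
        assert mt.sigma > base.sigma
        assert mt.rho > base.rho
        assert mt.eps_m > base.eps_m
        act = solve_steady_state(
            apply_perturbation(WT_DEFAULT, Perturbation("actin_disrupt", 0.5)), mat)
        assert act.sigma < base.sigma
        myo = solve_steady_state(
            apply_perturbation(WT_DEFAULT, Perturbation("myosin_inhibit", 0.5)), mat)
        assert myo.sigma < base.sigma
        no_v2 = solve_steady_state(WT_DEFAULT.replace(c_v2=0.0), mat)
        assert no_v2.sigma < base.sigma
        no_v1 = solve_steady_state(WT_DEFAULT.replace(c_v1=0.0), mat)
        assert no_v1.sigma > base.sigma
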