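"""Lie brackets, commutation table, structure constants, thermal scale."""

import itertools

import numpy as np
import pytest
import sympy as sp

from hhsym.lie_structure import (
    VectorField,
    angle_gate_map,
    bare_fields,
    conductance_sensitivity,
    coupled_realization,
    estimate_structure_constants,
    gate_angle_map,
    lie_bracket,
    lie_bracket_symbolic,
    q10_scale,
    thermal_voltage,
    verify_commutation_table,
)
from hhsym.rate_functions import GateSpec, steady_state


class TestLieBracket:
    def test_independent_generators_commute(self):
        f = bare_fields()
        br = lie_bracket(f["Xc"], f["Xg"], (1.0, 2.0, 0.0))
        np.testing.assert_allclose(br, 0.0, atol=1e-12)

    def test_bracket_with_self_vanishes(self):
        theta, g, t = sp.symbols("theta g t", real=True)
        X = VectorField.from_sympy(
            (theta, g, t), (sp.sin(theta) * g, g**2, theta + t)
        )
        np.testing.assert_allclose(
            lie_bracket(X, X, (0.7, 1.3, 0.2)), 0.0, atol=1e-9
        )

    def test_translation_vs_scaling_in_g(self):
        # [d/dg, g d/dg] = d/dg, checked against the symbolic oracle
        theta, g, t = sp.symbols("theta g t", real=True)
        X = VectorField.from_sympy((theta, g, t), (0, 1, 0), name="dg")
        Y = VectorField.from_sympy((theta, g, t), (0, g, 0), name="g*dg")
        numeric = lie_bracket(X, Y, (0.5, 2.0, 0.1))
        np.testing.assert_allclose(numeric, [0.0, 1.0, 0.0], atol=1e-9)
        symbolic = lie_bracket_symbolic(X, Y)
        assert tuple(symbolic.exprs) == (0, 1, 0)

    def test_jacobi_identity_on_random_polynomial_fields(self):
        # [X,[Y,Z]] + [Y,[Z,X]] + [Z,[X,Y]] = 0; the inner brackets are
        # exact symbolically, the outer ones numeric
        rng = np.random.default_rng(42)
        syms = sp.symbols("theta g t", real=True)
        monomials = [sp.Integer(1), syms[0], syms[1], syms[2],
                     syms[0] * syms[1], syms[1] * syms[2]]

        def random_field(name):
            coeffs = rng.uniform(-1, 1, size=(3, len(monomials)))
            exprs = [
                sum(c * mn for c, mn in zip(row, monomials))
                for row in coeffs
            ]
            return VectorField.from_sympy(syms, exprs, name=name)

        for trial in range(3):
            X, Y, Z = (random_field(n) for n in "XYZ")
            point = rng.uniform(0.2, 1.0, size=3)
            total = (
                lie_bracket(X, lie_bracket_symbolic(Y, Z), point)
                + lie_bracket(Y, lie_bracket_symbolic(Z, X), point)
                + lie_bracket(Z, lie_bracket_symbolic(X, Y), point)
            )
            np.testing.assert_allclose(total, 0.0, atol=1e-5)

    def test_mismatched_coordinates_rejected(self):
        a, b = sp.symbols("a b", real=True)
        X = VectorField.from_sympy((a,), (1,))
        Y = VectorField.from_sympy((b,), (1,))
        with pytest.raises(ValueError):
            lie_bracket(X, Y, (0.0,))


class TestCommutationTable:
    def test_bare_fields_with_zero_constants_all_pass(self):
        report = verify_commutation_table(0.0, 0.0)
        for res in report.values():
            assert res["status"] == "pass"
            assert res["residual"] == 0.0

    def test_nonzero_constants_without_realization_are_unrealized(self):
        report = verify_commutation_table(0.04, 0.04)
        assert report["[Xc,Xg]=0"]["status"] == "pass"
        assert report["[Xc,Xt]=gamma1*Xg"]["status"] == "unrealized"
        assert report["[Xg,Xt]=gamma2*Xg"]["status"] == "unrealized"

    def test_coupled_realization_satisfies_table(self):
        g1, g2 = 0.04, 0.05
        real = coupled_realization(g1, g2)
        report = verify_commutation_table(g1, g2, realization=real)
        for res in report.values():
            assert res["status"] == "pass"
            assert res["residual"] < 1e-6

    def test_coupled_realization_symbolic_oracle(self):
        # the deformed time generator gives the table exactly
        g1, g2 = 0.04, 0.05
        real = coupled_realization(g1, g2)
        br = lie_bracket_symbolic(real["Xg"], real["Xt"])
        g = [s for s in (real["Xg"].symbols or []) if str(s) == "g"][0]
        assert sp.simplify(br.exprs[1] - g2 * g) == 0
        br2 = lie_bracket_symbolic(real["Xc"], real["Xt"])
        assert sp.simplify(br2.exprs[1] - g1 * g) == 0
        assert br.exprs[0] == 0 and br.exprs[2] == 0


class TestStructureConstants:
    def test_canonical_scales_and_window(self):
        rep = estimate_structure_constants()
        assert rep.per_gate_scales["beta_n"] == 80.0
        assert rep.per_gate_scales["beta_m"] == 18.0
        assert 0.03 <= rep.gamma2 <= 0.05
        assert rep.gamma2 == 1.0 / rep.E0_aggregate
        assert rep.gamma1_approximate

    def test_synthetic_single_gate(self):
        gate = GateSpec(
            "synthetic",
            alpha_form="pure_exp",
            alpha_constants=(1.0, 0.0, 25.0),
            beta_form="constant",
            beta_constants=(0.5, 0.0, 1.0),
        )
        rep = estimate_structure_constants({"x": gate})
        assert rep.per_gate_scales == {"alpha_x": 25.0}
        assert rep.gamma2 == pytest.approx(0.04)
        assert "beta_x" in rep.excluded

    def test_all_constant_gate_rejected(self):
        gate = GateSpec(
            "flat", "constant", (1.0, 0.0, 1.0), "constant", (1.0, 0.0, 1.0)
        )
        with pytest.raises(ValueError):
            estimate_structure_constants({"x": gate})


class TestThermalAndQ10:
    def test_thermal_voltage_values(self):
        assert thermal_voltage(310.0) == pytest.approx(26.7, abs=0.05)
        assert thermal_voltage(0.0) == 0.0
        assert thermal_voltage(293.0) == pytest.approx(25.25, abs=0.01)

    def test_thermal_voltage_linear_in_temperature(self):
        T = np.array([100.0, 200.0, 300.0])
        v = np.array([thermal_voltage(t) for t in T])
        assert v[2] - v[1] == pytest.approx(v[1] - v[0], rel=1e-12)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            thermal_voltage(-1.0)

    @pytest.mark.parametrize(
        "dT, factor", [(0.0, 1.0), (10.0, 3.0), (-10.0, 1.0 / 3.0)]
    )
    def test_q10_scaling(self, dT, factor):
        assert q10_scale(0.04, 6.3 + dT, 6.3, Q10=3.0) == pytest.approx(
            0.04 * factor
        )

    def test_q10_must_be_positive(self):
        with pytest.raises(ValueError):
            q10_scale(0.04, 10.0, 6.3, Q10=0.0)


class TestAngleGateMap:
    @pytest.mark.parametrize(
        "theta, xi", [(0.0, 1.0), (np.pi, 0.0), (np.pi / 2, 0.5)]
    )
    def test_projection(self, theta, xi):
        assert angle_gate_map(theta) == pytest.approx(xi, abs=1e-15)

    def test_round_trip_on_principal_branch(self):
        theta = np.linspace(0.0, np.pi, 50)
        back = gate_angle_map(angle_gate_map(theta))
        np.testing.assert_allclose(back, theta, atol=1e-7)

    def test_inverse_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="bounded"):
            gate_angle_map(1.1)


class TestConductanceSensitivity:
    def test_decomposition_matches_direct_derivative(self):
        # 3 dln m/dE + dln h/dE must equal the centered difference of
        # ln(m_inf^3 h_inf)
        from hhsym.rate_functions import H_GATE, M_GATE

        E, h = -65.0, 1e-4
        _, _, total = conductance_sensitivity(E, h=h)

        def ln_g(e):
            return 3 * np.log(steady_state(M_GATE, e)) + np.log(
                steady_state(H_GATE, e)
            )

        direct = (ln_g(E + h) - ln_g(E - h)) / (2 * h)
        assert total == pytest.approx(direct, abs=1e-6)

    def test_signs_at_rest(self):
        act, inact, _ = conductance_sensitivity(-65.0)
        assert act > 0  # activation steepens with depolarization
        assert inact < 0  # inactivation opposes it
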