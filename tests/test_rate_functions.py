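"""Rate functions: printed constants, limits, identities, positivity."""

import numpy as np
import pytest
import sympy as sp

from hhsym.rate_functions import (
    CANONICAL_GATES,
    GateSpec,
    H_GATE,
    M_GATE,
    N_GATE,
    efold_scales,
    log_ratio_derivative,
    rate_value,
    steady_state,
    time_constant,
)

GRID = np.arange(-120.0, 20.0 + 0.5, 1.0)  # 141 points


def make_exp_gate(a_scale, b_scale, ka=1.0, kb=1.0):
    """Synthetic gate with alpha = ka e^{E/a}, beta = kb e^{-E/b}."""
    return GateSpec(
        "synthetic",
        alpha_form="pure_exp",
        alpha_constants=(ka, 0.0, a_scale),
        beta_form="pure_exp",
        beta_constants=(kb, 0.0, -b_scale),
    )


class TestRateValues:
    @pytest.mark.parametrize(
        "gate, which, E, expected",
        [
            (N_GATE, "beta", 0.0, 0.0555),  # e^0 = 1 leaves the prefactor
            (M_GATE, "beta", 0.0, 0.108),
            (M_GATE, "alpha", -40.0, 1.0),  # removable singularity limit
            (N_GATE, "alpha", -55.0, 0.1),
            (M_GATE, "alpha", -65.0, 0.22356372458463003),
            (H_GATE, "alpha", -65.0, 0.0027 * np.exp(3.25)),
        ],
    )
    def test_reference_values(self, gate, which, E, expected):
        assert rate_value(gate, which, E) == pytest.approx(
            expected, rel=1e-12
        )

    def test_singularity_is_two_sided_limit(self):
        # evaluating just off the singular voltage must agree with the
        # analytic limit from both sides
        lim = rate_value(M_GATE, "alpha", -40.0)
        for eps in (1e-6, -1e-6):
            assert rate_value(M_GATE, "alpha", -40.0 + eps) == pytest.approx(
                lim, abs=1e-6
            )

    def test_all_rates_positive_on_physiological_range(self):
        E = np.linspace(-120, 60, 181)
        for gate in CANONICAL_GATES.values():
            for which in ("alpha", "beta"):
                assert np.all(rate_value(gate, which, E) > 0)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            rate_value(M_GATE, "beta", np.nan)
        with pytest.raises(ValueError):
            rate_value(M_GATE, "beta", np.inf)

    def test_overflow_guarded_not_silent(self):
        with pytest.raises(ValueError, match="guard"):
            rate_value(N_GATE, "beta", -80.0 * 800)

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            GateSpec(
                "bad", "pure_exp", (1.0, 0.0, 0.0), "pure_exp", (1.0, 0.0, 1.0)
            )


class TestSteadyStateAndTau:
    def test_equal_rates_give_half(self):
        gate = make_exp_gate(25.0, 25.0)
        assert steady_state(gate, 0.0) == pytest.approx(0.5, abs=1e-15)

    def test_m_steady_state_monotone_to_one(self):
        E = np.linspace(-80, 60, 200)
        xinf = steady_state(M_GATE, E)
        assert np.all(np.diff(xinf) > 0)
        assert xinf[-1] > 0.999

    def test_n_steady_state_at_rest(self):
        # alpha_n(-65)=0.0582, beta_n(-65)=0.1251 -> ratio ~ 0.3176
        assert steady_state(N_GATE, -65.0) == pytest.approx(
            0.3175535299620042, rel=1e-12
        )

    def test_tau_definition_and_reference(self):
        gate = make_exp_gate(25.0, 25.0)  # alpha = beta = 1 at E = 0
        assert time_constant(gate, 0.0) == pytest.approx(0.5, abs=1e-15)
        assert time_constant(M_GATE, -65.0) == pytest.approx(
            0.2369479687384665, rel=1e-12
        )

    def test_tau_times_total_rate_is_one_on_grid(self):
        E = np.arange(-100.0, 40.0 + 0.5, 1.0)
        for gate in CANONICAL_GATES.values():
            a = np.asarray(rate_value(gate, "alpha", E))
            b = np.asarray(rate_value(gate, "beta", E))
            tau = np.asarray(time_constant(gate, E))
            np.testing.assert_allclose(tau * (a + b), 1.0, rtol=1e-14)

    def test_bounds_on_range(self):
        for gate in CANONICAL_GATES.values():
            xinf = steady_state(gate, GRID)
            assert np.all((xinf >= 0) & (xinf <= 1))
            assert np.all(np.asarray(time_constant(gate, GRID)) > 0)


class TestLogRatioDerivative:
    def test_pure_exponential_pair_is_sum_of_slopes(self):
        gate = make_exp_gate(25.0, 50.0)
        # d/dE ln(alpha/beta) = 1/25 + 1/50, voltage independent
        for E in (-60.0, 0.0, 30.0):
            assert log_ratio_derivative(gate, E) == pytest.approx(
                1 / 25 + 1 / 50, rel=1e-9
            )

    def test_h_gate_against_symbolic_derivative(self):
        E = sp.Symbol("E")
        expr = sp.log(
            (sp.Rational(27, 10000) * sp.exp(-E / 20))
            / (1 / (1 + sp.exp(-(E + 35) / 10)))
        )
        exact = float(sp.diff(expr, E).subs(E, -80))
        assert log_ratio_derivative(H_GATE, -80.0) == pytest.approx(
            exact, rel=1e-7
        )

    def test_steady_state_derivative_identity_on_grid(self):
        # d xi_inf/dE = xi_inf (1 - xi_inf) d/dE ln(alpha/beta)
        h = 1e-4
        for gate in CANONICAL_GATES.values():
            xinf = np.asarray(steady_state(gate, GRID))
            dxinf = (
                np.asarray(steady_state(gate, GRID + h))
                - np.asarray(steady_state(gate, GRID - h))
            ) / (2 * h)
            L = np.asarray(log_ratio_derivative(gate, GRID, h=h))
            np.testing.assert_allclose(
                dxinf, xinf * (1 - xinf) * L, atol=1e-6
            )


class TestExponentialComponents:
    def test_pure_exponential_rates_are_log_linear(self):
        # beta_m, alpha_h, beta_n: ln(rate) exactly linear in E with
        # e-fold scales 18, 20, 80 mV
        cases = [(M_GATE, "beta", 18.0), (H_GATE, "alpha", 20.0),
                 (N_GATE, "beta", 80.0)]
        E = np.linspace(-100, 40, 141)
        for gate, which, scale in cases:
            y = np.log(np.asarray(rate_value(gate, which, E)))
            slope, _ = np.polyfit(E, y, 1)
            resid = y - np.polyval(np.polyfit(E, y, 1), E)
            r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
            assert r2 > 1 - 1e-12
            assert -1.0 / slope == pytest.approx(scale, rel=1e-9)

    def test_efold_scales_inventory(self):
        scales = efold_scales()
        assert scales["beta_n"] == 80.0
        assert scales["beta_m"] == 18.0
        assert sorted(scales.values()) == [10.0, 10.0, 10.0, 18.0, 20.0, 80.0]
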