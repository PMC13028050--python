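"""Lie generators, brackets, and structure constants of gating dynamics.

The symmetry algebra of the gating system is spanned by three
generators on coordinates (theta, g, t):

    X_c = d/dtheta        conformational rotation, so(2) — compactness
                          of the gate angle forces 0 <= xi <= 1 via the
                          projection xi = (1 + cos theta)/2;
    X_g = g d/dg          conductance scaling, R — maximal-conductance
                          ratios are scale invariant;
    X_t = d/dt            time translation, R — autonomous first-order
                          kinetics.

The target commutation table is

    [X_c, X_g] = 0,   [X_c, X_t] = gamma1 X_g,   [X_g, X_t] = gamma2 X_g,

i.e. so(2) acting on an R^2 sector (semidirect product).  The bare
coordinate fields above commute pairwise, so nonzero structure
constants require a coupled realization; :func:`coupled_realization`
provides one that satisfies the table exactly (see docs/methods.md).

The structure constants are estimated from the empirical rate
functions: gamma2 = 1/E0 where E0 aggregates the e-fold voltage scales
of the exponential rate factors, and gamma1 is the same order of
magnitude (reported with an approximate flag, no normalization).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from scipy.constants import e as ELEMENTARY_CHARGE
from scipy.constants import k as BOLTZMANN

from .rate_functions import (
    CANONICAL_GATES,
    GateSpec,
    efold_scales,
    steady_state,
)

__all__ = [
    "VectorField",
    "StructureConstantReport",
    "lie_bracket",
    "lie_bracket_symbolic",
    "bare_fields",
    "coupled_realization",
    "verify_commutation_table",
    "estimate_structure_constants",
    "thermal_voltage",
    "q10_scale",
    "angle_gate_map",
    "gate_angle_map",
    "conductance_sensitivity",
]


@dataclass
class VectorField:
    """First-order differential operator sum_i f_i(x) d/dx_i.

    Coefficients are per-coordinate scalar functions of the full point;
    fields built from sympy expressions retain them for exact symbolic
    brackets alongside the lambdified numeric path.
    """

    coordinates: tuple[str, ...]
    coefficients: tuple[Callable[..., float], ...]
    exprs: tuple[sp.Expr, ...] | None = None
    symbols: tuple[sp.Symbol, ...] | None = None
    name: str = ""

    @classmethod
    def from_sympy(
        cls,
        coordinates: Sequence[sp.Symbol],
        exprs: Sequence[sp.Expr],
        name: str = "",
    ) -> "VectorField":
        syms = tuple(coordinates)
        exprs_t = tuple(sp.sympify(e) for e in exprs)
        funcs = tuple(
            sp.lambdify(syms, e, modules="numpy") for e in exprs_t
        )
        return cls(
            coordinates=tuple(str(s) for s in syms),
            coefficients=funcs,
            exprs=exprs_t,
            symbols=syms,
            name=name,
        )

    def __call__(self, point: Sequence[float]) -> np.ndarray:
        vals = np.array(
            [float(f(*point)) for f in self.coefficients], dtype=float
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"vector field {self.name or '<anon>'} non-finite at {point}"
            )
        return vals


def lie_bracket(
    X: VectorField,
    Y: VectorField,
    point: Sequence[float],
    h: float = 1e-5,
) -> np.ndarray:
    """Numerical commutator [X, Y] = J_Y X - J_X Y at a point.

    Jacobians by central differences with step ``h``.  Antisymmetric in
    (X, Y) up to the finite-difference truncation error.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    if X.coordinates != Y.coordinates:
        raise ValueError("vector fields must share a coordinate system")
    pt = np.asarray(point, dtype=float)
    dim = len(pt)
    Xv, Yv = X(pt), Y(pt)

    def jacobian(F: VectorField) -> np.ndarray:
        J = np.empty((dim, dim))
        for j in range(dim):
            step = np.zeros(dim)
            step[j] = h
            J[:, j] = (F(pt + step) - F(pt - step)) / (2.0 * h)
        return J

    return jacobian(Y) @ Xv - jacobian(X) @ Yv


def lie_bracket_symbolic(X: VectorField, Y: VectorField) -> VectorField:
    """Exact symbolic commutator (requires sympy-backed fields)."""
    if X.exprs is None or Y.exprs is None:
        raise ValueError("symbolic bracket requires sympy-backed fields")
    if X.coordinates != Y.coordinates:
        raise ValueError("vector fields must share a coordinate system")
    # differentiate w.r.t. the exact Symbol objects the expressions use
    syms = list(X.symbols or [sp.Symbol(c) for c in X.coordinates])
    Xe = [sp.sympify(e) for e in X.exprs]
    Ye = [sp.sympify(e) for e in Y.exprs]
    out = []
    for i in range(len(syms)):
        expr = sp.S.Zero
        for j, s in enumerate(syms):
            expr += Xe[j] * sp.diff(Ye[i], s) - Ye[j] * sp.diff(Xe[i], s)
        out.append(sp.simplify(expr))
    return VectorField.from_sympy(
        syms, out, name=f"[{X.name},{Y.name}]"
    )


def _symbols():
    return sp.symbols("theta g t", real=True)


def bare_fields() -> dict[str, VectorField]:
    """Uncoupled generators X_c = d/dtheta, X_g = g d/dg, X_t = d/dt."""
    theta, g, t = _symbols()
    coords = (theta, g, t)
    return {
        "Xc": VectorField.from_sympy(coords, (1, 0, 0), name="Xc"),
        "Xg": VectorField.from_sympy(coords, (0, g, 0), name="Xg"),
        "Xt": VectorField.from_sympy(coords, (0, 0, 1), name="Xt"),
    }


def coupled_realization(gamma1: float, gamma2: float) -> dict[str, VectorField]:
    """Coordinate realization satisfying the full commutation table.

    Keeps X_c and X_g bare and deforms the time generator to

        X_t -> d/dt + g (gamma2 ln g + gamma1 theta) d/dg   (g > 0),

    which gives [X_c, X_g] = 0, [X_c, X_t] = gamma1 X_g and
    [X_g, X_t] = gamma2 X_g exactly.  (A g-coefficient homogeneous of
    degree one in g, such as gamma2*t*g, commutes with X_g and cannot
    produce a nonzero gamma2; the ln g deformation breaks that
    homogeneity.)
    """
    theta, g, t = _symbols()
    coords = (theta, g, t)
    fields = bare_fields()
    fields["Xt"] = VectorField.from_sympy(
        coords,
        (0, g * (gamma2 * sp.log(g) + gamma1 * theta), 1),
        name="Xt_coupled",
    )
    return fields


_DEFAULT_POINTS = tuple(
    itertools.product((0.3, 1.1), (0.5, 2.0), (0.0, 1.5))
)


def verify_commutation_table(
    gamma1: float,
    gamma2: float,
    fields: dict[str, VectorField] | None = None,
    realization: dict[str, VectorField] | None = None,
    points: Sequence[Sequence[float]] = _DEFAULT_POINTS,
    h: float = 1e-5,
    tol: float = 1e-6,
    antisym_tol: float = 1e-8,
) -> dict[str, dict]:
    """Check the three commutation relations on sampled points.

    For each relation reports the worst residual of
    ``[X_i, X_j] - c * X_g`` across ``points`` and a pass/fail status.
    When nonzero structure constants are requested but only the bare
    (mutually commuting) fields are supplied, the gamma relations are
    reported as ``"unrealized"`` rather than failed — supply a coupled
    ``realization`` (e.g. :func:`coupled_realization`) to test them.
    Any antisymmetry violation above ``antisym_tol`` fails outright.
    """
    supplied = realization or fields
    used = dict(supplied) if supplied is not None else bare_fields()
    bare = supplied is None
    Xc, Xg, Xt = used["Xc"], used["Xg"], used["Xt"]

    relations = {
        "[Xc,Xg]=0": (Xc, Xg, 0.0),
        "[Xc,Xt]=gamma1*Xg": (Xc, Xt, gamma1),
        "[Xg,Xt]=gamma2*Xg": (Xg, Xt, gamma2),
    }
    report: dict[str, dict] = {}
    for label, (A, B, c) in relations.items():
        worst = 0.0
        anti_worst = 0.0
        for pt in points:
            br = lie_bracket(A, B, pt, h=h)
            anti = lie_bracket(B, A, pt, h=h)
            anti_worst = max(anti_worst, float(np.abs(br + anti).max()))
            resid = br - c * Xg(pt)
            worst = max(worst, float(np.abs(resid).max()))
        if anti_worst > antisym_tol:
            status = "fail"
        elif bare and c != 0.0:
            status = "unrealized"
        else:
            status = "pass" if worst <= tol else "fail"
        report[label] = {
            "status": status,
            "residual": worst,
            "antisymmetry_violation": anti_worst,
        }
    return report


@dataclass
class StructureConstantReport:
    """E-fold scales and structure constants from the rate functions."""

    per_gate_scales: dict[str, float]
    E0_aggregate: float
    gamma1: float
    gamma2: float
    gamma1_approximate: bool
    thermal_E0: float
    method: str
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_gate_scales_mV": self.per_gate_scales,
            "E0_aggregate_mV": self.E0_aggregate,
            "gamma1_per_mV": self.gamma1,
            "gamma1_approximate": self.gamma1_approximate,
            "gamma2_per_mV": self.gamma2,
            "thermal_E0_mV": self.thermal_E0,
            "method": self.method,
            "excluded": self.excluded,
        }


def estimate_structure_constants(
    gates: dict[str, GateSpec] | None = None,
    temperature_K: float = 310.0,
) -> StructureConstantReport:
    """Structure constants gamma1, gamma2 from rate-function e-fold scales.

    Reads the e-fold voltage scale of every exponential rate factor,
    aggregates them by arithmetic mean into E0, and sets
    gamma2 = 1/E0 exactly.  gamma1 is reported at the same magnitude
    with an approximate flag (its relation carries no independent
    normalization).  Rates with no exponential component are excluded
    with notice.
    """
    gates = CANONICAL_GATES if gates is None else gates
    scales = efold_scales(gates)
    excluded = [
        f"{which}_{label}"
        for label, gate in gates.items()
        for which in ("alpha", "beta")
        if gate.efold_scale(which) is None  # type: ignore[arg-type]
    ]
    if not scales:
        raise ValueError("no gate has an exponential rate component")
    E0 = float(np.mean(list(scales.values())))
    gamma2 = 1.0 / E0
    return StructureConstantReport(
        per_gate_scales=scales,
        E0_aggregate=E0,
        gamma1=gamma2,
        gamma2=gamma2,
        gamma1_approximate=True,
        thermal_E0=thermal_voltage(temperature_K),
        method=(
            "E0 = arithmetic mean of e-fold scales of exponential rate "
            "factors; gamma2 = 1/E0; gamma1 ~ 1/E0 (order of magnitude)"
        ),
        excluded=excluded,
    )


def thermal_voltage(T_kelvin: float) -> float:
    """Thermal voltage k_B T / e in mV (CODATA constants)."""
    if T_kelvin < 0:
        raise ValueError("absolute temperature must be >= 0")
    return BOLTZMANN * T_kelvin / ELEMENTARY_CHARGE * 1e3


def q10_scale(
    gamma2_ref: float, T: float, T_ref: float, Q10: float = 3.0
) -> float:
    """Temperature-scaled structure constant gamma2(T).

    Kinetic rates speed up by the factor Q10 per 10 degC, so
    gamma2(T) = gamma2(T_ref) * Q10**((T - T_ref)/10) with T in degC.
    """
    if Q10 <= 0:
        raise ValueError("Q10 must be positive")
    return gamma2_ref * Q10 ** ((T - T_ref) / 10.0)


def angle_gate_map(theta):
    """Project the compact gate angle to xi = (1 + cos theta)/2 in [0, 1]."""
    return (1.0 + np.cos(theta)) / 2.0


def gate_angle_map(xi):
    """Principal inverse of the angle map: theta = arccos(2 xi - 1) in [0, pi]."""
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr < 0.0) or np.any(xi_arr > 1.0):
        raise ValueError("gate value outside [0, 1]; boundedness violated")
    out = np.arccos(2.0 * xi_arr - 1.0)
    return out.item() if np.isscalar(xi) or out.ndim == 0 else out


def conductance_sensitivity(
    E: float, h: float = 1e-4, tol: float = 1e-12
) -> tuple[float, float, float]:
    """Decompose the steady-state sodium log-sensitivity at E.

    Returns (3 * dln m_inf/dE, dln h_inf/dE, total), the activation and
    inactivation contributions to d ln gNa/dE for gNa = gNa_max m^3 h
    at steady state, via central differences with step ``h`` (mV).
    """
    m_gate, h_gate = CANONICAL_GATES["m"], CANONICAL_GATES["h"]
    for gate in (m_gate, h_gate):
        xi = steady_state(gate, E)
        if xi < tol or xi > 1.0 - tol:
            raise ValueError(
                f"steady state of {gate.name} at E={E} is at a boundary; "
                "log-derivative undefined"
            )
    def dln(gate: GateSpec) -> float:
        return (
            np.log(steady_state(gate, E + h)) - np.log(steady_state(gate, E - h))
        ) / (2.0 * h)

    term_act = 3.0 * dln(m_gate)
    term_inact = dln(h_gate)
    return (term_act, term_inact, term_act + term_inact)
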