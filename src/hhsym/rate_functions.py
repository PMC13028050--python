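"""Hodgkin-Huxley gating rate functions.

Each gating variable xi (m, h, n) relaxes with voltage-dependent opening
and closing rates alpha(E), beta(E) in ms^-1.  The canonical squid-axon
rates are expressed here in the absolute-voltage convention (resting
potential near -65 mV):

    alpha_m(E) = 0.1 (E + 40) / (1 - exp(-(E + 40)/10))
    beta_m(E)  = 0.108 exp(-E/18)
    alpha_h(E) = 0.0027 exp(-E/20)
    beta_h(E)  = 1 / (1 + exp(-(E + 35)/10))
    alpha_n(E) = 0.01 (E + 55) / (1 - exp(-(E + 55)/10))
    beta_n(E)  = 0.0555 exp(-E/80)

The prefactors 0.108, 0.0027, 0.0555 are the classical values 4, 0.07,
0.125 with the -65 mV resting shift absorbed into the exponential.

Derived quantities: steady state xi_inf = alpha/(alpha+beta), time
constant tau = 1/(alpha+beta), and the logarithmic voltage sensitivity
d/dE ln(alpha/beta), whose reciprocal is the local e-fold voltage scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "GateSpec",
    "M_GATE",
    "H_GATE",
    "N_GATE",
    "CANONICAL_GATES",
    "rate_value",
    "steady_state",
    "time_constant",
    "log_ratio_derivative",
    "efold_scales",
]

#: largest |argument| accepted by the exponential guard
EXP_GUARD = 700.0

#: half-width of the removable-singularity window (mV)
SINGULAR_TOL = 1e-7

_FORMS = ("linoverexp", "pure_exp", "logistic", "constant")

RateKind = Literal["alpha", "beta"]


@dataclass(frozen=True)
class GateSpec:
    """Parameterization of one gating variable's opening/closing rates.

    Each rate is one of four functional forms, with constants
    ``(prefactor, offset_mV, scale_mV)``:

    ``linoverexp``
        ``k * (E - offset) / (1 - exp(-(E - offset)/scale))`` --
        linear-over-expm1; removable singularity at ``E = offset`` with
        limit ``k * scale``.
    ``pure_exp``
        ``k * exp((E - offset)/scale)``; ``scale`` may be negative for
        rates that fall with depolarization.
    ``logistic``
        ``k / (1 + exp(-(E - offset)/scale))``.
    ``constant``
        ``k`` (no voltage dependence; no exponential component).

    Units: prefactor ms^-1 (ms^-1 mV^-1 for linoverexp), offset mV,
    scale mV.
    """

    name: str
    alpha_form: str
    alpha_constants: tuple[float, float, float]
    beta_form: str
    beta_constants: tuple[float, float, float]

    def __post_init__(self) -> None:
        for label, form, consts in (
            ("alpha", self.alpha_form, self.alpha_constants),
            ("beta", self.beta_form, self.beta_constants),
        ):
            if form not in _FORMS:
                raise ValueError(
                    f"{self.name}: unknown {label}_form {form!r}; "
                    f"expected one of {_FORMS}"
                )
            if len(consts) != 3:
                raise ValueError(
                    f"{self.name}: {label}_constants must be "
                    "(prefactor, offset_mV, scale_mV)"
                )
            if form != "constant" and consts[2] == 0.0:
                raise ValueError(
                    f"{self.name}: {label} e-fold scale must be nonzero"
                )

    def efold_scale(self, which: RateKind) -> float | None:
        """|e-fold scale| of the exponential factor, or None for constant."""
        form, consts = (
            (self.alpha_form, self.alpha_constants)
            if which == "alpha"
            else (self.beta_form, self.beta_constants)
        )
        if form == "constant":
            return None
        return abs(consts[2])


#: sodium activation gate m
M_GATE = GateSpec(
    "activation-Na",
    alpha_form="linoverexp",
    alpha_constants=(0.1, -40.0, 10.0),
    beta_form="pure_exp",
    beta_constants=(0.108, 0.0, -18.0),
)

#: sodium inactivation gate h
H_GATE = GateSpec(
    "inactivation-Na",
    alpha_form="pure_exp",
    alpha_constants=(0.0027, 0.0, -20.0),
    beta_form="logistic",
    beta_constants=(1.0, -35.0, 10.0),
)

#: potassium activation gate n
N_GATE = GateSpec(
    "activation-K",
    alpha_form="linoverexp",
    alpha_constants=(0.01, -55.0, 10.0),
    beta_form="pure_exp",
    beta_constants=(0.0555, 0.0, -80.0),
)

CANONICAL_GATES: dict[str, GateSpec] = {"m": M_GATE, "h": H_GATE, "n": N_GATE}


def _check_voltage(E: np.ndarray) -> None:
    if not np.all(np.isfinite(E)):
        raise ValueError("membrane potential must be finite")


def _eval_form(
    form: str, consts: tuple[float, float, float], E: np.ndarray
) -> np.ndarray:
    k, offset, scale = consts
    if form == "constant":
        return np.full_like(E, k)
    x = E - offset
    arg = x / scale
    if np.any(np.abs(arg) > EXP_GUARD):
        raise ValueError(
            f"exponential argument exceeds guard range ({EXP_GUARD}); "
            "voltage outside supported domain"
        )
    if form == "pure_exp":
        return k * np.exp(arg)
    if form == "logistic":
        return k / (1.0 + np.exp(-arg))
    # linoverexp: k*x/(1 - exp(-x/scale)); limit k*scale as x -> 0
    singular = np.abs(x) < SINGULAR_TOL
    x_safe = np.where(singular, scale, x)  # dummy value on singular points
    val = k * x_safe / (-np.expm1(-x_safe / scale))
    return np.where(singular, k * scale, val)


def rate_value(gate: GateSpec, which: RateKind, E):
    """Evaluate the opening (alpha) or closing (beta) rate at E (mV).

    Accepts scalars or arrays; returns ms^-1.  Removable singularities
    of the linear-over-expm1 form return the analytic limit.  Non-finite
    voltages and exponential overflow are rejected.
    """
    if which not in ("alpha", "beta"):
        raise ValueError(f"which must be 'alpha' or 'beta', got {which!r}")
    E_arr = np.asarray(E, dtype=float)
    _check_voltage(E_arr)
    form, consts = (
        (gate.alpha_form, gate.alpha_constants)
        if which == "alpha"
        else (gate.beta_form, gate.beta_constants)
    )
    out = _eval_form(form, consts, E_arr)
    if not np.all(np.isfinite(out)):
        raise ValueError(f"rate evaluation produced non-finite value at E={E}")
    return out.item() if np.isscalar(E) or E_arr.ndim == 0 else out


def alpha(gate: GateSpec, E):
    return rate_value(gate, "alpha", E)


def beta(gate: GateSpec, E):
    return rate_value(gate, "beta", E)


def steady_state(gate: GateSpec, E):
    """Steady-state gate value xi_inf = alpha/(alpha+beta), in [0, 1]."""
    a = np.asarray(rate_value(gate, "alpha", E), dtype=float)
    b = np.asarray(rate_value(gate, "beta", E), dtype=float)
    total = a + b
    if np.any(total <= 0.0):
        raise ValueError("alpha + beta must be positive for a steady state")
    out = a / total
    return out.item() if np.isscalar(E) or out.ndim == 0 else out


def time_constant(gate: GateSpec, E):
    """Relaxation time constant tau = 1/(alpha+beta), in ms."""
    a = np.asarray(rate_value(gate, "alpha", E), dtype=float)
    b = np.asarray(rate_value(gate, "beta", E), dtype=float)
    total = a + b
    if np.any(total <= 0.0):
        raise ValueError("alpha + beta must be positive for a time constant")
    out = 1.0 / total
    return out.item() if np.isscalar(E) or out.ndim == 0 else out


def log_ratio_derivative(gate: GateSpec, E, h: float = 1e-3):
    """Central-difference estimate of d/dE ln(alpha/beta) at E, in mV^-1.

    For gates whose alpha and beta are both pure exponentials this is
    voltage independent and equals the sum of the two log-slopes; its
    reciprocal is the effective e-fold voltage scale at E.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    E_arr = np.asarray(E, dtype=float)
    vals = []
    for Eh in (E_arr + h, E_arr - h):
        a = np.asarray(rate_value(gate, "alpha", Eh), dtype=float)
        b = np.asarray(rate_value(gate, "beta", Eh), dtype=float)
        if np.any(a <= 0.0) or np.any(b <= 0.0):
            raise ValueError("alpha and beta must be positive on the stencil")
        vals.append(np.log(a / b))
    out = (vals[0] - vals[1]) / (2.0 * h)
    return out.item() if np.isscalar(E) or out.ndim == 0 else out


def efold_scales(
    gates: dict[str, GateSpec] | None = None,
) -> dict[str, float]:
    """E-fold voltage scales (mV) of every exponential rate component.

    Keys are ``"alpha_<gate>"`` / ``"beta_<gate>"``; rates of constant
    form carry no exponential factor and are omitted.
    """
    gates = CANONICAL_GATES if gates is None else gates
    scales: dict[str, float] = {}
    for label, gate in gates.items():
        for which in ("alpha", "beta"):
            s = gate.efold_scale(which)  # type: ignore[arg-type]
            if s is not None:
                scales[f"{which}_{label}"] = s
    return scales
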