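"""Full Hodgkin-Huxley membrane dynamics and clamp protocols.

State is (E, m, h, n): membrane potential in mV plus three gating
variables.  Membrane current balance:

    C_M dE/dt = I_inj - [ gNa_max m^3 h (E - ENa)
                          + gK_max n^4 (E - EK) + gL_max (E - EL) ]

with first-order gate kinetics d xi/dt = alpha(E)(1 - xi) - beta(E) xi.
Integration is classical fixed-step RK4 (deterministic, reproducible).
In voltage clamp the potential follows the command waveform and only
the gates evolve.

Units package-wide: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .rate_functions import CANONICAL_GATES, steady_state

__all__ = [
    "MembraneParams",
    "Protocol",
    "Trajectory",
    "gating_derivative",
    "ionic_current",
    "resting_state",
    "simulate",
]

#: fixed-step stability contract for the default RK4 integrator (ms)
DT_STABLE = 0.05

#: tolerance on gate range checks
GATE_TOL = 1e-7


@dataclass(frozen=True)
class MembraneParams:
    """Membrane parameters: maximal conductances, reversals, capacitance.

    Defaults are the classical squid-axon values in the absolute-voltage
    convention (gNa_max=120, gK_max=36 mS/cm^2; leak and reversals are
    conventional, with EL tuned so the resting potential sits near
    -65 mV).
    """

    gNa_max: float = 120.0
    gK_max: float = 36.0
    gL_max: float = 0.3
    ENa: float = 50.0
    EK: float = -77.0
    EL: float = -54.387
    CM: float = 1.0
    temperature_C: float = 6.3

    def __post_init__(self) -> None:
        for name in ("gNa_max", "gK_max", "gL_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.CM <= 0:
            raise ValueError("CM must be > 0")

    def scaled(self, lam: float) -> "MembraneParams":
        """All maximal conductances scaled by lam > 0."""
        if lam <= 0:
            raise ValueError("conductance scale factor must be > 0")
        return MembraneParams(
            gNa_max=lam * self.gNa_max,
            gK_max=lam * self.gK_max,
            gL_max=lam * self.gL_max,
            ENa=self.ENa,
            EK=self.EK,
            EL=self.EL,
            CM=self.CM,
            temperature_C=self.temperature_C,
        )


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant stimulus protocol.

    ``segments`` is a list of (duration_ms, level); in current clamp the
    level is injected current (uA/cm^2), in voltage clamp it is the
    command potential (mV).  ``initial_policy`` selects either gates at
    their steady state for ``hold_E`` or an explicit initial state.
    """

    kind: str  # "current_clamp" | "voltage_clamp"
    segments: tuple[tuple[float, float], ...]
    initial_policy: str = "steady_state_at_hold"
    hold_E: float = -65.0
    initial_state: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, _ in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
        if self.initial_policy not in ("steady_state_at_hold", "explicit"):
            raise ValueError(f"unknown initial policy {self.initial_policy!r}")
        if self.initial_policy == "explicit" and self.initial_state is None:
            raise ValueError("explicit initial policy requires initial_state")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def is_autonomous(self) -> bool:
        """True when the stimulus is constant in time (single level)."""
        levels = {lvl for _, lvl in self.segments}
        return len(levels) == 1

    def level_at(self, t: float) -> float:
        """Stimulus level at local protocol time t (last level held)."""
        acc = 0.0
        for dur, lvl in self.segments:
            acc += dur
            if t < acc:
                return lvl
        return self.segments[-1][1]


@dataclass
class Trajectory:
    """Simulated time series of state and derived conductances.

    gNa = gNa_max * m^3 h and gK = gK_max * n^4 are the instantaneous
    conductances; the maximal conductances in ``params`` stay fixed.
    """

    t: np.ndarray
    E: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    gNa: np.ndarray
    gK: np.ndarray
    params: MembraneParams
    dt: float
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arrays = (self.t, self.E, self.m, self.h, self.n, self.gNa, self.gK)
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("trajectory arrays must share length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def gate_excursion(self) -> float:
        """Worst excursion of any gate outside [0, 1] (0 if none)."""
        gates = np.stack([self.m, self.h, self.n])
        return float(np.maximum(-gates, gates - 1.0).max().clip(min=0.0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t,
                "E_mV": self.E,
                "m": self.m,
                "h": self.h,
                "n": self.n,
                "gNa_mS_cm2": self.gNa,
                "gK_mS_cm2": self.gK,
            }
        )


def gating_derivative(xi: float, alpha: float, beta: float) -> float:
    """First-order gate kinetics: d xi/dt = alpha (1 - xi) - beta xi."""
    return alpha * (1.0 - xi) - beta * xi


def ionic_current(
    state: tuple[float, float, float, float], params: MembraneParams
) -> float:
    """Total ionic current (uA/cm^2) at the given state.

    Sum of the sodium (m^3 h gating), potassium (n^4) and leak Ohmic
    terms; excludes the capacitive term.  Gates must lie in [0, 1] to
    within a small tolerance.
    """
    E, m, h, n = state
    for name, val in (("m", m), ("h", h), ("n", n)):
        if val < -GATE_TOL or val > 1.0 + GATE_TOL:
            raise ValueError(f"gate {name}={val} outside [0, 1]")
    return (
        params.gNa_max * m**3 * h * (E - params.ENa)
        + params.gK_max * n**4 * (E - params.EK)
        + params.gL_max * (E - params.EL)
    )


def _gate_rates(E: float) -> tuple[float, float, float, float, float, float]:
    # scalar fast path for the inner RK4 loop; identical formulas to
    # rate_functions (linoverexp limits handled the same way)
    x = E + 40.0
    am = 1.0 if abs(x) < 1e-7 else 0.1 * x / (-math.expm1(-x / 10.0))
    bm = 0.108 * math.exp(-E / 18.0)
    ah = 0.0027 * math.exp(-E / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(E + 35.0) / 10.0))
    x = E + 55.0
    an = 0.1 if abs(x) < 1e-7 else 0.01 * x / (-math.expm1(-x / 10.0))
    bn = 0.0555 * math.exp(-E / 80.0)
    return am, bm, ah, bh, an, bn


def steady_gates(E: float) -> tuple[float, float, float]:
    """Gate steady states (m_inf, h_inf, n_inf) at potential E."""
    return (
        steady_state(CANONICAL_GATES["m"], E),
        steady_state(CANONICAL_GATES["h"], E),
        steady_state(CANONICAL_GATES["n"], E),
    )


def resting_state(
    params: MembraneParams, bracket: tuple[float, float] = (-90.0, -40.0)
) -> tuple[float, float, float, float]:
    """True resting equilibrium: E* with I_ion(E*, xi_inf(E*)) = 0.

    Solved by bracketed root finding; with the default parameters the
    root lies near -65 mV.
    """

    def net_current(E: float) -> float:
        m, h, n = steady_gates(E)
        return ionic_current((E, m, h, n), params)

    E_star = brentq(net_current, *bracket, xtol=1e-12)
    m, h, n = steady_gates(E_star)
    return (float(E_star), m, h, n)


def _deriv_current_clamp(
    y: np.ndarray, I_inj: float, params: MembraneParams
) -> np.ndarray:
    E, m, h, n = y
    am, bm, ah, bh, an, bn = _gate_rates(E)
    I_ion = (
        params.gNa_max * m**3 * h * (E - params.ENa)
        + params.gK_max * n**4 * (E - params.EK)
        + params.gL_max * (E - params.EL)
    )
    return np.array(
        [
            (I_inj - I_ion) / params.CM,
            gating_derivative(m, am, bm),
            gating_derivative(h, ah, bh),
            gating_derivative(n, an, bn),
        ]
    )


def _deriv_voltage_clamp(y: np.ndarray, E_cmd: float) -> np.ndarray:
    _, m, h, n = y
    am, bm, ah, bh, an, bn = _gate_rates(E_cmd)
    return np.array(
        [
            0.0,
            gating_derivative(m, am, bm),
            gating_derivative(h, ah, bh),
            gating_derivative(n, an, bn),
        ]
    )


def simulate(
    params: MembraneParams,
    protocol: Protocol,
    dt: float = 0.01,
    t_end: float | None = None,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate the membrane equations with fixed-step RK4.

    ``t_end`` defaults to the protocol's total duration; ``t0`` offsets
    the reported time axis only (the dynamics are autonomous, so the
    arithmetic is identical for any offset).  Raises on NaN/overflow
    during integration; a dt above the stability contract is recorded
    as a warning in the trajectory provenance.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    warn_list: list[str] = []
    if dt > DT_STABLE:
        msg = f"dt={dt} exceeds stability contract {DT_STABLE} ms"
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)
    if t_end is None:
        t_end = protocol.total_duration

    n_steps = int(round(t_end / dt))
    t_local = np.arange(n_steps + 1) * dt

    if protocol.initial_policy == "explicit":
        y = np.array(protocol.initial_state, dtype=float)
    else:
        hold = (
            protocol.hold_E
            if protocol.kind == "current_clamp"
            else protocol.segments[0][1]
        )
        m0, h0, n0 = steady_gates(hold)
        y = np.array([hold, m0, h0, n0])

    current_clamp = protocol.kind == "current_clamp"
    ys = np.empty((n_steps + 1, 4))
    ys[0] = y
    for i in range(n_steps):
        t = t_local[i]
        if current_clamp:
            lvl = protocol.level_at(t)
            lvl_mid = protocol.level_at(t + 0.5 * dt)
            lvl_end = protocol.level_at(t + dt)
            k1 = _deriv_current_clamp(y, lvl, params)
            k2 = _deriv_current_clamp(y + 0.5 * dt * k1, lvl_mid, params)
            k3 = _deriv_current_clamp(y + 0.5 * dt * k2, lvl_mid, params)
            k4 = _deriv_current_clamp(y + dt * k3, lvl_end, params)
        else:
            E_cmd = protocol.level_at(t)
            E_mid = protocol.level_at(t + 0.5 * dt)
            E_end = protocol.level_at(t + dt)
            y[0] = E_cmd
            k1 = _deriv_voltage_clamp(y, E_cmd)
            k2 = _deriv_voltage_clamp(y + 0.5 * dt * k1, E_mid)
            k3 = _deriv_voltage_clamp(y + 0.5 * dt * k2, E_mid)
            k4 = _deriv_voltage_clamp(y + dt * k3, E_end)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not current_clamp:
            y[0] = protocol.level_at(t + dt)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"integration diverged at step {i + 1} (t={t + dt:.4f} ms)"
            )
        ys[i + 1] = y

    E, m, h, n = ys.T
    return Trajectory(
        t=t_local + t0,
        E=E.copy(),
        m=m.copy(),
        h=h.copy(),
        n=n.copy(),
        gNa=params.gNa_max * m**3 * h,
        gK=params.gK_max * n**4,
        params=params,
        dt=dt,
        warnings_=warn_list,
    )
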