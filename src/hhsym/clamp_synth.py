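"""Synthetic voltage-clamp conductance traces.

Emulates step-protocol voltage-clamp experiments on Na and K channels:
from a holding potential the command steps to a test level and the
instantaneous conductance g(t) = g_max * act(t)^p * inact(t)^q is
recorded.  Gates evolve by the exact closed-form clamp solution

    xi(t) = xi_inf(V) + (xi_inf(hold) - xi_inf(V)) * exp(-t / tau(V)),

not by the ODE integrator, so the traces are oracle-exact and any
fitting error is attributable to the fitter.  Optional additive i.i.d.
Gaussian noise with an explicit integer seed makes noisy datasets
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .membrane_model import MembraneParams
from .rate_functions import CANONICAL_GATES, GateSpec, steady_state, time_constant

__all__ = ["ClampTrace", "ClampDataset", "synthesize_clamp",
           "write_dataset", "read_dataset", "clamp_gate_course"]

V_MIN, V_MAX = -120.0, 60.0

#: activation / inactivation gate for each channel
CHANNEL_GATES: dict[str, tuple[GateSpec, GateSpec]] = {
    "Na": (CANONICAL_GATES["m"], CANONICAL_GATES["h"]),
    "K": (CANONICAL_GATES["n"], CANONICAL_GATES["h"]),
}


def clamp_gate_course(
    gate: GateSpec, hold: float, step: float, t: np.ndarray
) -> np.ndarray:
    """Exact gate relaxation under a voltage step hold -> step."""
    xi0 = steady_state(gate, hold)
    xi_inf = steady_state(gate, step)
    tau = time_constant(gate, step)
    return xi_inf + (xi0 - xi_inf) * np.exp(-t / tau)


@dataclass(frozen=True)
class ClampTrace:
    trace_id: str
    channel: str
    hold_mV: float
    step_mV: float
    t: np.ndarray
    g: np.ndarray


@dataclass
class ClampDataset:
    """Collection of voltage-step conductance traces with provenance."""

    traces: list[ClampTrace]
    noise_sd: float
    seed: int
    dt: float
    true_exponents: tuple[float, float] | None = None
    notes: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "channel": tr.channel,
                    "hold_mV": tr.hold_mV,
                    "step_mV": tr.step_mV,
                    "t_ms": tr.t,
                    "g_mS_cm2": tr.g,
                }
            )
            for tr in self.traces
        ]
        return pd.concat(frames, ignore_index=True)


def synthesize_clamp(
    params: MembraneParams,
    channel: str,
    steps: list[float],
    hold: float = -65.0,
    duration: float = 20.0,
    dt: float = 0.05,
    exponents: tuple[float, float] = (4, 0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ClampDataset:
    """Generate a synthetic step-protocol clamp dataset.

    ``exponents = (p, q)`` are the activation and inactivation powers;
    integers reproduce the canonical n^4 / m^3 h conductances, and real
    values are accepted so symmetry-broken (fractional-exponent) data
    can be produced for diagnostics.  Deterministic given ``seed``;
    exactly noiseless when ``noise_sd`` is 0.
    """
    if channel not in CHANNEL_GATES:
        raise ValueError(f"channel must be 'Na' or 'K', got {channel!r}")
    p, q = exponents
    if p < 1:
        raise ValueError("activation exponent p must be >= 1")
    if q < 0:
        raise ValueError("inactivation exponent q must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for v in [hold, *steps]:
        if not (V_MIN <= v <= V_MAX):
            raise ValueError(f"voltage {v} mV outside [{V_MIN}, {V_MAX}]")
    act_gate, inact_gate = CHANNEL_GATES[channel]
    notes: list[str] = []
    if channel == "K" and q > 0:
        notes.append(
            "inactivation exponent q > 0 on channel K: hypothetical channel"
        )
    # the slowest relaxation must be well resolved by the trace length
    taus = [time_constant(act_gate, v) for v in steps]
    if q > 0:
        taus += [time_constant(inact_gate, v) for v in steps]
    if duration < 5.0 * max(taus):
        raise ValueError(
            f"duration {duration} ms < 5*max tau ({5 * max(taus):.2f} ms)"
        )

    g_max = params.gNa_max if channel == "Na" else params.gK_max
    t = np.arange(int(round(duration / dt)) + 1) * dt
    rng = np.random.default_rng(seed)
    traces = []
    for i, step in enumerate(steps):
        act = clamp_gate_course(act_gate, hold, step, t)
        g = g_max * act**p
        if q > 0:
            inact = clamp_gate_course(inact_gate, hold, step, t)
            g = g * inact**q
        if noise_sd > 0:
            g = g + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(
            ClampTrace(
                trace_id=f"{channel}_{i:02d}",
                channel=channel,
                hold_mV=hold,
                step_mV=step,
                t=t.copy(),
                g=g,
            )
        )
    return ClampDataset(
        traces=traces,
        noise_sd=noise_sd,
        seed=seed,
        dt=dt,
        true_exponents=(p, q),
        notes=notes,
    )


def write_dataset(ds: ClampDataset, out_dir: str | Path) -> None:
    """Write traces CSV plus JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.to_dataframe().to_csv(out / "traces.csv", index=False)
    meta = {
        "seed": ds.seed,
        "noise_sd": ds.noise_sd,
        "dt_ms": ds.dt,
        "true_exponents": list(ds.true_exponents)
        if ds.true_exponents
        else None,
        "notes": ds.notes,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_dataset(in_dir: str | Path) -> ClampDataset:
    """Load a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    df = pd.read_csv(src / "traces.csv")
    meta_path = src / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        traces.append(
            ClampTrace(
                trace_id=str(tid),
                channel=str(grp["channel"].iloc[0]),
                hold_mV=float(grp["hold_mV"].iloc[0]),
                step_mV=float(grp["step_mV"].iloc[0]),
                t=grp["t_ms"].to_numpy(),
                g=grp["g_mS_cm2"].to_numpy(),
            )
        )
    dt = float(traces[0].t[1] - traces[0].t[0]) if len(traces[0].t) > 1 else 0.0
    exps = meta.get("true_exponents")
    return ClampDataset(
        traces=traces,
        noise_sd=float(meta.get("noise_sd", 0.0)),
        seed=int(meta.get("seed", 0)),
        dt=float(meta.get("dt_ms", dt)),
        true_exponents=tuple(exps) if exps else None,
        notes=list(meta.get("notes", [])),
    )
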