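"""Run configuration and deterministic report serialization.

Configuration files are YAML (or JSON, a YAML subset) with three
optional blocks::

    params:    {gNa_max: 120, gK_max: 36, gL_max: 0.3, ENa: 50,
                EK: -77, EL: -54.387, CM: 1, temperature_C: 6.3}
    protocol:  {kind: current_clamp, segments: [[50, 0.0]],
                hold_E: -65}
    integrator: {dt: 0.01, t_end: null}
    seed: 0

Unknown keys are rejected (naming the field), every defaulted field is
recorded in the provenance, and serialization is deterministic so the
same object always produces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from . import __version__
from .membrane_model import MembraneParams, Protocol

__all__ = ["ConfigError", "RunConfig", "load_config", "write_report"]


class ConfigError(ValueError):
    """Invalid or unknown configuration field."""


_PROTOCOL_KEYS = {"kind", "segments", "initial_policy", "hold_E", "initial_state"}
_INTEGRATOR_KEYS = {"dt", "t_end"}
_TOP_KEYS = {"params", "protocol", "integrator", "seed", "tolerances"}

_DEFAULT_PROTOCOL = Protocol(
    kind="current_clamp", segments=((50.0, 0.0),), hold_E=-65.0
)


@dataclass
class RunConfig:
    params: MembraneParams = field(default_factory=MembraneParams)
    protocol: Protocol = field(default_factory=lambda: _DEFAULT_PROTOCOL)
    dt: float = 0.01
    t_end: float | None = None
    seed: int = 0
    tolerances: dict = field(default_factory=dict)
    defaulted_fields: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": {
                f.name: getattr(self.params, f.name)
                for f in dc_fields(MembraneParams)
            },
            "protocol": {
                "kind": self.protocol.kind,
                "segments": [list(s) for s in self.protocol.segments],
                "initial_policy": self.protocol.initial_policy,
                "hold_E": self.protocol.hold_E,
            },
            "integrator": {"dt": self.dt, "t_end": self.t_end},
            "seed": self.seed,
            "tolerances": self.tolerances,
        }


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in {where}")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration, filling defaults.

    An empty file yields all documented defaults; every field that fell
    back to its default is listed in ``defaulted_fields``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")

    defaulted: list[str] = []

    params_block = raw.get("params", {}) or {}
    allowed_params = {f.name for f in dc_fields(MembraneParams)}
    _reject_unknown(params_block, allowed_params, "params")
    for name in sorted(allowed_params - set(params_block)):
        defaulted.append(f"params.{name}")
    try:
        params = MembraneParams(**params_block)
    except ValueError as err:
        raise ConfigError(f"params: {err}") from err

    proto_block = raw.get("protocol")
    if proto_block is None:
        protocol = _DEFAULT_PROTOCOL
        defaulted.append("protocol")
    else:
        _reject_unknown(proto_block, _PROTOCOL_KEYS, "protocol")
        try:
            segments = tuple(
                (float(d), float(lvl))
                for d, lvl in proto_block.get("segments", [[50.0, 0.0]])
            )
            protocol = Protocol(
                kind=proto_block.get("kind", "current_clamp"),
                segments=segments,
                initial_policy=proto_block.get(
                    "initial_policy", "steady_state_at_hold"
                ),
                hold_E=float(proto_block.get("hold_E", -65.0)),
                initial_state=(
                    tuple(proto_block["initial_state"])
                    if proto_block.get("initial_state") is not None
                    else None
                ),
            )
        except (ValueError, TypeError) as err:
            raise ConfigError(f"protocol: {err}") from err

    integ = raw.get("integrator", {}) or {}
    _reject_unknown(integ, _INTEGRATOR_KEYS, "integrator")
    dt = float(integ.get("dt", 0.01))
    if "dt" not in integ:
        defaulted.append("integrator.dt")
    if dt <= 0:
        raise ConfigError("integrator.dt must be positive")
    t_end = integ.get("t_end")
    t_end = None if t_end is None else float(t_end)

    if "seed" not in raw:
        defaulted.append("seed")
    return RunConfig(
        params=params,
        protocol=protocol,
        dt=dt,
        t_end=t_end,
        seed=int(raw.get("seed", 0)),
        tolerances=dict(raw.get("tolerances", {}) or {}),
        defaulted_fields=defaulted,
    )


def write_report(obj, path: str | Path, format: str = "json") -> None:
    """Serialize a report object deterministically.

    JSON output carries a package version stamp and preserves the
    object's field order; CSV goes through the object's declared
    ``to_dataframe``.  The same object always yields identical bytes.
    """
    path = Path(path)
    if format == "json":
        if hasattr(obj, "to_dict"):
            payload = obj.to_dict()
        elif isinstance(obj, dict):
            payload = obj
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__} to JSON")
        doc = {"hhsym_version": __version__, **payload}
        path.write_text(json.dumps(doc, indent=2, default=float) + "\n")
    elif format == "csv":
        if not hasattr(obj, "to_dataframe"):
            raise TypeError(f"cannot serialize {type(obj).__name__} to CSV")
        obj.to_dataframe().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
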