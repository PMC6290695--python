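"""Configuration file round-tripping (TOML canonical, JSON accepted).

The on-disk layout mirrors :class:`~isrsim.engine.SimulationConfig`:
scalar geometry/run fields at the top level and one table each for
``[scenario]``, ``[growth]``, ``[mechanics]`` and ``[flow]``.  The writer is
deterministic (sorted keys, repr floats) so regenerating a campaign produces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Any

from .engine import SimulationConfig
from .growth import GrowthParams, ScenarioSchedule
from .hemodynamics import FlowParams
from .mechanics import MechanicsParams

__all__ = ["config_to_dict", "config_from_dict", "load_config",
           "save_config", "dumps_toml"]

_SECTIONS = {
    "scenario": ScenarioSchedule,
    "growth": GrowthParams,
    "mechanics": MechanicsParams,
    "flow": FlowParams,
}


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in dataclasses.fields(SimulationConfig):
        value = getattr(config, f.name)
        if f.name in _SECTIONS:
            out[f.name] = dataclasses.asdict(value)
        elif f.name == "snapshot_days":
            if value is not None:
                out[f.name] = list(value)
        else:
            out[f.name] = value
    return out


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = cls(**data.pop(name))
    if "snapshot_days" in data:
        sd = data.pop("snapshot_days")
        kwargs["snapshot_days"] = tuple(sd) if sd is not None else None
    kwargs.update(data)
    return SimulationConfig(**kwargs)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dumps_toml(data: dict[str, Any]) -> str:
    """Minimal deterministic TOML emitter for flat table-of-scalars configs."""
    lines: list[str] = []
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    for key in sorted(scalars):
        if scalars[key] is None:
            continue
        lines.append(f"{key} = {_toml_value(scalars[key])}")
    for tname in sorted(tables):
        lines.append("")
        lines.append(f"[{tname}]")
        for key in sorted(tables[tname]):
            value = tables[tname][key]
            if value is None:
                continue
            lines.append(f"{key} = {_toml_value(value)}")
    return "\n".join(lines) + "\n"


def save_config(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(dumps_toml(data))


def load_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return config_from_dict(data)
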