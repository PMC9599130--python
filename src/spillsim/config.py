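"""Configuration loading: TOML or JSON files with [geometry], [simulation]
and [sweep] sections, validated into the corresponding parameter models.

Unknown sections or keys are rejected with the offending key path.  A file
may contain any subset of the three sections; omitted fields take the
documented defaults.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

from pydantic import ValidationError

from .dynamics import SimulationConfig
from .experiments import SweepSpec
from .geometry import GeometryParams

_SECTIONS = {"geometry", "simulation", "sweep"}


class ConfigError(ValueError):
    """Invalid configuration file."""


@dataclass(frozen=True)
class ConfigBundle:
    geometry: GeometryParams
    simulation: SimulationConfig
    sweep: SweepSpec | None = None


def _format_validation_error(section: str, err: ValidationError) -> str:
    lines = [f"invalid [{section}] configuration:"]
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {section}.{loc}: {e['msg']}")
    return "\n".join(lines)


def parse_config(raw: dict) -> ConfigBundle:
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(
            f"unknown config section(s): {', '.join(sorted(unknown))}; "
            f"expected {sorted(_SECTIONS)}")
    try:
        geometry = GeometryParams.model_validate(raw.get("geometry", {}))
    except ValidationError as err:
        raise ConfigError(_format_validation_error("geometry", err)) from err
    try:
        simulation = SimulationConfig.model_validate(raw.get("simulation", {}))
    except ValidationError as err:
        raise ConfigError(_format_validation_error("simulation", err)) from err
    sweep = None
    if "sweep" in raw:
        sweep_raw = dict(raw["sweep"])
        sweep_raw.setdefault("base_config", simulation.model_dump())
        sweep_raw.setdefault("base_geometry_params", geometry.model_dump())
        try:
            sweep = SweepSpec.model_validate(sweep_raw)
        except ValidationError as err:
            raise ConfigError(_format_validation_error("sweep", err)) from err
    return ConfigBundle(geometry=geometry, simulation=simulation, sweep=sweep)


def load_config(path: str | Path) -> ConfigBundle:
    """Load and validate a TOML (.toml) or JSON (.json) configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format: {path.suffix} "
                          "(use .toml or .json)")
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a table/object")
    return parse_config(raw)


def dump_config(bundle: ConfigBundle) -> dict:
    """Normalized dict form; load(dump(x)) round-trips."""
    out = {"geometry": bundle.geometry.model_dump(),
           "simulation": bundle.simulation.model_dump()}
    if bundle.sweep is not None:
        out["sweep"] = bundle.sweep.model_dump()
    return out


def save_config_json(path: str | Path, bundle: ConfigBundle) -> None:
    Path(path).write_text(json.dumps(dump_config(bundle), indent=2) + "\n")
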