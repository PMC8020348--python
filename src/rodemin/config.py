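"""Structured-text (YAML) run configuration.

One file with sections ``geometry``, ``orientation``, ``diffusivity``,
``kinetics``, ``levelset`` and ``run``; every key carries its unit in its
name (``_um``, ``_um2s``, ``_s`` ...).  All sections and keys are optional
except that a run section must state at least ``ph_acid`` and
``duration_s``; unknown sections or keys are rejected with the full key
path so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Any, Dict, Mapping, Optional

import yaml

from .geometry import GeometryConfig
from .orientation import LocalDiffusivity, OrientationModel
from .solver import (
    KineticsParams,
    LevelSetParams,
    SimulationConfig,
    SolverOptions,
)

__all__ = ["load_config", "loads_config", "dump_config", "config_to_dict", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file problem, annotated with the offending key path."""


_GEOMETRY_KEYS = {
    "l_um": "l", "L_um": "L", "rho_head_um": "rho_head", "sheath_um": "sheath_thickness",
    "nx": "nx", "ny": "ny", "nz": "nz", "head_center_um": "head_center",
    "tail_width_um": "tail_width", "tail_length_um": "tail_length",
    "tail_tip_ratio": "tail_tip_ratio",
}
_ORIENTATION_KEYS = {
    "theta_coeffs": "theta_coeffs", "psi_coeffs": "psi_coeffs",
    "max_angle_rad": "max_angle_rad", "transition_um": "transition_um",
}
_DIFFUSIVITY_KEYS = {
    "d_fast_um2s": "d_fast", "d_trans_um2s": "d_trans",
    "d_sheath_um2s": "d_sheath", "d_demin_um2s": "d_demin",
}
_KINETICS_KEYS = {
    "k_per_s": "k", "Hc_mol_l": "Hc", "ph_threshold": "pH_threshold",
    "porosity_eps_t": "porosity_eps_t", "constrictivity_delta": "constrictivity_delta",
    "tortuosity_tau": "tortuosity_tau",
}
_LEVELSET_KEYS = {
    "gamma_um_s": "gamma", "eps_um": "eps", "demin_rate_per_s": "demin_rate",
    "grad_floor": "grad_floor", "cfl_safety": "cfl_safety",
}
_RUN_KEYS = {
    "scenario": "scenario", "ph_acid": "pH_acid", "duration_s": "duration_s",
    "dt_s": "dt_s", "snapshot_every_s": "snapshot_every_s",
    "store_states": "store_states", "H_initial_mol_l": "H_initial",
    "H_far_mol_l": "H_far",
}
_SOLVER_KEYS = {
    "method": "method", "direct_limit": "direct_limit",
    "adi_rate_cap": "adi_rate_cap", "phi_drift_refresh": "phi_drift_refresh",
}
_SECTIONS = {
    "geometry": _GEOMETRY_KEYS, "orientation": _ORIENTATION_KEYS,
    "diffusivity": _DIFFUSIVITY_KEYS, "kinetics": _KINETICS_KEYS,
    "levelset": _LEVELSET_KEYS, "run": _RUN_KEYS, "solver": _SOLVER_KEYS,
}


def _translate(section: str, data: Mapping[str, Any], keymap: Mapping[str, str]) -> Dict[str, Any]:
    if not isinstance(data, Mapping):
        raise ConfigError(f"section {section!r} must be a mapping")
    out: Dict[str, Any] = {}
    for key, value in data.items():
        if key not in keymap:
            raise ConfigError(f"unknown key {section}.{key}")
        out[keymap[key]] = value
    return out


def _build(section: str, cls, kwargs: Dict[str, Any]):
    # normalise sequences to tuples for frozen dataclasses
    for name in ("head_center", "theta_coeffs", "psi_coeffs"):
        if name in kwargs and kwargs[name] is not None:
            kwargs[name] = tuple(float(v) for v in kwargs[name])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} configuration: {exc}") from exc


def parse_config(raw: Mapping[str, Any]) -> SimulationConfig:
    """Validate a parsed mapping and build a fully-defaulted configuration."""
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping of sections")
    for section in raw:
        if section not in _SECTIONS:
            raise ConfigError(f"unknown section {section!r}")
    geo = _build("geometry", GeometryConfig,
                 _translate("geometry", raw.get("geometry", {}), _GEOMETRY_KEYS))
    ori = _build("orientation", OrientationModel,
                 _translate("orientation", raw.get("orientation", {}), _ORIENTATION_KEYS))
    dif = _build("diffusivity", LocalDiffusivity,
                 _translate("diffusivity", raw.get("diffusivity", {}), _DIFFUSIVITY_KEYS))
    kin = _build("kinetics", KineticsParams,
                 _translate("kinetics", raw.get("kinetics", {}), _KINETICS_KEYS))
    lvl = _build("levelset", LevelSetParams,
                 _translate("levelset", raw.get("levelset", {}), _LEVELSET_KEYS))
    sol = _build("solver", SolverOptions,
                 _translate("solver", raw.get("solver", {}), _SOLVER_KEYS))
    run = _translate("run", raw.get("run", {}), _RUN_KEYS)
    cfg = _build("run", SimulationConfig, dict(
        geometry=geo, orientation=ori, diffusivity=dif, kinetics=kin,
        levelset=lvl, solver=sol, **run,
    ))
    return cfg


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML run configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return parse_config(raw)


def loads_config(text: str) -> SimulationConfig:
    """Parse a YAML configuration from a string."""
    return parse_config(yaml.safe_load(text) or {})


def _section_dict(obj, keymap: Mapping[str, str]) -> Dict[str, Any]:
    data = asdict(obj)
    out = {}
    for file_key, attr in keymap.items():
        v = data[attr]
        if isinstance(v, tuple):
            v = list(v)
        out[file_key] = v
    return out


def config_to_dict(config: SimulationConfig) -> Dict[str, Any]:
    """Full round-trippable mapping of a configuration (defaults included)."""
    run = {
        "scenario": config.scenario, "ph_acid": config.pH_acid,
        "duration_s": config.duration_s, "dt_s": config.dt_s,
        "snapshot_every_s": config.snapshot_every_s,
        "store_states": config.store_states,
        "H_initial_mol_l": config.H_initial, "H_far_mol_l": config.H_far,
    }
    out = {
        "geometry": _section_dict(config.geometry, _GEOMETRY_KEYS),
        "orientation": _section_dict(config.orientation, _ORIENTATION_KEYS),
        "diffusivity": _section_dict(config.diffusivity, _DIFFUSIVITY_KEYS),
        "kinetics": _section_dict(config.kinetics, _KINETICS_KEYS),
        "levelset": _section_dict(config.levelset, _LEVELSET_KEYS),
        "solver": _section_dict(config.solver, _SOLVER_KEYS),
        "run": run,
    }
    # tuples come back as lists from asdict-free paths
    hc = out["geometry"]["head_center_um"]
    if hc is not None:
        out["geometry"]["head_center_um"] = [float(v) for v in hc]
    return out


def dump_config(config: SimulationConfig, path: Optional[str] = None) -> str:
    """Serialise a configuration to YAML; round-trips to an equal config."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
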