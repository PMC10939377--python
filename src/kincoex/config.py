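"""Run configuration: YAML parsing, validation, defaults, and echo.

A run configuration is a nested key-value file with sections ``model``,
``protocol`` (required), and optional ``sweep``, ``synth``, ``solver``,
``output``, ``seed``, ``log_level``.  Unknown keys anywhere are rejected,
and every run writes back a fully resolved configuration echo so results
can be reproduced from the echo alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

from .model import (
    CommunityModel,
    DeathModel,
    InteractionMatrix,
    StrainParams,
    default_two_member,
)
from .protocol import ProtocolSpec, SolverOptions
from .synth import SynthConfig, SynthStrain

__all__ = ["ConfigError", "RunConfig", "parse_config", "default_config",
           "echo_config"]


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every offending key."""

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


REQUIRED_SECTIONS = ("model", "protocol")

_DEFAULT_MODEL_SECTION = {
    "members": [
        {"name": "cooperator_A", "role": "cooperator",
         "max_growth_rate": 0.5, "allee_constant": 0.0},
        {"name": "cheater_B", "role": "cheater",
         "max_growth_rate": 0.75, "allee_constant": 0.0},
    ],
    "interactions": {
        "coefficients": [[0.0, 1.9], [1.75, 0.0]],
        "symmetric_regulator": False,
    },
    "deaths": [
        {"kind": "constant", "constant_rate": -0.6},
        {"kind": "linear_in_density", "slope": -5.0, "intercept": 1.0},
    ],
}

_DEFAULT_PROTOCOL_SECTION = {
    "cycle_hours": 24.0,
    "n_cycles": 7,
    "dilution_mode": "to_fixed_total",
    "dilution_factor": 10.0,
    "initial_total_density": 0.03,
    "initial_proportions": None,
    "antibiotic_window": [72.0, 96.0],
}

_DEFAULT_SWEEP_SECTION = {
    "n_points": 25,
    "cheater_rate_min": 0.3,
    "cheater_rate_max": 0.75,
    "density_min": 1e-4,
    "density_max": 1e-1,
    "alpha_min": -1.0,
    "alpha_max": 2.0,
    "phenotypes": ["sensitive", "detoxifying", "intrinsic"],
    "regulator_rate": 0.75,
    "sweep_density": 0.03,
    "sweep_n_cycles": 7,
}

_DEFAULT_SYNTH_SECTION = {
    "strains": [
        {"name": "cooperator_A", "growth_rate": 0.5, "smx_death_rate": -0.6},
        {"name": "cheater_B", "growth_rate": 0.75, "smx_death_rate": 0.8},
    ],
    "inoculum_min": 1e5,
    "inoculum_max": 1e9,
    "inoculum_n": 5,
    "smx_concentration": 200.0,
    "replicates": 6,
    "od_noise_sigma": 0.02,
    "sampling_interval": 0.5,
    "horizon": 72.0,
    "clearance_coefficient": 1e-6,
    "smx_noise_sigma": 5.0,
    "cooperator_density": 1e7,
}

_DEFAULT_SOLVER_SECTION = {
    "method": "LSODA",
    "rtol": 1e-8,
    "atol": 1e-12,
    "output_resolution": 0.1,
    "extinction_floor": 1e-9,
}


def default_config() -> Dict[str, Any]:
    """Fully resolved shipped default configuration (deep copy)."""
    return copy.deepcopy(
        {
            "model": _DEFAULT_MODEL_SECTION,
            "protocol": _DEFAULT_PROTOCOL_SECTION,
            "sweep": _DEFAULT_SWEEP_SECTION,
            "synth": _DEFAULT_SYNTH_SECTION,
            "solver": _DEFAULT_SOLVER_SECTION,
            "output": {"directory": "kincoex_out"},
            "seed": 0,
            "log_level": "INFO",
        }
    )


def _merge(defaults: Any, user: Any, path: str, errors: List[str]) -> Any:
    """Deep-merge ``user`` onto ``defaults``, rejecting unknown keys."""
    if isinstance(defaults, dict):
        if not isinstance(user, dict):
            errors.append(f"{path}: expected a mapping")
            return copy.deepcopy(defaults)
        out = copy.deepcopy(defaults)
        for key, value in user.items():
            if key not in defaults:
                errors.append(f"{path}.{key}: unknown key")
                continue
            out[key] = _merge(defaults[key], value, f"{path}.{key}", errors)
        return out
    # lists of member/death dicts replace wholesale (lengths may differ)
    return copy.deepcopy(user)


@dataclass
class RunConfig:
    """A fully resolved run configuration with built domain objects."""

    model: CommunityModel
    protocol: ProtocolSpec
    sweep: Dict[str, Any]
    synth: SynthConfig
    solver: SolverOptions
    output_dir: Path
    seed: int
    log_level: str
    resolved: Dict[str, Any] = field(repr=False, default_factory=dict)


def _build_model(section: Dict[str, Any], window, errors: List[str]):
    try:
        members = tuple(
            StrainParams(
                name=str(m.get("name", f"member_{i}")),
                role=str(m.get("role", "cooperator")),
                max_growth_rate=float(m.get("max_growth_rate", 0.5)),
                allee_constant=float(m.get("allee_constant", 0.0)),
            )
            for i, m in enumerate(section["members"])
        )
        inter = section["interactions"]
        interactions = InteractionMatrix(
            np.array(inter["coefficients"], dtype=float),
            symmetric_regulator=bool(inter.get("symmetric_regulator", False)),
        )
        w = window if window is not None else (72.0, 96.0)
        deaths = tuple(
            DeathModel(
                kind=str(d.get("kind", "constant")),
                constant_rate=float(d.get("constant_rate", 0.0)),
                slope=float(d.get("slope", 0.0)),
                intercept=float(d.get("intercept", 0.0)),
                window_start=w[0],
                window_end=w[1],
            )
            for d in section["deaths"]
        )
        return CommunityModel(members, interactions, deaths)
    except (ValueError, KeyError, TypeError) as err:
        errors.append(f"model: {err}")
        return None


def _build_protocol(section: Dict[str, Any], errors: List[str]):
    try:
        window = section["antibiotic_window"]
        if window is not None:
            window = (float(window[0]), float(window[1]))
        props = section["initial_proportions"]
        if props is not None:
            props = tuple(float(p) for p in props)
        return ProtocolSpec(
            cycle_hours=float(section["cycle_hours"]),
            n_cycles=int(section["n_cycles"]),
            dilution_mode=str(section["dilution_mode"]),
            dilution_factor=float(section["dilution_factor"]),
            initial_total_density=float(section["initial_total_density"]),
            initial_proportions=props,
            antibiotic_window=window,
        )
    except (ValueError, KeyError, TypeError) as err:
        errors.append(f"protocol.{_field_hint(err)}: {err}")
        return None


def _field_hint(err: Exception) -> str:
    msg = str(err)
    for name in ("initial_proportions", "initial_total_density",
                 "dilution_factor", "antibiotic_window", "cycle_hours",
                 "n_cycles", "dilution_mode"):
        if name in msg:
            return name
    return "section"


def _build_synth(section: Dict[str, Any], seed: int, errors: List[str]):
    try:
        strains = tuple(
            SynthStrain(
                name=str(s["name"]),
                growth_rate=float(s["growth_rate"]),
                smx_death_rate=float(s.get("smx_death_rate", 0.0)),
            )
            for s in section["strains"]
        )
        grid = tuple(
            np.logspace(
                np.log10(float(section["inoculum_min"])),
                np.log10(float(section["inoculum_max"])),
                int(section["inoculum_n"]),
            )
        )
        return SynthConfig(
            strains=strains,
            inoculum_densities=grid,
            smx_concentration=float(section["smx_concentration"]),
            replicates=int(section["replicates"]),
            od_noise_sigma=float(section["od_noise_sigma"]),
            sampling_interval=float(section["sampling_interval"]),
            horizon=float(section["horizon"]),
            seed=seed,
        )
    except (ValueError, KeyError, TypeError) as err:
        errors.append(f"synth: {err}")
        return None


def parse_config(path: Union[str, Path, None]) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Missing optional sections are filled with the shipped defaults (the
    study's simulation parameters).  Raises :class:`ConfigError` listing
    every validation problem at once.
    """
    if path is None:
        user: Dict[str, Any] = {sec: {} for sec in REQUIRED_SECTIONS}
    else:
        text = Path(path).read_text()
        user = yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError(["top level must be a mapping of sections"])

    errors: List[str] = []
    missing = [sec for sec in REQUIRED_SECTIONS if sec not in user]
    if missing:
        raise ConfigError(
            [f"missing required section: {sec}" for sec in missing]
        )

    resolved = _merge(default_config(), user, "config", errors)
    if errors:
        raise ConfigError(errors)

    protocol = _build_protocol(resolved["protocol"], errors)
    window = protocol.antibiotic_window if protocol is not None else None
    model = _build_model(resolved["model"], window, errors)
    seed = int(resolved["seed"])
    synth = _build_synth(resolved["synth"], seed, errors)
    try:
        solver = SolverOptions(**resolved["solver"])
    except TypeError as err:
        errors.append(f"solver: {err}")
        solver = None
    if errors:
        raise ConfigError(errors)

    return RunConfig(
        model=model,
        protocol=protocol,
        sweep=resolved["sweep"],
        synth=synth,
        solver=solver,
        output_dir=Path(resolved["output"]["directory"]),
        seed=seed,
        log_level=str(resolved["log_level"]),
        resolved=resolved,
    )


def echo_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Write the fully resolved configuration for provenance/round-trip."""
    Path(path).write_text(
        yaml.safe_dump(cfg.resolved, sort_keys=False, default_flow_style=None)
    )
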