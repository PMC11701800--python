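"""Configuration schema, unit normalization and validation.

Configs are YAML with the sections of :func:`moabsim.synthetic_data.reference_config`.
Quantities are plain numbers in SI or strings with an explicit unit suffix
("500 um", "6 mm", "5 uL/min"); everything is normalized to SI on load.
Unknown sections or keys are rejected, and all violations are reported in a
single error.
"""

from __future__ import annotations

import copy
import hashlib
import re

import yaml

from .design import PhysiologicalRanges, SimulationSetup, make_setup
from .flow import FluidProperties
from .geometry import (ChamberSpec, GridSpec, MicrostructureSpec,
                       ScaffoldArraySpec)
from .oxygen import CellLoading, OxygenParams, UnitConversion
from .synthetic_data import reference_config

__all__ = ["load_config", "save_config", "validate_config", "parse_quantity",
           "build_setup", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    pass


# multiplicative factors to SI
_UNITS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    "m3/s": 1.0, "ul/min": 1e-9 / 60.0, "uL/min": 1e-9 / 60.0,
    "ml/min": 1e-6 / 60.0, "mL/min": 1e-6 / 60.0,
    "pa": 1.0, "Pa": 1.0, "mPa": 1e-3, "mpa": 1e-3,
    "pa*s": 1.0, "Pa*s": 1.0, "Pa s": 1.0, "mPa*s": 1e-3,
    "m/s": 1.0, "um/s": 1e-6, "mm/s": 1e-3,
    "m2/s": 1.0, "mol/m3": 1.0, "mol/s": 1.0,
    "kg/m3": 1.0, "%": 1.0, "c": 1.0, "C": 1.0,
}


def parse_quantity(value):
    """Number -> itself; '5 uL/min' / '500 um' style strings -> SI float."""
    if isinstance(value, bool) or value is None:
        return value
    if isinstance(value, (int, float)):
        return value
    if isinstance(value, str):
        m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([^\s]+(?:\s*/\s*\S+)?)?\s*",
                         value)
        if not m:
            raise ConfigError(f"cannot parse quantity {value!r}")
        num = float(m.group(1))
        unit = (m.group(2) or "").replace(" ", "")
        if not unit:
            return num
        if unit not in _UNITS:
            raise ConfigError(f"unknown unit {unit!r} in {value!r}")
        return num * _UNITS[unit]
    raise ConfigError(f"cannot parse quantity {value!r}")


def _positive(x):
    return isinstance(x, (int, float)) and not isinstance(x, bool) and x > 0


def _nonneg(x):
    return isinstance(x, (int, float)) and not isinstance(x, bool) and x >= 0


def _boolean(x):
    return isinstance(x, bool)


def _count(x):
    return isinstance(x, int) and not isinstance(x, bool) and x >= 0


def _positive_or_none(x):
    return x is None or _positive(x)


def _number_list(x):
    return isinstance(x, list) and len(x) > 0 and all(_positive(v) for v in x)


def _string(x):
    return isinstance(x, str)


_SCHEMA = {
    "chamber": {"length_x": _positive, "width_y": _positive,
                "height_z": _positive, "inlet_diameter": _positive,
                "inlet_height": _positive, "half_model": _boolean},
    "microstructure": {k: _positive for k in
                       ("footprint_x", "footprint_y", "height", "pore_x",
                        "pore_y", "pore_z")} | {"beam_axial": _nonneg,
                                                "beam_lateral": _nonneg},
    "array": {"n_rows": _count, "n_cols": _count,
              "pitch_x": _positive_or_none, "lateral_offset": _nonneg},
    "grid": {"dx": _positive, "dy": _positive, "dz_fine": _positive,
             "z_fine_limit": _positive, "growth": _positive},
    "unit_cell": {"spacing": _positive, "near_surface_offset": _positive},
    "fluid": {"mu": _positive, "rho": _positive,
              "temperature": lambda x: isinstance(x, (int, float))},
    "oxygen": {"D": _positive, "C0": _positive, "Vmax": _positive,
               "Km": _positive},
    "cells": {"n_total": _count, "n_array": _count, "n_flat": _count},
    "conversion": {"percent_at_C0": _positive, "hypoxia_percent": _positive,
                   "normoxia_percent": _positive},
    "ranges": {"velocity_min": _positive, "velocity_max": _positive,
               "velocity_max_broad": _positive, "wss_min": _positive,
               "wss_max": _positive},
    "sweep": {"rates_ul_min": _number_list, "rule": _string},
    "solver": {"tol": _positive, "maxiter": _count, "picard_tol": _positive,
               "picard_maxiter": _count},
    "_seed": _count,
}


def validate_config(cfg: dict) -> dict:
    """Normalize units, fill defaults, reject unknown keys.

    Returns a complete SI config; raises ConfigError listing every
    violation at once.
    """
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    errors = []
    out = copy.deepcopy(reference_config())
    for section, content in cfg.items():
        if section == "_seed":
            if not _count(content):
                errors.append("_seed must be a non-negative integer")
            else:
                out["_seed"] = content
            continue
        if section not in _SCHEMA:
            errors.append(f"unknown section [{section}]")
            continue
        if not isinstance(content, dict):
            errors.append(f"[{section}] must be a mapping")
            continue
        for key, raw in content.items():
            if key not in _SCHEMA[section]:
                errors.append(f"unknown key {section}.{key}")
                continue
            try:
                if section == "sweep" and key == "rates_ul_min":
                    # numbers are uL/min; strings with units are converted
                    val = [parse_quantity(v) / (1e-9 / 60.0)
                           if isinstance(v, str) else v
                           for v in raw] if isinstance(raw, list) else raw
                elif _SCHEMA[section][key] is _string or \
                        isinstance(raw, (bool, type(None))):
                    val = raw
                else:
                    val = parse_quantity(raw)
            except ConfigError as e:
                errors.append(f"{section}.{key}: {e}")
                continue
            if not _SCHEMA[section][key](val):
                errors.append(f"{section}.{key}: invalid value {raw!r}")
                continue
            out[section][key] = val
    cells = out["cells"]
    if cells["n_array"] + cells["n_flat"] != cells["n_total"]:
        errors.append("cells: n_array + n_flat must equal n_total")
    if errors:
        raise ConfigError("invalid configuration:\n  - "
                          + "\n  - ".join(errors))
    return out


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def save_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_setup(cfg: dict) -> SimulationSetup:
    """Turn a validated config into a sweep-ready SimulationSetup."""
    cfg = validate_config(cfg)
    ms = MicrostructureSpec(**cfg["microstructure"])
    chamber = ChamberSpec(**cfg["chamber"])
    array = ScaffoldArraySpec(microstructure=ms, **cfg["array"])
    gridspec = GridSpec(**cfg["grid"])
    ox = OxygenParams(**cfg["oxygen"])
    conv = UnitConversion(C0=ox.C0, **cfg["conversion"])
    return make_setup(
        chamber=chamber, array=array, gridspec=gridspec,
        fluid=FluidProperties(**cfg["fluid"]),
        oxygen=ox,
        loading=CellLoading(**cfg["cells"]),
        conversion=conv,
        ranges=PhysiologicalRanges(**cfg["ranges"]),
        cell_spacing=cfg["unit_cell"]["spacing"],
        near_surface_offset=cfg["unit_cell"]["near_surface_offset"],
        solver=cfg["solver"],
    )


def sweep_rates_si(cfg: dict) -> list[float]:
    return [r * 1e-9 / 60.0 for r in cfg["sweep"]["rates_ul_min"]]
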