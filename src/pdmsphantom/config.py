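"""Run configuration: a single YAML file with sectioned defaults.

Sections: ``instrument`` (emulator settings), ``calibration``
(concentration-to-optics model), ``recipes`` (grid or explicit pairs),
``inversion`` (fixed g and input uncertainties), ``fitting``, ``tissue``.
Any subset may be given; missing keys take the defaults below, and
``dump_defaults()`` prints the fully resolved default file.
"""

from __future__ import annotations

import copy
from dataclasses import fields
from pathlib import Path

import numpy as np
import yaml

from .phantom_model import CalibrationConfig, SpectralGrid
from .synthetic_data import DEFAULT_CBP_LEVELS, DEFAULT_TDP_LEVELS, InstrumentConfig

__all__ = ["DEFAULTS", "load_config", "dump_defaults", "build_instrument", "build_calibration"]

DEFAULTS: dict = {
    "instrument": {
        "grid_min_nm": 500.0,
        "grid_max_nm": 850.0,
        "grid_step_nm": 5.0,
        "resolution_fwhm_nm": 8.5,
        "n_repeats": 5,
        "noise_floor": 0.01,
        "edge_noise_factor": 3.0,
        "edge_width_nm": 50.0,
        "rho_std": 0.99,
        "seed": 20211118,
    },
    "calibration": {f.name: f.default for f in fields(CalibrationConfig)},
    "recipes": {
        "tdp_levels": list(DEFAULT_TDP_LEVELS),
        "cbp_levels": list(DEFAULT_CBP_LEVELS),
        "pairs": None,
        "include_ps_set": False,
        "thickness_cm": 0.25,
    },
    "inversion": {
        "g": 0.5,
        "u_thickness_cm": 0.005,
        "u_rho": 0.005,
        "u_n": 0.005,
        "budget": True,
    },
    "fitting": {"weighted": True},
    "tissue": {"table": None, "scale_a": 10.0, "scale_b": 0.5},
}


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config file, merged over the defaults."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_defaults() -> str:
    """The fully resolved default configuration as YAML text."""
    return yaml.safe_dump(DEFAULTS, sort_keys=False)


def build_instrument(cfg: dict) -> InstrumentConfig:
    ins = cfg["instrument"]
    grid = SpectralGrid(
        np.arange(ins["grid_min_nm"], ins["grid_max_nm"] + 1e-9, ins["grid_step_nm"])
    )
    return InstrumentConfig(
        grid=grid,
        resolution_fwhm_nm=ins["resolution_fwhm_nm"],
        n_repeats=int(ins["n_repeats"]),
        noise_floor=ins["noise_floor"],
        edge_noise_factor=ins["edge_noise_factor"],
        edge_width_nm=ins["edge_width_nm"],
        rho_std=ins["rho_std"],
        seed=int(ins["seed"]),
    )


def build_calibration(cfg: dict) -> CalibrationConfig:
    return CalibrationConfig(**cfg["calibration"])
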