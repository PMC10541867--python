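"""Flat key/value (YAML) configuration files and run-summary output.

A config file is a flat mapping whose keys mirror the simulation
configuration; every key is optional (defaults are the SOIREE-style
ensemble baseline) and unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .ecosystem import BioParams
from .engine import SimulationConfig, Trajectory
from .geometry import ForcingLaws, PatchShape
from .moments import SurroundingState, TracerMoments

__all__ = ["config_from_mapping", "load_config", "run_summary", "write_run_summary"]

_DEFAULTS: dict[str, Any] = {
    # geometry
    "W0_km": 5.0,
    "L0_km": 5.0,
    "gamma0": 0.12,
    "kappa0": 0.1,
    "strain_exponent": -2.0 / 3.0,
    "kappa_exponent": 1.0,
    # biology
    "nu": 1.05,
    "k": 2.0,
    "m": 0.05,
    "alpha": 0.0,
    "mortality_form": "linear",
    "m_quad": 0.0,
    "fe_to_c": 1e-5,
    # tracers (umol m^-3, iron currency for biomass)
    "patch_resource": 1.0,
    "surrounding_resource": 0.1,
    "patch_biomass": 0.0249,
    "surrounding_biomass": 0.0249,
    "var_r0": 0.0,
    "var_b0": 0.0,
    "cov_rb0": 0.0,
    # integration
    "tau": 30.0,
    "dt": 0.01,
    "thickness": 10.0,
    "mode": "heterogeneous",
}


def config_from_mapping(values: Mapping[str, Any] | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from flat key/value overrides."""
    values = dict(values or {})
    unknown = sorted(set(values) - set(_DEFAULTS))
    if unknown:
        raise KeyError(f"unknown config keys: {', '.join(unknown)}")
    cfg = {**_DEFAULTS, **values}

    shape0 = PatchShape(float(cfg["W0_km"]), float(cfg["L0_km"]))
    forcing = ForcingLaws(
        gamma0=float(cfg["gamma0"]),
        kappa0=float(cfg["kappa0"]),
        S0=shape0.S,
        strain_exponent=float(cfg["strain_exponent"]),
        kappa_exponent=float(cfg["kappa_exponent"]),
    )
    bio = BioParams(
        nu=float(cfg["nu"]),
        k=float(cfg["k"]),
        m=float(cfg["m"]),
        alpha=float(cfg["alpha"]),
        mortality_form=cfg["mortality_form"],
        m_quad=float(cfg["m_quad"]),
        fe_to_c=float(cfg["fe_to_c"]),
    )
    surrounding = SurroundingState(
        mean_r=float(cfg["surrounding_resource"]), mean_b=float(cfg["surrounding_biomass"])
    )
    initial = TracerMoments(
        mean_r=float(cfg["patch_resource"]),
        mean_b=float(cfg["patch_biomass"]),
        var_r=float(cfg["var_r0"]),
        var_b=float(cfg["var_b0"]),
        cov_rb=float(cfg["cov_rb0"]),
    )
    return SimulationConfig(
        shape0=shape0,
        forcing=forcing,
        bio=bio,
        surrounding=surrounding,
        initial_moments=initial,
        tau=float(cfg["tau"]),
        dt=float(cfg["dt"]),
        thickness=float(cfg["thickness"]),
        mode=cfg["mode"],
    )


def load_config(path: str | Path) -> SimulationConfig:
    """Read a flat YAML config file; unknown keys raise ``KeyError``."""
    with open(path) as fh:
        values = yaml.safe_load(fh) or {}
    if not isinstance(values, Mapping):
        raise ValueError(f"config file {path} must contain a flat key/value mapping")
    return config_from_mapping(values)


def run_summary(traj: Trajectory) -> dict[str, Any]:
    """JSON-serialisable summary: parameters, bloom peak, LBA, dilution."""
    from .metrics import dilution_factor, lagrangian_biomass_anomaly

    cfg = traj.config
    summary: dict[str, Any] = {
        "peak_day": float(traj.time[int(np.argmax(traj.mean_b))]),
        "peak_mean_b": float(traj.mean_b.max()),
        "n_psd_clamps": traj.n_psd_clamps,
    }
    if cfg is not None:
        summary["peak_ratio"] = summary["peak_mean_b"] / cfg.surrounding.mean_b
        summary["LBA_MgC"] = lagrangian_biomass_anomaly(traj, cfg.surrounding.mean_b, cfg.conversion)
        summary["dilution_factor"] = dilution_factor(traj)
        summary["parameters"] = {
            "shape0": asdict(cfg.shape0),
            "forcing": asdict(cfg.forcing),
            "bio": asdict(cfg.bio),
            "surrounding": asdict(cfg.surrounding),
            "initial_moments": asdict(cfg.initial_moments),
            "tau": cfg.tau,
            "dt": cfg.dt,
            "thickness": cfg.thickness,
            "mode": cfg.mode,
        }
    return summary


def write_run_summary(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(run_summary(traj), fh, indent=2)
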