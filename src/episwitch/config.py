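"""Configuration loading, validation, seeding and run manifests.

Runs are configured by a YAML/JSON file with a flat ``theta:`` block (or a
``ranges:`` block for ensemble sampling) and a ``constants:`` block; unknown
keys anywhere are an error, which guards against silently mistyped parameter
names.  Every command writes a ``manifest.json`` next to its outputs with
the config hash, package version, resolved defaults and the seed, so any
artifact can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import THETA_KEYS, ModelParams
from .reference import DEFAULT_CONSTANTS, DEFAULT_PRIOR_RANGES

__all__ = ["RunConfig", "load_config", "dump_config", "write_manifest"]

_CONSTANT_KEYS = ("rho", "C1", "C2", "C4", "Lambda_A", "Lambda_I",
                  "rho_A", "rho_I", "Omega_T", "Omega_S")
_TOP_KEYS = {"constants", "theta", "ranges", "seed", "x_thr", "grid",
             "ssa", "basins", "therapy", "ensemble"}
_GRID_KEYS = {"n_points", "x_min"}
_SSA_KEYS = {"t_max", "burn_in", "record_stride", "omega_t", "omega_s"}
_BASIN_KEYS = {"eps", "n_samples", "t_max"}
_THERAPY_KEYS = {"protocols", "nu_grid"}
_ENSEMBLE_KEYS = {"n_accepted", "n_grid", "omega_t"}


@dataclass
class RunConfig:
    """Validated run configuration with every default made explicit."""

    constants: dict
    theta: dict | None = None
    ranges: dict | None = None
    seed: int = 0
    x_thr: float | None = None
    grid: dict = field(default_factory=lambda: {"n_points": 400, "x_min": 1e-3})
    ssa: dict = field(default_factory=lambda: {"t_max": 1000.0, "burn_in": 100.0,
                                               "record_stride": 0.1,
                                               "omega_t": None, "omega_s": None})
    basins: dict = field(default_factory=lambda: {"eps": 0.1, "n_samples": 1000,
                                                  "t_max": 200.0})
    therapy: dict = field(default_factory=lambda: {"protocols": ["K6", "K12", "K6-K12"],
                                                   "nu_grid": None})
    ensemble: dict = field(default_factory=lambda: {"n_accepted": 500, "n_grid": 200,
                                                    "omega_t": None})

    def model_params(self) -> ModelParams:
        if self.theta is None:
            raise ValueError("config has no theta block (only ranges)")
        return ModelParams(theta=self.theta, **self.constants)

    def to_dict(self) -> dict:
        return {
            "constants": dict(self.constants), "theta": self.theta,
            "ranges": self.ranges, "seed": self.seed, "x_thr": self.x_thr,
            "grid": dict(self.grid), "ssa": dict(self.ssa),
            "basins": dict(self.basins), "therapy": dict(self.therapy),
            "ensemble": dict(self.ensemble),
        }


def _check_keys(block: dict, allowed, where: str):
    unknown = set(block) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _validated(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    constants = {**DEFAULT_CONSTANTS, **(raw.get("constants") or {})}
    _check_keys(constants, _CONSTANT_KEYS, "constants")
    if constants["Omega_S"] / constants["Omega_T"] >= 1:
        raise ValueError("constants: eps2 = Omega_S/Omega_T must be < 1")

    theta = raw.get("theta")
    if theta is not None:
        missing = set(THETA_KEYS) - set(theta)
        if missing:
            raise ValueError(f"theta block missing component(s): {sorted(missing)}")
        _check_keys(theta, THETA_KEYS, "theta")
        theta = {k: float(theta[k]) for k in THETA_KEYS}

    ranges = raw.get("ranges")
    if ranges is not None:
        _check_keys(ranges, THETA_KEYS, "ranges")
        missing = set(THETA_KEYS) - set(ranges)
        if missing:
            raise ValueError(f"ranges block missing component(s): {sorted(missing)}")
        ranges = {k: tuple(map(float, ranges[k])) for k in THETA_KEYS}

    cfg = RunConfig(constants=constants, theta=theta, ranges=ranges,
                    seed=int(raw.get("seed", 0)),
                    x_thr=raw.get("x_thr"))
    for name, allowed in (("grid", _GRID_KEYS), ("ssa", _SSA_KEYS),
                          ("basins", _BASIN_KEYS), ("therapy", _THERAPY_KEYS),
                          ("ensemble", _ENSEMBLE_KEYS)):
        block = raw.get(name) or {}
        _check_keys(block, allowed, name)
        getattr(cfg, name).update(block)
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file; defaults are filled in and
    visible in the returned object (and recorded by the run manifest)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return _validated(raw)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def write_manifest(cfg: RunConfig, out_dir, command: str, extra: dict | None = None):
    """Write manifest.json (config hash, version, seed) next to the outputs."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    manifest = {
        "command": command,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "version": __version__,
        "seed": cfg.seed,
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
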