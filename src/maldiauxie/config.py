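"""Run configuration: YAML blocks for the model, scans, simulation,
noise and phenotyping, merged over package defaults, plus the provenance
manifest written next to every pipeline output."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import scipy
import yaml

from .genotypes import GenotypeFactors
from .phenotyping import DetectionConfig, SmootherConfig
from .regulon import RegulonParams
from .simulate import CultureConfig, NoiseModel, SugarSpec

__all__ = ["default_config", "load_config", "build_objects", "write_manifest"]


def default_config() -> dict[str, Any]:
    """The complete default configuration as a plain dictionary."""
    params = RegulonParams()
    rmin = (params.b_T + params.u_T_max) / params.d_T
    return {
        "model": {
            "params": {k: v for k, v in asdict(params).items()},
            "genotypes": asdict(GenotypeFactors()),
        },
        "scan": {
            "K_T_axis": {"start": 1.1, "stop": 5.0, "num": 120},
            "ratio_axis": {"start": 1.05 * rmin, "stop": 10.0 * rmin, "num": 120, "log": True},
            "n_values": [2, 3, 4],
        },
        "hysteresis": {"ratio": 3.3, "K_T_axis": {"start": 1.1, "stop": 4.5, "num": 60}},
        "simulation": {
            "culture": {
                "sugar1": asdict(SugarSpec("galactose", 0.5, 0.25)),
                "sugar2": asdict(SugarSpec("palatinose", 0.5, 0.12)),
                "B0": 0.02,
                "mode": "sequential",
                "lag_h": 3.0,
                "initial_lag_h": 2.0,
                "duration_h": 48.0,
                "reporter": False,
            },
            "design": {
                "conc1": [0.2, 0.4, 0.6, 0.8],
                "conc2": [0.5],
                "replicates": 3,
                "blanks": 2,
            },
        },
        "noise": asdict(NoiseModel()),
        "phenotyping": {
            "smoother": asdict(SmootherConfig()),
            "detection": asdict(DetectionConfig()),
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Defaults merged under the user's YAML (user values win)."""
    cfg = default_config()
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        with open(p) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def _axis(spec: dict) -> np.ndarray:
    if spec.get("log"):
        return np.geomspace(spec["start"], spec["stop"], int(spec["num"]))
    return np.linspace(spec["start"], spec["stop"], int(spec["num"]))


def build_objects(cfg: dict[str, Any]) -> dict[str, Any]:
    """Materialise the dataclasses and axes a pipeline run needs."""
    params = RegulonParams(**cfg["model"]["params"])
    sim = cfg["simulation"]["culture"]
    culture = CultureConfig(
        sugar1=SugarSpec(**sim["sugar1"]),
        sugar2=SugarSpec(**sim["sugar2"]),
        B0=sim["B0"],
        mode=sim["mode"],
        lag_h=sim["lag_h"],
        initial_lag_h=sim["initial_lag_h"],
        duration_h=sim["duration_h"],
        reporter=sim["reporter"],
        regulon_params=params if sim["mode"] == "regulon" else None,
    )
    return {
        "params": params,
        "factors": GenotypeFactors(**cfg["model"]["genotypes"]),
        "K_T_axis": _axis(cfg["scan"]["K_T_axis"]),
        "ratio_axis": _axis(cfg["scan"]["ratio_axis"]),
        "n_values": list(cfg["scan"]["n_values"]),
        "hysteresis_ratio": float(cfg["hysteresis"]["ratio"]),
        "hysteresis_axis": _axis(cfg["hysteresis"]["K_T_axis"]),
        "culture": culture,
        "design": cfg["simulation"]["design"],
        "noise": NoiseModel(**cfg["noise"]),
        "smoother": SmootherConfig(**cfg["phenotyping"]["smoother"]),
        "detection": DetectionConfig(**cfg["phenotyping"]["detection"]),
    }


def write_manifest(out_dir: str | Path, cfg: dict, seed: int | None, stages: list[str]) -> Path:
    """Record inputs, seed, versions and thresholds next to the outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "maldiauxie",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": cfg,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
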