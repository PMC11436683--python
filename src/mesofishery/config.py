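"""YAML configuration, seed management and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .design import DEFAULT_BOUNDS, UncertaintySpace, build_space
from .params import BioEconParams, GovParams, SimConfig

__all__ = ["default_config", "load_config", "parse_config",
           "stage_seed", "write_manifest"]

#: stage names with a reserved, deterministically derived sub-seed
STAGES = ("sampling", "trees", "analysis")


def default_config() -> dict[str, Any]:
    """Full configuration with baseline parameters and sampling bounds."""
    return {
        "bio": asdict(BioEconParams()),
        "gov": asdict(GovParams()),
        "sim": asdict(SimConfig()),
        "bounds": {k: [lo, up] for k, (lo, up, _) in DEFAULT_BOUNDS.items()},
        "ensemble": {"n": 20_000, "seed": 1, "worst_case_quantile": 0.1},
        # structural toggles recorded for every run (see docs/methods.md)
        "toggles": {
            "demand_compounding": "X**t",
            "quota_units": "Q0 * multipliers * M_t (tonnes)",
            "effort_units": "dE = alpha * profit / cost_per_day",
            "concern_proxy": "yearly injection M_t*mu vs year-5 baseline",
            "subset_rule": "range-midpoint quadrants (FL 1.5, E_effect 0.5)",
        },
    }


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config, filling unspecified sections with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section not in cfg:
            raise KeyError(f"unknown config section {section!r}")
        if isinstance(cfg[section], dict) and isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def parse_config(cfg: dict[str, Any]) -> tuple[BioEconParams, GovParams,
                                               SimConfig, UncertaintySpace]:
    """Materialise dataclasses and the sampling space from a config dict."""
    bio = BioEconParams(**cfg["bio"])
    gov = GovParams(**cfg["gov"])
    sim = SimConfig(**cfg["sim"])
    space = build_space({k: tuple(v) for k, v in cfg["bounds"].items()})
    return bio, gov, sim, space


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31 from one global seed."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; expected one of {STAGES}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % 2**31)


def write_manifest(path: str | Path, cfg: dict[str, Any], seed: int,
                   n_samples: int, outputs: list[str],
                   extra: Optional[dict[str, Any]] = None) -> dict[str, Any]:
    """JSON manifest tying outputs to the config, seed and package version."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGES},
        "n_samples": n_samples,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": cfg,
        "outputs": outputs,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
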