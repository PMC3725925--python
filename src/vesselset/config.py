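"""Run configuration: defaults, YAML config files, CLI overrides.

Precedence (lowest to highest): built-in defaults, config file, explicit
command-line flags.  The fully resolved configuration is logged and written
to each run's manifest so a run can be reproduced bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .energy import DEFAULT_BETA, ModelParams
from .evolution import InitSpec, StopSpec
from .weights import NeighborhoodSpec

DEFAULTS: dict[str, Any] = {
    "alpha": 1.0,
    "beta": DEFAULT_BETA,
    "dt": 0.1,
    "epsilon": 1.0,
    "sigma_g_sq": 10.0,
    "radius": 1,
    "include_center": True,
    "max_iterations": 500,
    "tolerance": 1e-4,
    "init": "circle",
    "channel": "green",
    "vessel_class": "darker",
    "normalize": False,
    "fov_estimate": False,
    "seed": 0,
}


def load_config_file(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def resolve(
    file_cfg: dict[str, Any] | None = None,
    overrides: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Merge defaults, config-file values and CLI overrides (None skipped)."""
    cfg = dict(DEFAULTS)
    cfg.update(file_cfg or {})
    cfg.update({k: v for k, v in (overrides or {}).items() if v is not None})
    return cfg


def model_params(cfg: dict[str, Any]) -> ModelParams:
    """Build ModelParams from a resolved config.

    With ``normalize`` set, intensities live on [0, 1] and β is rescaled by
    1/255² so the functional's minimiser is unchanged.
    """
    beta = cfg["beta"] / 255.0**2 if cfg["normalize"] else cfg["beta"]
    return ModelParams(
        mu=None,
        alpha=cfg["alpha"],
        beta=beta,
        dt=cfg["dt"],
        epsilon=cfg["epsilon"],
        spec=NeighborhoodSpec(
            radius=cfg["radius"],
            sigma_g_sq=cfg["sigma_g_sq"],
            include_center=cfg["include_center"],
        ),
    )


def init_spec(cfg: dict[str, Any]) -> InitSpec:
    return InitSpec(method=cfg["init"])


def stop_spec(cfg: dict[str, Any]) -> StopSpec:
    return StopSpec(max_iterations=cfg["max_iterations"], tolerance=cfg["tolerance"])
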