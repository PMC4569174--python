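"""YAML run configuration.

Layout::

    epoch: 2004-01-01          # optional; enables ISO dates in input tables
    simulate: { ... SimConfig field overrides ... }
    ranks: { k: 100.0, start_rating: 1000.0 }
    correlate: { n_perm: 1000 }
    lrs: { cap_days: 1461, survival_days: 365, stability: false }
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Any, Optional

import yaml

from .synthetic_data import SimConfig

__all__ = ["load_config", "resolve_sim_config", "resolved_config_yaml"]

_DEFAULTS: dict[str, dict[str, Any]] = {
    "ranks": {"k": 100.0, "start_rating": 1000.0},
    "correlate": {"n_perm": 1000},
    "lrs": {"cap_days": 1461, "survival_days": 365, "stability": False},
}


def load_config(path: Optional[str]) -> dict:
    """Read the YAML config (or start empty) and fill stage defaults."""
    cfg: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
    for stage, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        merged.update(cfg.get(stage) or {})
        cfg[stage] = merged
    cfg.setdefault("simulate", {})
    return cfg


def resolve_sim_config(cfg: dict, seed: Optional[int] = None) -> SimConfig:
    overrides = dict(cfg.get("simulate") or {})
    if seed is not None:
        overrides["seed"] = seed
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    for key, value in overrides.items():
        if isinstance(value, list):
            overrides[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
    return SimConfig(**overrides)


def parse_epoch(cfg: dict) -> Optional[_dt.date]:
    epoch = cfg.get("epoch")
    if epoch is None:
        return None
    if isinstance(epoch, _dt.date):
        return epoch
    return _dt.date.fromisoformat(str(epoch))


def resolved_config_yaml(cfg: dict, sim: SimConfig) -> str:
    out = {k: v for k, v in cfg.items() if k != "simulate"}
    out["simulate"] = dataclasses.asdict(sim)
    return yaml.safe_dump(out, sort_keys=True)
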