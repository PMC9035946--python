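"""Global simulation configuration.

All tunable parameters ship in a versioned YAML file
(``immunotox/params/default_params.yaml``); :func:`default_config` loads it
once and :func:`load_config` merges user overrides on top.  The engine only
reads parameters through :class:`SimConfig`, so extending the model (new
secretion entries, different lattice, other chemicals) is a config change,
not a code change.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .shape_space import AffinityParams

__all__ = ["SimConfig", "default_config", "load_config", "deep_merge"]


def deep_merge(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class SimConfig:
    """Typed view over the merged parameter dictionary."""

    raw: dict[str, Any]

    # --- derived, set in __post_init__ ---
    affinity: AffinityParams = field(init=False)
    steps_per_day: int = field(init=False)

    def __post_init__(self) -> None:
        ss = self.raw["shape_space"]
        self.affinity = AffinityParams(
            l=ss["l"], d_min=ss["d_min"], alpha=ss["alpha"], p_max=ss["p_max"]
        )
        dt = self.raw["time"]["dt_hours"]
        if 24 % dt != 0:
            raise ValueError(f"dt_hours must divide 24, got {dt}")
        self.steps_per_day = 24 // dt

    # convenience accessors -------------------------------------------------
    @property
    def l(self) -> int:
        return self.affinity.l

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.raw.get(key, default)

    def day_to_step(self, day: float) -> int:
        return int(round(day * self.steps_per_day))

    def with_overrides(self, override: dict) -> "SimConfig":
        return SimConfig(deep_merge(self.raw, override))


def _load_packaged_defaults() -> dict:
    ref = resources.files("immunotox").joinpath("params/default_params.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_DEFAULTS: dict | None = None


def default_config() -> SimConfig:
    """The shipped default configuration (fresh object each call)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _load_packaged_defaults()
    return SimConfig(copy.deepcopy(_DEFAULTS))


def load_config(path: str | Path | None = None) -> SimConfig:
    """Defaults merged with the YAML overrides at ``path`` (if given)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return cfg.with_overrides(override)
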