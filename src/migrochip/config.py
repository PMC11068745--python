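"""YAML configuration loading for the CLI.

A simulation config file is a flat mapping with a mandatory ``seed``
key; sections ``simulation``, ``render``, ``channel``, ``pillar``,
``cell3d`` and ``tsdr`` feed the corresponding dataclasses, with
unknown keys rejected so typos fail loudly.
"""
from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .geometry import ChannelGeometry, PillarGeometry
from .synthetic_data import RenderConfig, SimulationConfig, SyntheticCell3D

__all__ = ["load_config", "build_section"]

_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "render": RenderConfig,
    "channel": ChannelGeometry,
    "pillar": PillarGeometry,
    "cell3d": SyntheticCell3D,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ValueError(f"config {path} must define a 'seed' key")
    return cfg


def build_section(cfg: dict, section: str, **overrides):
    """Instantiate the dataclass behind ``section`` from a config dict.

    The top-level ``seed`` is injected into sections that accept one.
    List-valued fields that dataclasses expect as tuples are coerced.
    """
    cls = _SECTION_TYPES[section]
    raw = dict(cfg.get(section) or {})
    raw.update(overrides)
    names = {f.name for f in fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    if "seed" in names and "seed" not in raw:
        raw["seed"] = cfg["seed"]
    for key, val in raw.items():
        if isinstance(val, list):
            raw[key] = tuple(val)
    return cls(**raw)
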