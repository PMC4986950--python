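"""Sub-model coefficient configuration.

All tunable coefficients of the simulator live in a YAML file shipped with
the package (``data/submodels.yaml``). A user file with the same block
structure can override any subset of blocks; unknown blocks are rejected so
typos surface early.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

logger = logging.getLogger("forestflame")

_REQUIRED_BLOCKS = (
    "n_sides",
    "default_traits",
    "time_to_ignition",
    "flame_duration",
    "leaf_flame_length",
    "flame_angle",
    "plume",
    "flame_merge",
    "wind_profile",
    "surface_fire",
    "engine",
)


@dataclass(frozen=True)
class ModelConfig:
    """Validated coefficient set; access blocks via ``cfg['block']``."""

    raw: Mapping[str, Any]

    def __getitem__(self, block: str) -> Mapping[str, Any]:
        try:
            return self.raw[block]
        except KeyError as exc:
            raise KeyError(f"unknown sub-model block {block!r}") from exc


def _defaults() -> dict:
    text = (
        importlib.resources.files("forestflame") / "data" / "submodels.yaml"
    ).read_text()
    return yaml.safe_load(text)


def load_config(path: str | None = None) -> ModelConfig:
    """Load the default coefficients, optionally overlaying a user YAML.

    The overlay is block-deep: a user block replaces keys within the default
    block rather than the whole block.
    """
    merged = _defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(merged)
        if unknown:
            raise ValueError(f"unknown config block(s): {sorted(unknown)}")
        for block, values in user.items():
            if isinstance(values, Mapping):
                merged[block] = {**merged[block], **values}
            else:
                merged[block] = values
    missing = [b for b in _REQUIRED_BLOCKS if b not in merged]
    if missing:
        raise ValueError(f"config missing required block(s): {missing}")
    return ModelConfig(raw=merged)
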