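"""YAML configuration: one nested file mapping onto the module configs.

Sections ``preprocess``, ``generator``, ``discriminator`` and ``training``
each accept the fields of the corresponding dataclass; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .discriminator import DiscConfig
from .generator import GenConfig
from .preprocess import PreprocConfig
from .training import TrainConfig

__all__ = ["load_config", "Configs"]

_SECTIONS = {
    "preprocess": PreprocConfig,
    "generator": GenConfig,
    "discriminator": DiscConfig,
    "training": TrainConfig,
}

_TUPLE_FIELDS = {"clahe_tile_grid", "dilation_rates", "plain_blocks"}


class Configs(dict):
    """Dict of section name -> config dataclass instance."""

    @property
    def preprocess(self) -> PreprocConfig:
        return self["preprocess"]

    @property
    def generator(self) -> GenConfig:
        return self["generator"]

    @property
    def discriminator(self) -> DiscConfig:
        return self["discriminator"]

    @property
    def training(self) -> TrainConfig:
        return self["training"]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Configs:
    """Build all configs from a YAML file plus flat ``section.key`` overrides."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        section, _, name = key.partition(".")
        if not name:
            raise KeyError(f"override {key!r} must be 'section.key'")
        raw.setdefault(section, {})[name] = value

    out = Configs()
    for section, cls in _SECTIONS.items():
        kwargs = dict(raw.get(section) or {})
        valid = {f.name for f in fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise KeyError(f"unknown keys in [{section}]: {sorted(unknown)}")
        for k in list(kwargs):
            if k in _TUPLE_FIELDS and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        out[section] = cls(**kwargs).validate()
    extra = set(raw) - set(_SECTIONS)
    if extra:
        raise KeyError(f"unknown config sections: {sorted(extra)}")
    return out
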