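"""Hierarchical run configuration: YAML sections mapped onto config dataclasses.

A run config file has sections named after the pipeline stages
(``preprocess``, ``augment``, ``model``, ``train``, ``postprocess``,
``synth``) plus optional top-level ``seed``. Unknown sections or keys are
rejected by name rather than ignored, so typos fail loudly; CLI flags
override file values; the effective configuration is dumped next to the run
artifacts.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Any, Type, TypeVar

import yaml

from .augment import AugmentConfig
from .nn.models import BaselineConfig, ModelConfig
from .postprocess import MergeConfig
from .preprocess import PreprocessConfig
from .synth import SynthConfig
from .train import TrainConfig

T = TypeVar("T")

SECTIONS: dict[str, type] = {
    "preprocess": PreprocessConfig,
    "augment": AugmentConfig,
    "model": ModelConfig,
    "baseline": BaselineConfig,
    "train": TrainConfig,
    "postprocess": MergeConfig,
    "synth": SynthConfig,
}


class ConfigError(ValueError):
    pass


def dataclass_from_dict(cls: Type[T], d: dict[str, Any], section: str = "") -> T:
    """Build a config dataclass, rejecting unknown keys by name."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section or cls.__name__!r}; "
            f"valid keys: {sorted(names)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path: str | os.PathLike | None,
                overrides: dict[str, dict[str, Any]] | None = None
                ) -> dict[str, Any]:
    """Load a YAML run config; returns {section: dataclass, 'seed': int}."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(os.fspath(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(SECTIONS) - {"seed", "output_dir"}
    if unknown:
        raise ConfigError(f"unknown config section(s) {sorted(unknown)}; "
                          f"valid sections: {sorted(SECTIONS) + ['seed', 'output_dir']}")
    merged: dict[str, dict[str, Any]] = {
        k: dict(raw.get(k, {})) for k in SECTIONS}
    for sec, kv in (overrides or {}).items():
        merged.setdefault(sec, {}).update(
            {k: v for k, v in kv.items() if v is not None})
    out: dict[str, Any] = {sec: dataclass_from_dict(cls, merged.get(sec, {}), sec)
                           for sec, cls in SECTIONS.items()}
    # the train config embeds the augment section
    out["train"] = dataclasses.replace(out["train"], augment=out["augment"])
    out["seed"] = int(raw.get("seed", 0))
    out["output_dir"] = raw.get("output_dir")
    return out


def dump_effective(cfg: dict[str, Any], path: str | os.PathLike) -> None:
    """Write the effective (defaults + overrides) configuration as YAML."""
    doc: dict[str, Any] = {}
    for sec, val in cfg.items():
        if dataclasses.is_dataclass(val):
            doc[sec] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in dataclasses.asdict(val).items()}
        elif val is not None:
            doc[sec] = val
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
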