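"""Structured run configuration (YAML) shared by the CLI subcommands.

Unknown keys are rejected rather than ignored, so typos in a config file
fail loudly; every run logs its fully-resolved configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .features import WindowSpec
from .preprocess import FilterSettings
from .synth import GestureProtocol
from .training import TrainConfig

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Nested settings for every pipeline stage."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    protocol: GestureProtocol = field(default_factory=GestureProtocol)
    filters: FilterSettings = field(default_factory=FilterSettings)
    windows: WindowSpec = field(default_factory=WindowSpec)
    train: TrainConfig = field(default_factory=TrainConfig)

    def resolved(self) -> dict:
        out = {"schema_version": self.schema_version, "seed": self.seed}
        for name in ("protocol", "filters", "windows", "train"):
            section = getattr(self, name)
            out[name] = {
                f.name: _plain(getattr(section, f.name))
                for f in dataclasses.fields(section)
            }
        return out

    def log_resolved(self) -> None:
        log.info("resolved config: %s", self.resolved())


def _plain(v):
    try:
        import numpy as np

        if isinstance(v, np.ndarray):
            return v.tolist()
    except ImportError:  # pragma: no cover
        pass
    return v


_SECTIONS = {
    "protocol": GestureProtocol,
    "filters": FilterSettings,
    "windows": WindowSpec,
    "train": TrainConfig,
}


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown sections or keys raise with their names."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    known = set(_SECTIONS) | {"schema_version", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: schema version {version}, expected {SCHEMA_VERSION}")
    kwargs = {"schema_version": version, "seed": int(raw.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"{path}: section {name!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ValueError(f"{path}: unknown keys {sorted(bad)} in section {name!r}")
        kwargs[name] = cls(**section)
    cfg = RunConfig(**kwargs)
    if "seed" in raw:
        cfg.protocol.seed = cfg.seed
        cfg.train.seed = cfg.seed
    return cfg
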