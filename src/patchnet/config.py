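"""YAML run configuration: validation, defaults, resolved-config echoing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .mc import MoveSchedule
from .model import ModelParams
from .phase import ClassifyThresholds

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTION_TYPES = {
    "model": ModelParams,
    "schedule": MoveSchedule,
    "thresholds": ClassifyThresholds,
}

_RUN_KEYS = {"n_sweeps": 500_000, "record_every": 2_500}
_SWEEP_KEYS = {"axis1": None, "axis2": None, "values1": None, "values2": None,
               "replicates": 3}
_SYNTH_KEYS = {"preset": "short-like", "n_rings": 3, "n_particles": None,
               "defect_rates": [0.0, 0.0], "n_components": 3, "field_nm": 750.0,
               "lattice_nm": 16.0, "pixels": 256, "height_nm": 2.0,
               "noise_sd": 0.1, "line_offset_sd": 0.2}
_IMAGE_KEYS = {"pixel_nm": None, "lattice_nm": 16.0, "flatten_order": 0,
               "threshold_nm": None, "cutoff_nm": None}
_TOP_KEYS = {"model", "schedule", "thresholds", "run", "sweep", "synth",
             "image", "seed", "outdir", "log_level"}


def _build_section(name: str, data: dict) -> Any:
    cls = _SECTION_TYPES[name]
    allowed = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    if name == "synth" and isinstance(data.get("defect_rates"), list):
        data = {**data, "defect_rates": tuple(data["defect_rates"])}
    return cls(**data)


def _merge_plain(name: str, defaults: dict, data: dict) -> dict:
    unknown = set(data) - set(defaults)
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    return {**defaults, **data}


@dataclass
class RunConfig:
    """Validated configuration for every pipeline stage."""

    model: ModelParams = field(default_factory=ModelParams)
    schedule: MoveSchedule = field(default_factory=MoveSchedule)
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    run: dict = field(default_factory=lambda: dict(_RUN_KEYS))
    sweep: dict = field(default_factory=lambda: dict(_SWEEP_KEYS))
    synth: dict = field(default_factory=lambda: dict(_SYNTH_KEYS))
    image: dict = field(default_factory=lambda: dict(_IMAGE_KEYS))
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "model": {k: v for k, v in dataclasses.asdict(self.model).items()
                      if k != "n_patches"},
            "schedule": dataclasses.asdict(self.schedule),
            "thresholds": dataclasses.asdict(self.thresholds),
            "run": self.run, "sweep": self.sweep, "synth": self.synth,
            "image": self.image, "seed": self.seed, "outdir": self.outdir,
            "log_level": self.log_level,
        }
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: Union[str, Path, None] = None,
                data: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML config; unknown keys raise, defaults fill in."""
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kw: dict[str, Any] = {}
    for name in ("model", "schedule", "thresholds"):
        if name in data:
            kw[name] = _build_section(name, dict(data[name] or {}))
    for name, defaults in (("run", _RUN_KEYS), ("sweep", _SWEEP_KEYS),
                           ("synth", _SYNTH_KEYS), ("image", _IMAGE_KEYS)):
        if name in data:
            kw[name] = _merge_plain(name, dict(defaults), dict(data[name] or {}))
    for name in ("seed", "outdir", "log_level"):
        if name in data:
            kw[name] = data[name]
    return RunConfig(**kw)


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
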