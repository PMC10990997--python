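"""Pipeline configuration: defaults, YAML round-tripping, hashing.

Every under-specified constant of the analysis lives here with its
default (partition coefficient λ = 0.80, m = 1, decapitation at 60 s,
interpolating calibration with hard range errors, no quench correction,
α = 0.05, the study-mirror synthetic design).  Fields left at their
default when a config file is loaded are logged, so a run's provenance
is explicit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError

__all__ = [
    "KineticsConfig",
    "CalibrationConfig",
    "QuenchConfig",
    "StatsConfig",
    "SyntheticConfig",
    "PipelineConfig",
]

logger = logging.getLogger(__name__)


@dataclass
class KineticsConfig:
    partition_coefficient: float = 0.80  # YAML key: lambda
    m: float = 1.0
    decap_time_s: float = 60.0


@dataclass
class CalibrationConfig:
    mode: str = "interpolating"          # or "linear"
    extrapolation: str = "error"         # or "clamp"
    min_readings: int = 8


@dataclass
class QuenchConfig:
    """Linear quench curve efficiency = a + b·quench_index; a=1, b=0 means
    no correction (efficiency columns in the blood file take precedence)."""

    a: float = 1.0
    b: float = 0.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    layout: str = "per_region"           # or "group_by_region"


@dataclass
class SyntheticConfig:
    n_per_group: int = 8
    between_animal_cv: float = 0.10
    od_noise_sd: float = 0.002
    arterial_noise_cv: float = 0.05
    peak_conc: float = 600.0
    rise_time_s: float = 60.0


_SECTION_KEYS = {
    "kinetics": {"lambda": "partition_coefficient", "m": "m",
                 "decap_time_s": "decap_time_s"},
}


def _load_section(cls, raw: dict, section: str):
    mapping = _SECTION_KEYS.get(section, {})
    kwargs = {}
    known = {f.name for f in fields(cls)}
    for key, value in (raw or {}).items():
        name = mapping.get(key, key)
        if name not in known:
            raise ValidationError(f"unknown key {key!r} in config section {section!r}")
        kwargs[name] = value
    defaulted = sorted(known - set(kwargs))
    if defaulted:
        logger.info("config section %s: using defaults for %s", section, defaulted)
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "out"
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    quench: QuenchConfig = field(default_factory=QuenchConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        cfg = cls(
            seed=int(raw.pop("seed", 0)),
            output_dir=str(raw.pop("output_dir", "out")),
            kinetics=_load_section(KineticsConfig, raw.pop("kinetics", {}), "kinetics"),
            calibration=_load_section(CalibrationConfig, raw.pop("calibration", {}),
                                      "calibration"),
            quench=_load_section(QuenchConfig, raw.pop("quench", {}), "quench"),
            stats=_load_section(StatsConfig, raw.pop("stats", {}), "stats"),
            synthetic=_load_section(SyntheticConfig, raw.pop("synthetic", {}),
                                    "synthetic"),
        )
        if raw:
            raise ValidationError(f"unknown top-level config keys: {sorted(raw)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        kin = d["kinetics"]
        kin["lambda"] = kin.pop("partition_coefficient")
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        """sha256 of the canonical serialized config (provenance stamp)."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()
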