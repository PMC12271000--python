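"""Run configuration: one YAML file describing a full commissioning run.

Sections map one-to-one onto the package's domain types (collimator,
beam geometry, dose engine, gamma criteria, metrics) and every section is
validated through the corresponding type's own invariants before any
computation starts.  All randomness in a run flows from the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .collimator import CollimatorSpec
from .dose import BeamModel
from .gamma import GammaCriteria
from .transforms import BeamGeometry

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    collimator: CollimatorSpec = field(default_factory=CollimatorSpec)
    beam: BeamGeometry = field(default_factory=lambda: BeamGeometry(snout_extension=235.0))
    dose_engine: BeamModel = field(default_factory=BeamModel)
    gamma: GammaCriteria = field(default_factory=GammaCriteria)
    geud_exponent: float = -10.0
    cylinder_diameters: tuple = (5.0, 10.0, 15.0)
    depth_range: tuple = (50.0, 150.0)
    phantom_surface_z: float = 100.0
    seed: int = 0
    output_dir: str = "protongrid_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beam"]["isocenter_translation"] = [float(v) for v in
                                              self.beam.isocenter_translation]
        return d


_SECTION_TYPES = {
    "collimator": CollimatorSpec,
    "beam": BeamGeometry,
    "dose_engine": BeamModel,
    "gamma": GammaCriteria,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Any omitted section or key falls back to the defaults; unknown keys are
    rejected so typos fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            if not isinstance(value, dict):
                raise ValueError(f"section '{key}' must be a mapping")
            valid = set(cls.__dataclass_fields__)
            unknown = set(value) - valid
            if unknown:
                raise ValueError(f"unknown keys in section '{key}': {sorted(unknown)}")
            if "field_size" in value:
                value["field_size"] = tuple(value["field_size"])
            kwargs[key] = cls(**value)
        elif key in RunConfig.__dataclass_fields__:
            if key in ("cylinder_diameters", "depth_range"):
                value = tuple(value)
            kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key: {key}")
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
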