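"""Run configuration with YAML loading and full defaulting.

All protocol constants live in :mod:`protonfilm._constants`; a
:class:`RunConfig` collects the tunable ones for a pipeline run so a single
YAML file (any subset of the fields) reproduces an analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._constants import (
    CALIBRATION_DOSE_GRID_GY,
    KINETICS_TIME_GRID_H,
    PLATEAU_THRESHOLD_PCT_PER_H,
    REFERENCE_TIME_H,
    SENSITIVITY_PERTURBATION,
)

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Seed, conventions and grids for one reproducible pipeline run."""

    seed: int = 0
    sigma_form: str = "standard"  # netOD uncertainty formula variant
    roi: str = "central:0.5"  # 'x0,y0,w,h' or 'central:FRACTION'
    dose_grid_gy: list = field(default_factory=lambda: list(CALIBRATION_DOSE_GRID_GY))
    time_grid_h: list = field(default_factory=lambda: list(KINETICS_TIME_GRID_H))
    resolvability_k: float = 2.0
    plateau_threshold_pct_per_h: float = PLATEAU_THRESHOLD_PCT_PER_H
    reference_time_h: float = REFERENCE_TIME_H
    sensitivity_perturbation: float = SENSITIVITY_PERTURBATION

    def __post_init__(self) -> None:
        if self.plateau_threshold_pct_per_h <= 0:
            raise ValueError("plateau threshold must be positive")
        if self.sigma_form not in ("standard", "paper"):
            raise ValueError("sigma_form must be 'standard' or 'paper'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
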