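"""Run configuration: one structured YAML file drives the whole pipeline.

The config nests the population models, plate design, optics, segmentation
and screening thresholds, the dose ladder, and the run seed.  It round-trips
losslessly through YAML, and its canonical-JSON SHA-256 hash is logged at
the start of every run for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .models import PopulationModel
from .simulate import (
    DEFAULT_SEEDING,
    IncubationConfig,
    OpticsConfig,
    default_populations,
)


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    smoothing_sigma: float = Field(default=2.0, gt=0)
    expected_radius_px: float = Field(default=6.0, gt=0)
    min_area_px: Optional[int] = None
    ring_px: int = Field(default=4, ge=1)


class ScreeningConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    huh7_min_inhib: float = Field(default=50.0, ge=0, le=100)
    fa2n4_max_inhib: float = Field(default=20.0, ge=0, le=100)
    zprime_gate: float = Field(default=0.5, le=1.0)
    min_cells: int = Field(default=100, ge=0)
    replicate_disagreement_pp: float = Field(default=30.0, gt=0)


class DoseLadderConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    log10_min: float = -12.0  # 1 pM
    log10_max: float = -4.0  # 100 uM
    n_points: int = Field(default=9, ge=4)
    include_zero: bool = True

    def doses_m(self):
        import numpy as np

        ladder = np.logspace(self.log10_min, self.log10_max, self.n_points)
        if self.include_zero:
            ladder = np.concatenate([[0.0], ladder])
        return ladder


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    output_dir: str = "hccscreen_out"
    images_dir: Optional[str] = None
    tables_dir: Optional[str] = None
    plate_id: str = "P1"
    n_compounds: int = Field(default=43, ge=3)
    replicates: int = Field(default=2, ge=1)
    test_dose_m: float = Field(default=10e-6, gt=0)
    seeding: Dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_SEEDING))
    populations: Dict[str, PopulationModel] = Field(
        default_factory=default_populations)
    optics: OpticsConfig = OpticsConfig()
    incubation: IncubationConfig = IncubationConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    screening: ScreeningConfig = ScreeningConfig()
    dose_ladder: DoseLadderConfig = DoseLadderConfig()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
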