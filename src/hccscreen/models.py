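"""Domain types for the co-culture screening pipeline.

The screen mixes a malignant population (HCC, Huh7-like) with an immortalized
hepatocyte population (Fa2N-4-like) in 384-well plates, treats with a compound
library, and reads out per-population cell counts from multi-channel
fluorescence images.  The types here describe the two populations, the drug
library, the plate layout, and the containers the simulator and analysis
stages exchange.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

# Channel naming contract shared by the simulator, file I/O and segmentation.
CHANNELS = ("hoechst", "chalv1", "afp", "lyso", "ctsb", "casp3")

PLATE_ROWS = [chr(ord("A") + i) for i in range(16)]  # A..P
PLATE_COLS = list(range(1, 25))  # 1..24

ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_TEST = "test"
ROLE_EMPTY = "empty"

DMSO_ID = "DMSO"
SORAFENIB_ID = "sorafenib"
SORAFENIB_DOSE_M = 10e-6  # 10 uM positive control


class LogNormalIntensity(BaseModel):
    """Log-normal fluorescence intensity: median and geometric SD (>= 1)."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    gsd: float = Field(ge=1.0)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        sigma = np.log(self.gsd)
        return np.exp(rng.normal(np.log(self.median), sigma, size=size))


class PopulationModel(BaseModel):
    """Growth and marker parameters of one cell population.

    ``doubling_time_h`` drives the exponential growth law
    N(t) = N0 * 2**(t / Td); marker intensities are log-normal per channel.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    doubling_time_h: float = Field(gt=0)
    nucleus_radius_mean_px: float = Field(gt=0)
    nucleus_radius_sd_px: float = Field(ge=0)
    marker_intensity: Dict[str, LogNormalIntensity]
    baseline_death_frac: float = Field(ge=0, lt=1, default=0.0)

    def grown_count(self, n0: float, t_h: float) -> float:
        return n0 * 2.0 ** (t_h / self.doubling_time_h)


def check_marker_contrast(hcc: PopulationModel, hepatocyte: PopulationModel,
                          markers: Tuple[str, ...] = ("chalv1", "afp")) -> None:
    """The HCC population must have strictly higher CHALV1/AFP medians.

    This is the premise of two-marker classification; a library of drugs
    cannot be screened if the populations are not separable.
    """
    for m in markers:
        if hcc.marker_intensity[m].median <= hepatocyte.marker_intensity[m].median:
            raise ValueError(
                f"HCC population {hcc.name!r} must exceed hepatocyte "
                f"{hepatocyte.name!r} in marker {m!r} median intensity"
            )


class FourPLKill(BaseModel):
    """4PL viability curve V(c) = bottom + (top-bottom)/(1+(c/ic50)**hill).

    top/bottom are % viability; ic50 in molar; hill > 0 (kill curves decrease
    with dose).
    """

    model_config = ConfigDict(frozen=True)

    top: float = Field(default=100.0)
    bottom: float = Field(default=0.0, ge=0)
    ic50_m: float = Field(gt=0)
    hill: float = Field(gt=0, default=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")
        return self

    def viability_pct(self, dose_m) -> np.ndarray:
        c = np.asarray(dose_m, dtype=float)
        with np.errstate(divide="ignore"):
            frac = np.where(c > 0, (c / self.ic50_m) ** self.hill, 0.0)
        return self.bottom + (self.top - self.bottom) / (1.0 + frac)

    def survival_frac(self, dose_m) -> np.ndarray:
        return np.clip(self.viability_pct(dose_m) / 100.0, 0.0, None)


class DrugEffectModel(BaseModel):
    """Per-population kill curves of one compound."""

    model_config = ConfigDict(frozen=True)

    compound_id: str
    effects: Dict[str, FourPLKill]  # population name -> curve

    def survival(self, population: str, dose_m: float) -> float:
        if population not in self.effects:
            return 1.0
        return float(self.effects[population].survival_frac(dose_m))


LAYOUT_COLUMNS = ["plate", "well", "role", "compound", "dose_M", "replicate"]


def well_name(row: str, col: int) -> str:
    return f"{row}{col:02d}"


def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    """Check a plate-layout table against the 384-well design contract."""
    missing = set(LAYOUT_COLUMNS) - set(layout.columns)
    if missing:
        raise ValueError(f"layout missing columns: {sorted(missing)}")
    bad = ~layout["role"].isin([ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_TEST, ROLE_EMPTY])
    if bad.any():
        raise ValueError(f"unknown roles: {sorted(layout.loc[bad, 'role'].unique())}")
    for plate, sub in layout.groupby("plate"):
        n_neg = (sub["role"] == ROLE_NEGATIVE).sum()
        n_pos = (sub["role"] == ROLE_POSITIVE).sum()
        if n_neg < 8 or n_pos < 8:
            raise ValueError(
                f"plate {plate!r} needs >=8 negative and >=8 positive control "
                f"wells (got {n_neg} / {n_pos})"
            )
        neg = sub[sub["role"] == ROLE_NEGATIVE]
        if (neg["dose_M"] != 0).any():
            raise ValueError("negative controls must carry dose 0 (DMSO)")
        pos = sub[sub["role"] == ROLE_POSITIVE]
        if not np.allclose(pos["dose_M"], SORAFENIB_DOSE_M):
            raise ValueError("positive controls must carry 10 uM sorafenib")
        if sub["well"].duplicated().any():
            raise ValueError(f"plate {plate!r} has duplicated wells")
    return layout


@dataclass
class WellTruth:
    """Ground truth for one simulated well (test oracle, not measurement)."""

    n_seeded: Dict[str, int]
    n_grown: Dict[str, float]  # expected counts after growth (pre-kill)
    n_survive: Dict[str, int]  # realized surviving counts in the whole well
    cells: pd.DataFrame  # rendered cells: field,row,col,population,radius_px,...


@dataclass
class WellRecord:
    """One well: its layout role and, when present, images, features, truth."""

    plate: str
    well: str
    role: str
    compound: str
    dose_m: float
    replicate: int
    images: Dict[Tuple[int, str], np.ndarray] = field(default_factory=dict)
    cells: Optional[pd.DataFrame] = None
    truth: Optional[WellTruth] = None

    @property
    def n_fields(self) -> int:
        return len({f for f, _ in self.images})

    def channel_stack(self, channel: str) -> Dict[int, np.ndarray]:
        return {f: img for (f, ch), img in self.images.items() if ch == channel}


@dataclass
class SpheroidStack:
    """A 3D spheroid z-stack: per-slice nuclei + cleaved caspase-3 channels."""

    nuclei: np.ndarray  # (n_slices, H, W) uint16
    casp3: np.ndarray  # (n_slices, H, W) uint16
    center: Tuple[float, float]
    radius_px: float
    true_midplane_apoptotic_frac: float
    midplane_cells: pd.DataFrame  # row,col,apoptotic

    @property
    def n_slices(self) -> int:
        return int(self.nuclei.shape[0])

    @property
    def midplane_index(self) -> int:
        return self.n_slices // 2


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string-able parts.

    Used to derive per-well / per-object seeds from one run seed so that any
    well can be regenerated in isolation, bit-identically, on any platform.
    """
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
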