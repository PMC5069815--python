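"""Synthetic co-culture screen generator.

Emulates the study conditions of a 384-well two-population phenotypic screen:
Huh7-like HCC cells (doubling time 23.8 h) mixed with Fa2N-4-like hepatocytes
(43.5 h) at 800:1500 cells/well, 16 h attachment then 72 h compound exposure,
4 image fields per well, DMSO negative and 10 uM sorafenib positive controls,
and per-compound two-population 4PL kill curves.  Every image and table
carries ground truth so each downstream stage can be tested against a known
answer without any external data.

All randomness flows from one explicit seed; per-well streams are derived by
stable hashing so regeneration of any single well is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .models import (
    DMSO_ID,
    LAYOUT_COLUMNS,
    PLATE_COLS,
    PLATE_ROWS,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ROLE_TEST,
    SORAFENIB_DOSE_M,
    SORAFENIB_ID,
    DrugEffectModel,
    FourPLKill,
    LogNormalIntensity,
    PopulationModel,
    SpheroidStack,
    WellRecord,
    WellTruth,
    check_marker_contrast,
    stable_seed,
    validate_layout,
    well_name,
)

HCC = "Huh7"
HEPATOCYTE = "Fa2N-4"

# --------------------------------------------------------------------------
# growth law
# --------------------------------------------------------------------------


def grow_population(n0: float, doubling_time_h: float, t_h: float,
                    rng: Optional[np.random.Generator] = None) -> float:
    """Expected cell count after exponential growth, N = n0 * 2**(t/Td).

    With ``rng`` given, returns a Poisson draw centred on the expectation
    (the stochastic variant used by the well simulator).
    """
    if doubling_time_h <= 0:
        raise ValueError("doubling_time_h must be > 0")
    if n0 < 0 or t_h < 0:
        raise ValueError("n0 and t must be >= 0")
    expected = n0 * 2.0 ** (t_h / doubling_time_h)
    if rng is None:
        return expected
    return float(rng.poisson(expected))


# --------------------------------------------------------------------------
# study-condition defaults
# --------------------------------------------------------------------------


class OpticsConfig(BaseModel):
    """Rendering geometry and noise; fixture parameters, not instrument claims."""

    model_config = ConfigDict(frozen=True)

    field_size_px: int = Field(default=512, ge=64)
    n_fields: int = Field(default=4, ge=1)
    background: float = Field(default=100.0, ge=0)
    read_noise_sd: float = Field(default=10.0, ge=0)
    poisson_noise: bool = False
    # fraction of the whole well's cells captured across all fields; a 20x
    # objective images a small part of a 384-well, so counts per field stay
    # in the low hundreds.  The default keeps control wells near 280
    # cells/field: a 10-percentage-point inhibition margin is then ~3 SD of
    # the duplicate-mean counting noise, giving the hit rule adequate power
    capture_fraction: float = Field(default=0.07, gt=0, le=1)
    min_sep_factor: float = Field(default=1.2, gt=0)  # x mean nucleus diameter
    ring_px: int = Field(default=4, ge=1)
    hoechst: LogNormalIntensity = LogNormalIntensity(median=6000, gsd=1.2)


class IncubationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    pre_incubation_h: float = Field(default=16.0, ge=0)
    exposure_h: float = Field(default=72.0, ge=0)

    @property
    def total_h(self) -> float:
        return self.pre_incubation_h + self.exposure_h


def default_populations() -> Dict[str, PopulationModel]:
    """The two co-culture populations at the study's growth rates."""
    hcc = PopulationModel(
        name=HCC,
        doubling_time_h=23.8,
        nucleus_radius_mean_px=6.0,
        nucleus_radius_sd_px=1.0,
        marker_intensity={
            "chalv1": LogNormalIntensity(median=1200, gsd=1.4),
            "afp": LogNormalIntensity(median=1200, gsd=1.4),
        },
        baseline_death_frac=0.02,
    )
    hep = PopulationModel(
        name=HEPATOCYTE,
        doubling_time_h=43.5,
        nucleus_radius_mean_px=6.0,
        nucleus_radius_sd_px=1.0,
        marker_intensity={
            "chalv1": LogNormalIntensity(median=120, gsd=1.4),
            "afp": LogNormalIntensity(median=120, gsd=1.4),
        },
        baseline_death_frac=0.02,
    )
    check_marker_contrast(hcc, hep)
    return {HCC: hcc, HEPATOCYTE: hep}


DEFAULT_SEEDING = {HEPATOCYTE: 1500, HCC: 800}  # cells/well, pilot densities

# Reference potencies (uM -> M) of the three selective anti-folates.
# Hepatocyte arms carry a high bottom plateau: in co-culture the hepatocyte
# population resists these compounds (its inhibition stays under the 20% hit
# gate) even though monoculture IC50s are low.
_SELECTIVE = {
    "methotrexate-like": (0.004074e-6, 0.01518e-6),
    "pyrimethamine-like": (2.764e-6, 23.43e-6),
    "aminopterin-like": (0.0005194e-6, 0.001688e-6),
}


def default_drug_library(n_compounds: int = 43) -> Dict[str, DrugEffectModel]:
    """Deterministic 43-compound pilot library with 3 HCC-selective hits.

    Composition mirrors a small screening deck: 3 selective anti-folate-like
    compounds, a block of pan-cytotoxic compounds (kill both populations), a
    block of hepatotoxic compounds (kill hepatocytes preferentially), and
    inactive filler.  Plus the two controls (DMSO, sorafenib).
    """
    if n_compounds < 3:
        raise ValueError("library needs at least the 3 selective compounds")
    lib: Dict[str, DrugEffectModel] = {}
    for name, (ic50_hcc, ic50_hep) in _SELECTIVE.items():
        lib[name] = DrugEffectModel(
            compound_id=name,
            effects={
                HCC: FourPLKill(top=100, bottom=2, ic50_m=ic50_hcc, hill=1.0),
                HEPATOCYTE: FourPLKill(top=100, bottom=90, ic50_m=ic50_hep, hill=1.0),
            },
        )
    n_rest = n_compounds - 3
    n_tox = max(0, min(12, n_rest))
    n_hepatotox = max(0, min(8, n_rest - n_tox))
    n_inactive = n_rest - n_tox - n_hepatotox
    rng = np.random.default_rng(stable_seed("library"))
    for i in range(n_tox):
        ic50 = float(10 ** rng.uniform(-6.5, -5.5))
        lib[f"cytotoxic-{i+1:02d}"] = DrugEffectModel(
            compound_id=f"cytotoxic-{i+1:02d}",
            effects={
                HCC: FourPLKill(top=100, bottom=5, ic50_m=ic50, hill=1.2),
                HEPATOCYTE: FourPLKill(top=100, bottom=10, ic50_m=ic50 * 1.5, hill=1.2),
            },
        )
    for i in range(n_hepatotox):
        ic50 = float(10 ** rng.uniform(-6.3, -5.7))
        lib[f"hepatotoxic-{i+1:02d}"] = DrugEffectModel(
            compound_id=f"hepatotoxic-{i+1:02d}",
            effects={
                HCC: FourPLKill(top=100, bottom=50, ic50_m=100e-6, hill=1.0),
                HEPATOCYTE: FourPLKill(top=100, bottom=15, ic50_m=ic50, hill=1.2),
            },
        )
    for i in range(n_inactive):
        lib[f"inactive-{i+1:02d}"] = DrugEffectModel(
            compound_id=f"inactive-{i+1:02d}",
            effects={
                HCC: FourPLKill(top=100, bottom=95, ic50_m=1e-3, hill=1.0),
                HEPATOCYTE: FourPLKill(top=100, bottom=95, ic50_m=1e-3, hill=1.0),
            },
        )
    # controls
    lib[DMSO_ID] = DrugEffectModel(compound_id=DMSO_ID, effects={})
    lib[SORAFENIB_ID] = DrugEffectModel(
        compound_id=SORAFENIB_ID,
        effects={
            HCC: FourPLKill(top=100, bottom=3, ic50_m=2e-6, hill=1.5),
            HEPATOCYTE: FourPLKill(top=100, bottom=40, ic50_m=4e-6, hill=1.5),
        },
    )
    return lib


def selective_compounds() -> List[str]:
    return list(_SELECTIVE)


def pilot_plate_layout(compounds: Sequence[str], plate_id: str = "P1",
                       n_negative: int = 8, n_positive: int = 8,
                       replicates: int = 2,
                       test_dose_m: float = 10e-6) -> pd.DataFrame:
    """384-well pilot layout: controls in columns 1-2, tests in duplicate."""
    rows = []
    for i in range(n_negative):
        rows.append((plate_id, well_name(PLATE_ROWS[i], 1), ROLE_NEGATIVE,
                     DMSO_ID, 0.0, i + 1))
    for i in range(n_positive):
        rows.append((plate_id, well_name(PLATE_ROWS[i], 2), ROLE_POSITIVE,
                     SORAFENIB_ID, SORAFENIB_DOSE_M, i + 1))
    slots = [(r, c) for c in PLATE_COLS[2:] for r in PLATE_ROWS]
    need = len(compounds) * replicates
    if need > len(slots):
        raise ValueError("layout overflow: too many test wells for one plate")
    k = 0
    for comp in compounds:
        for rep in range(1, replicates + 1):
            r, c = slots[k]
            rows.append((plate_id, well_name(r, c), ROLE_TEST, comp,
                         test_dose_m, rep))
            k += 1
    return validate_layout(pd.DataFrame(rows, columns=LAYOUT_COLUMNS))


def default_dose_ladder() -> np.ndarray:
    """The 10-point hit-confirmation ladder (molar).

    A zero-dose vehicle control plus 9 doses at whole decades from 1 pM to
    100 uM — ten concentrations in total.
    """
    return np.concatenate([[0.0], np.logspace(-12, -4, 9)])


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


class FieldTooCrowdedError(RuntimeError):
    pass


def _place_cells(n: int, size: int, min_sep: float, margin: float,
                 rng: np.random.Generator, max_attempts: int = 2000
                 ) -> np.ndarray:
    """Rejection-sample ``n`` centroids with pairwise distance >= min_sep."""
    pts = np.empty((n, 2))
    lo, hi = margin, size - margin
    if hi <= lo:
        raise FieldTooCrowdedError(
            f"field of {size} px cannot hold cells with margin {margin} px")
    for i in range(n):
        for _ in range(max_attempts):
            cand = rng.uniform(lo, hi, size=2)
            if i == 0 or (np.linalg.norm(pts[:i] - cand, axis=1) >= min_sep).all():
                pts[i] = cand
                break
        else:
            raise FieldTooCrowdedError(
                f"could not place {n} cells at min separation {min_sep:.1f} px "
                f"in a {size}x{size} px field")
    return pts


def _disk_mask(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2) <= radius**2


def _add_patch(img: np.ndarray, row: float, col: float, patch: np.ndarray) -> None:
    """Accumulate a square patch centred at (row, col), clipped at borders."""
    r, c = int(round(row)), int(round(col))
    h = patch.shape[0] // 2
    r0, r1 = max(0, r - h), min(img.shape[0], r + h + 1)
    c0, c1 = max(0, c - h), min(img.shape[1], c + h + 1)
    pr0, pc0 = r0 - (r - h), c0 - (c - h)
    img[r0:r1, c0:c1] += patch[pr0:pr0 + (r1 - r0), pc0:pc0 + (c1 - c0)]


def _gaussian_patch(radius: float, amplitude: float) -> np.ndarray:
    sigma = radius / 2.0
    r = int(math.ceil(3 * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def _finalize(img: np.ndarray, optics: OpticsConfig,
              rng: np.random.Generator) -> np.ndarray:
    out = img + optics.background
    if optics.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if optics.read_noise_sd > 0:
        out = out + rng.normal(0, optics.read_noise_sd, img.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def render_field(cells: pd.DataFrame, optics: OpticsConfig,
                 rng: np.random.Generator,
                 channels: Sequence[str] = ("hoechst", "chalv1", "afp"),
                 ) -> Dict[str, np.ndarray]:
    """Render one field from a per-cell table (row,col,radius_px,<channel>...).

    Hoechst nuclei are Gaussian spots; marker channels are uniform disks over
    the nucleus-plus-ring footprint scaled by each cell's sampled intensity.
    """
    size = optics.field_size_px
    acc = {ch: np.zeros((size, size)) for ch in channels}
    for cell in cells.itertuples(index=False):
        r = cell.radius_px
        if "hoechst" in acc:
            _add_patch(acc["hoechst"], cell.row, cell.col,
                       _gaussian_patch(r, cell.hoechst))
        foot = _disk_mask(r + optics.ring_px)
        for ch in channels:
            if ch == "hoechst":
                continue
            val = getattr(cell, ch)
            _add_patch(acc[ch], cell.row, cell.col, foot * float(val))
    return {ch: _finalize(a, optics, rng) for ch, a in acc.items()}


# --------------------------------------------------------------------------
# well / plate simulation
# --------------------------------------------------------------------------


def simulate_well(entry, populations: Dict[str, PopulationModel],
                  drug_models: Dict[str, DrugEffectModel],
                  seed: int,
                  seeding: Optional[Dict[str, int]] = None,
                  optics: Optional[OpticsConfig] = None,
                  incubation: Optional[IncubationConfig] = None,
                  render: bool = True) -> WellRecord:
    """Simulate one well end to end: growth, drug kill, placement, rendering.

    ``entry`` is one layout row (anything with plate/well/role/compound/
    dose_M/replicate attributes).  Growth spans attachment plus exposure;
    the compound's per-population 4PL survival applies as an endpoint
    multiplier.  Surviving cells are thinned by the optics capture fraction,
    split across fields, placed without degenerate overlap, and rendered as
    one 16-bit image per channel per field.
    """
    optics = optics or OpticsConfig()
    incubation = incubation or IncubationConfig()
    seeding = seeding or DEFAULT_SEEDING
    rng = np.random.default_rng(seed)
    drug = drug_models[entry.compound]

    n_grown: Dict[str, float] = {}
    n_survive: Dict[str, int] = {}
    for name, pop in populations.items():
        grown = pop.grown_count(seeding.get(name, 0), incubation.total_h)
        n_grown[name] = grown
        surv_frac = drug.survival(name, entry.dose_M) * (1 - pop.baseline_death_frac)
        n_survive[name] = int(rng.poisson(grown * min(surv_frac, 1.0)))

    mean_r = float(np.mean([p.nucleus_radius_mean_px for p in populations.values()]))
    min_sep = optics.min_sep_factor * 2 * mean_r

    truth_rows: List[pd.DataFrame] = []
    images: Dict[Tuple[int, str], np.ndarray] = {}
    p_field = optics.capture_fraction / optics.n_fields
    for f in range(optics.n_fields):
        counts = {name: rng.binomial(n_survive[name], p_field)
                  for name in populations}
        n_tot = sum(counts.values())
        tbl = {
            "field": np.full(n_tot, f, dtype=int),
            "population": np.concatenate(
                [np.full(c, name, dtype=object) for name, c in counts.items()]
            ) if n_tot else np.empty(0, dtype=object),
        }
        pos = _place_cells(n_tot, optics.field_size_px, min_sep,
                           margin=2 * mean_r, rng=rng) if n_tot else np.empty((0, 2))
        cells = pd.DataFrame(tbl)
        cells["row"], cells["col"] = pos[:, 0], pos[:, 1]
        radii, hoechst = np.empty(n_tot), np.empty(n_tot)
        marker_cols = {"chalv1": np.empty(n_tot), "afp": np.empty(n_tot)}
        idx = 0
        for name, c in counts.items():
            pop = populations[name]
            sl = slice(idx, idx + c)
            radii[sl] = np.clip(
                rng.normal(pop.nucleus_radius_mean_px, pop.nucleus_radius_sd_px, c),
                2.0, None)
            hoechst[sl] = optics.hoechst.sample(rng, c)
            for m in marker_cols:
                marker_cols[m][sl] = pop.marker_intensity[m].sample(rng, c)
            idx += c
        cells["radius_px"] = radii
        cells["hoechst"] = hoechst
        for m, v in marker_cols.items():
            cells[m] = v
        truth_rows.append(cells)
        if render:
            field_imgs = render_field(cells, optics, rng)
            for ch, img in field_imgs.items():
                images[(f, ch)] = img

    truth_cells = (pd.concat(truth_rows, ignore_index=True)
                   if truth_rows else pd.DataFrame())
    truth = WellTruth(
        n_seeded={k: int(v) for k, v in seeding.items()},
        n_grown=n_grown,
        n_survive=n_survive,
        cells=truth_cells,
    )
    return WellRecord(plate=entry.plate, well=entry.well, role=entry.role,
                      compound=entry.compound, dose_m=entry.dose_M,
                      replicate=int(entry.replicate), images=images, truth=truth)


@dataclass
class PlateSim:
    """A simulated plate: layout plus one WellRecord per non-empty well."""

    layout: pd.DataFrame
    wells: Dict[str, WellRecord]
    populations: Dict[str, PopulationModel] = field(default_factory=dict)
    drug_models: Dict[str, DrugEffectModel] = field(default_factory=dict)
    seed: int = 0


def simulate_plate(layout: pd.DataFrame,
                   populations: Optional[Dict[str, PopulationModel]] = None,
                   drug_models: Optional[Dict[str, DrugEffectModel]] = None,
                   seed: int = 0,
                   seeding: Optional[Dict[str, int]] = None,
                   optics: Optional[OpticsConfig] = None,
                   incubation: Optional[IncubationConfig] = None,
                   render: bool = True) -> PlateSim:
    populations = populations or default_populations()
    drug_models = drug_models or default_drug_library()
    validate_layout(layout)
    hcc_pops = [p for p in populations.values() if p.name == HCC]
    hep_pops = [p for p in populations.values() if p.name == HEPATOCYTE]
    if hcc_pops and hep_pops:
        check_marker_contrast(hcc_pops[0], hep_pops[0])
    wells: Dict[str, WellRecord] = {}
    for entry in layout.itertuples(index=False):
        if entry.role == "empty":
            continue
        wseed = stable_seed(seed, entry.plate, entry.well)
        wells[entry.well] = simulate_well(
            entry, populations, drug_models, seed=wseed, seeding=seeding,
            optics=optics, incubation=incubation, render=render)
    return PlateSim(layout=layout, wells=wells, populations=populations,
                    drug_models=drug_models, seed=seed)


def match_to_truth(features: pd.DataFrame, truth_cells: pd.DataFrame,
                   max_dist_px: float = 2.0) -> pd.DataFrame:
    """Match segmented cells to generator ground truth by nearest centroid.

    One-to-one greedy matching per field (closest pairs first) within
    ``max_dist_px``.  Returns the feature rows that found a partner, with the
    truth ``population`` and the centroid offset attached — the basis for
    detection-rate and classification-accuracy checks.
    """
    from scipy.spatial import cKDTree

    out = []
    for f, feats in features.groupby("field"):
        truth = truth_cells[truth_cells["field"] == f]
        if truth.empty or feats.empty:
            continue
        tpos = truth[["row", "col"]].to_numpy(float)
        dpos = feats[["centroid_row", "centroid_col"]].to_numpy(float)
        dist, idx = cKDTree(tpos).query(dpos)
        order = np.argsort(dist, kind="stable")
        used_t, used_d = set(), set()
        for d_i in order:
            t_i = int(idx[d_i])
            if dist[d_i] > max_dist_px or t_i in used_t or d_i in used_d:
                continue
            used_t.add(t_i)
            used_d.add(int(d_i))
            row = feats.iloc[int(d_i)].to_dict()
            row["true_population"] = truth.iloc[t_i]["population"]
            row["match_dist_px"] = float(dist[d_i])
            out.append(row)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# plate-reader style tables
# --------------------------------------------------------------------------


def simulate_dose_response_table(drug_model: FourPLKill,
                                 doses_m: Sequence[float],
                                 replicates: int = 3,
                                 noise_sd: float = 0.0,
                                 seed: int = 0,
                                 compound: str = "compound") -> pd.DataFrame:
    """Viability % table (compound, dose_M, replicate, viability_pct).

    Noise-free tables reproduce the 4PL exactly; Gaussian noise of SD
    ``noise_sd`` (percentage points) is added otherwise.
    """
    doses = np.asarray(doses_m, dtype=float)
    if doses[0] != 0:
        raise ValueError("first entry must be the zero-dose control")
    if not np.all(np.diff(doses) > 0):
        raise ValueError("doses must be strictly increasing")
    if np.unique(doses[doses > 0]).size < 4:
        raise ValueError("need >=4 distinct nonzero doses for downstream fitting")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        v = drug_model.viability_pct(doses)
        if noise_sd > 0:
            v = v + rng.normal(0, noise_sd, size=v.shape)
        for d, vi in zip(doses, v):
            rows.append((compound, d, rep, float(vi)))
    return pd.DataFrame(rows, columns=["compound", "dose_M", "replicate",
                                       "viability_pct"])


def simulate_resazurin(viable_count: float, gain: float, background: float,
                       noise_sd: float = 0.0, seed: int = 0) -> float:
    """570/600 nm resazurin-reduction ratio: linear in viable cell number."""
    if gain <= 0:
        raise ValueError("gain must be > 0")
    signal = background + gain * viable_count
    if noise_sd > 0:
        signal += float(np.random.default_rng(seed).normal(0, noise_sd))
    return float(signal)


# --------------------------------------------------------------------------
# organelle (MoA) images
# --------------------------------------------------------------------------


@dataclass
class OrganelleSim:
    lyso: np.ndarray
    ctsb: np.ndarray
    cell_labels: np.ndarray  # footprint label map, 0 = background
    truth: pd.DataFrame  # cell_id,row,col,puncta_count,translocated_frac


def simulate_organelle_image(n_cells: int,
                             vesicle_rate: float,
                             vesicle_radius_px: float = 2.0,
                             translocated_frac: float = 0.0,
                             cell_radius_px: float = 18.0,
                             size: int = 512,
                             ctsb_total: float = 60000.0,
                             puncta_amplitude: float = 3000.0,
                             background: float = 50.0,
                             read_noise_sd: float = 3.0,
                             seed: int = 0) -> OrganelleSim:
    """LysoTracker + cathepsin-B channels for ``n_cells`` grid-placed cells.

    Per cell, a Poisson(vesicle_rate) number of puncta is placed inside the
    footprint (non-overlapping); the cathepsin-B budget is split with fraction
    ``translocated_frac`` spread uniformly over the footprint (cytosolic) and
    the remainder concentrated in the puncta (lysosomal).
    """
    if vesicle_rate < 0:
        raise ValueError("vesicle_rate must be >= 0")
    if not 0 <= translocated_frac <= 1:
        raise ValueError("translocated_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    pitch = int(2 * cell_radius_px + 6)
    per_side = max(1, (size - pitch) // pitch + 1)
    if n_cells > per_side**2:
        raise ValueError(f"at most {per_side**2} cells fit a {size} px image")
    lyso = np.zeros((size, size))
    ctsb = np.zeros((size, size))
    labels = np.zeros((size, size), dtype=np.int32)
    foot = _disk_mask(cell_radius_px)
    foot_area = int(foot.sum())
    punct = _disk_mask(vesicle_radius_px)
    punct_area = int(punct.sum())
    rows = []
    for i in range(n_cells):
        gr, gc = divmod(i, per_side)
        cy = pitch // 2 + gr * pitch + rng.uniform(-2, 2)
        cx = pitch // 2 + gc * pitch + rng.uniform(-2, 2)
        lab = np.zeros_like(labels)
        _add_patch(lab, cy, cx, foot.astype(np.int32))
        labels[lab > 0] = i + 1
        # place puncta with min separation so detection is well-posed
        k = int(rng.poisson(vesicle_rate))
        placed: List[Tuple[float, float]] = []
        attempts = 0
        while len(placed) < k and attempts < 200 * max(k, 1):
            attempts += 1
            ang = rng.uniform(0, 2 * np.pi)
            rad = (cell_radius_px - vesicle_radius_px - 1) * math.sqrt(rng.uniform())
            py, px = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
            if all((py - q[0])**2 + (px - q[1])**2 >= (2.5 * vesicle_radius_px)**2
                   for q in placed):
                placed.append((py, px))
        k = len(placed)
        lyso_per_punctum = puncta_amplitude
        ctsb_in_puncta = (1 - translocated_frac) * ctsb_total
        for py, px in placed:
            _add_patch(lyso, py, px, punct * lyso_per_punctum)
            _add_patch(ctsb, py, px,
                       punct * (ctsb_in_puncta / max(k, 1) / punct_area))
        _add_patch(ctsb, cy, cx,
                   foot * (translocated_frac * ctsb_total / foot_area))
        rows.append((i + 1, cy, cx, k, translocated_frac))
    noise = OpticsConfig(background=background, read_noise_sd=read_noise_sd)
    out_lyso = _finalize(lyso, noise, rng)
    out_ctsb = _finalize(ctsb, noise, rng)
    truth = pd.DataFrame(rows, columns=["cell_id", "row", "col",
                                        "puncta_count", "translocated_frac"])
    return OrganelleSim(lyso=out_lyso, ctsb=out_ctsb, cell_labels=labels,
                        truth=truth)


# --------------------------------------------------------------------------
# spheroid stacks
# --------------------------------------------------------------------------


def simulate_spheroid_stack(n_slices: int = 50,
                            apoptotic_frac: float = 0.0,
                            size: int = 512,
                            radius_px: float = 170.0,
                            cells_per_midplane: int = 180,
                            nucleus_radius_px: float = 6.0,
                            casp3_amplitude: float = 3000.0,
                            seed: int = 0) -> SpheroidStack:
    """Disk-cross-section spheroid z-stack with mid-plane apoptosis truth.

    Each slice holds nuclei inside the sphere's circular cross-section; at
    the mid-plane an exact ``round(apoptotic_frac * n)`` subset carries
    cleaved-caspase-3 signal over the cell footprint.
    """
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    if not 0 <= apoptotic_frac <= 1:
        raise ValueError("apoptotic_frac must be in [0,1]")
    rng = np.random.default_rng(seed)
    optics = OpticsConfig(field_size_px=size)
    nuclei = np.zeros((n_slices, size, size), dtype=np.uint16)
    casp3 = np.zeros((n_slices, size, size), dtype=np.uint16)
    center = (size / 2.0, size / 2.0)
    mid = n_slices // 2
    half_span = (n_slices - 1) / 2.0
    mid_cells = pd.DataFrame()
    true_frac = 0.0
    foot = _disk_mask(nucleus_radius_px + optics.ring_px)
    for z in range(n_slices):
        rel = (z - mid) / max(half_span, 1)
        r_k = radius_px * math.sqrt(max(1 - rel**2, 0.0))
        n_z = int(round(cells_per_midplane * (r_k / radius_px) ** 2))
        acc_n = np.zeros((size, size))
        acc_c = np.zeros((size, size))
        rows = []
        min_sep = optics.min_sep_factor * 2 * nucleus_radius_px
        pts: List[Tuple[float, float]] = []
        attempts = 0
        while len(pts) < n_z and attempts < 400 * max(n_z, 1):
            attempts += 1
            ang = rng.uniform(0, 2 * np.pi)
            rad = r_k * math.sqrt(rng.uniform())
            py = center[0] + rad * math.sin(ang)
            px = center[1] + rad * math.cos(ang)
            if all((py - q[0])**2 + (px - q[1])**2 >= min_sep**2 for q in pts):
                pts.append((py, px))
        n_z = len(pts)
        flags = np.zeros(n_z, dtype=bool)
        if z == mid and n_z:
            k = int(round(apoptotic_frac * n_z))
            flags[rng.choice(n_z, size=k, replace=False)] = True
            true_frac = k / n_z
        for (py, px), apo in zip(pts, flags):
            amp = float(optics.hoechst.sample(rng, 1)[0])
            _add_patch(acc_n, py, px, _gaussian_patch(nucleus_radius_px, amp))
            if apo:
                _add_patch(acc_c, py, px, foot * casp3_amplitude)
            rows.append((py, px, bool(apo)))
        nuclei[z] = _finalize(acc_n, optics, rng)
        casp3[z] = _finalize(acc_c, optics, rng)
        if z == mid:
            mid_cells = pd.DataFrame(rows, columns=["row", "col", "apoptotic"])
    return SpheroidStack(nuclei=nuclei, casp3=casp3, center=center,
                         radius_px=radius_px,
                         true_midplane_apoptotic_frac=true_frac,
                         midplane_cells=mid_cells)
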