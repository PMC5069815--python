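"""Per-cell mode-of-action readouts.

Quantifies the organelle phenotypes of the follow-up study: lysosomal puncta
(count, size, intensity) from the LysoTracker channel, cathepsin-B
lysosome-to-cytosol translocation, diffuse nuclear channel intensities
(gamma-H2AX, EdU, ROS, TMRM), caspase-3/7 fold activation from plate-reader
lysate readings, and the apoptotic-cell fraction at a spheroid's mid-plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .models import SpheroidStack
from .segmentation import SegmentationParams, detect_nuclei

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PunctaParams:
    """Laplacian-of-Gaussian blob detection settings for lysosomal puncta."""

    min_radius_px: float = 1.0
    max_radius_px: float = 4.0
    intensity_floor: float = 200.0  # LoG response threshold scale (image units)
    overlap: float = 0.3


def image_background(image: np.ndarray, cell_labels: np.ndarray) -> float:
    """Per-image background: median intensity outside all cell footprints."""
    outside = np.asarray(image, dtype=float)[cell_labels == 0]
    return float(np.median(outside)) if outside.size else 0.0


def detect_puncta(lyso_image: np.ndarray, cell_labels: np.ndarray,
                  params: Optional[PunctaParams] = None
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Detect LysoTracker puncta and assign them to cells.

    Returns ``(puncta, per_cell)``: one row per punctum (row, col, radius_px,
    cell_id) and one row per cell with ``puncta_count``,
    ``mean_puncta_area_px`` and background-subtracted
    ``total_lyso_intensity`` over the cell footprint.  A punctum belongs to
    the footprint containing its centroid; orphans (background centroid) are
    dropped and logged.
    """
    if cell_labels is None:
        raise ValueError("cell footprints are required")
    params = params or PunctaParams()
    img = np.asarray(lyso_image, dtype=float)
    bg = image_background(img, cell_labels)
    sub = np.clip(img - bg, 0, None)
    scale = max(sub.max(), 1.0)
    blobs = blob_log(sub / scale,
                     min_sigma=params.min_radius_px / np.sqrt(2),
                     max_sigma=params.max_radius_px / np.sqrt(2),
                     num_sigma=5,
                     threshold=params.intensity_floor / scale,
                     overlap=params.overlap)
    rows = []
    n_orphan = 0
    for r, c, sigma in blobs:
        lab = int(cell_labels[int(round(r)), int(round(c))])
        if lab == 0:
            n_orphan += 1
            continue
        rows.append((r, c, float(sigma * np.sqrt(2)), lab))
    if n_orphan:
        logger.info("detect_puncta: dropped %d orphan puncta", n_orphan)
    puncta = pd.DataFrame(rows, columns=["row", "col", "radius_px", "cell_id"])
    ids = np.unique(cell_labels[cell_labels > 0])
    tot = ndi.sum_labels(sub, labels=cell_labels, index=ids)
    per_cell = pd.DataFrame({"cell_id": ids.astype(int),
                             "total_lyso_intensity": tot})
    if len(puncta):
        grp = puncta.groupby("cell_id")
        counts = grp.size()
        areas = grp["radius_px"].apply(lambda r: float(np.mean(np.pi * r**2)))
    else:
        counts = pd.Series(dtype=float)
        areas = pd.Series(dtype=float)
    per_cell["puncta_count"] = per_cell["cell_id"].map(counts).fillna(0).astype(int)
    per_cell["mean_puncta_area_px"] = per_cell["cell_id"].map(areas)
    return puncta, per_cell


def puncta_mask_from_detections(puncta: pd.DataFrame, shape: Tuple[int, int]
                                ) -> np.ndarray:
    """Rasterize detected puncta into a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for p in puncta.itertuples(index=False):
        mask |= (yy - p.row) ** 2 + (xx - p.col) ** 2 <= p.radius_px**2
    return mask


def translocation_index(ctsb_image: np.ndarray, puncta_mask: np.ndarray,
                        cell_footprint: np.ndarray,
                        background: Optional[float] = None) -> float:
    """Fraction of a cell's cathepsin-B signal outside its lysosomal puncta.

    index = 1 - I_puncta / I_footprint on background-subtracted intensity,
    clipped to [0, 1]; 0 means fully punctate (lysosomal), 1 fully diffuse
    (cytosolic).  Scale-invariant: multiplying the channel by any positive
    constant (with the background measured on the scaled image) leaves it
    unchanged.  Raises on a cell with no signal above background.
    """
    img = np.asarray(ctsb_image, dtype=float)
    foot = np.asarray(cell_footprint, dtype=bool)
    if background is None:
        background = float(np.median(img[~foot])) if (~foot).any() else 0.0
    sub = np.clip(img - background, 0, None)
    total = float(sub[foot].sum())
    if total <= 0:
        raise ValueError("cell has zero total cathepsin-B signal; excluded")
    inside = float(sub[np.asarray(puncta_mask, dtype=bool) & foot].sum())
    return float(np.clip(1.0 - inside / total, 0.0, 1.0))


def translocation_table(ctsb_image: np.ndarray, puncta_mask: np.ndarray,
                        cell_labels: np.ndarray) -> pd.DataFrame:
    """Per-cell translocation indices; cells without signal are logged."""
    bg = image_background(ctsb_image, cell_labels)
    rows = []
    for lab in np.unique(cell_labels[cell_labels > 0]):
        foot = cell_labels == lab
        try:
            idx = translocation_index(ctsb_image, puncta_mask, foot, bg)
        except ValueError:
            logger.info("translocation: cell %d excluded (no signal)", lab)
            continue
        rows.append((int(lab), idx))
    return pd.DataFrame(rows, columns=["cell_id", "translocation_index"])


def nuclear_intensity_stats(channel_image: np.ndarray,
                            labels: np.ndarray,
                            condition: str = "",
                            ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mean per-cell channel intensity over a label map, with summaries.

    Used for diffuse nuclear markers (gamma-H2AX over nucleus labels) and,
    with footprint labels, for cytosolic/mitochondrial dyes (ROS, TMRM).
    Returns ``(per_cell, summary)`` where the summary carries n, mean and a
    two-pass SD.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return (pd.DataFrame(columns=["cell_id", "mean_intensity"]),
                pd.DataFrame(columns=["condition", "n", "mean", "sd"]))
    means = ndi.mean(np.asarray(channel_image, dtype=float),
                     labels=labels, index=ids)
    per_cell = pd.DataFrame({"cell_id": ids.astype(int),
                             "mean_intensity": means})
    summary = summarize_condition(per_cell["mean_intensity"], condition)
    return per_cell, summary


def summarize_condition(values: Sequence[float], condition: str = ""
                        ) -> pd.DataFrame:
    v = np.asarray(list(values), dtype=float)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return pd.DataFrame([{"condition": condition, "n": int(v.size),
                          "mean": float(v.mean()) if v.size else np.nan,
                          "sd": sd}])


def positive_fraction(values: Sequence[float],
                      min_separation_ratio: float = 3.0,
                      abs_floor: Optional[float] = None) -> float:
    """Fraction of cells above an Otsu cut on per-cell intensities.

    Used for EdU-positive and cleaved-caspase-3-positive fractions.  When the
    distribution is effectively unimodal (max/min below
    ``min_separation_ratio``) the Otsu split is meaningless; the cells are
    then compared against ``abs_floor`` instead (all-negative when no floor
    is given and the values sit low, all-positive when they sit high is
    decided by the floor).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no cells to classify")
    vmax, vmin = float(v.max()), float(max(v.min(), 1e-9))
    if vmax / vmin < min_separation_ratio:
        if abs_floor is None:
            raise ValueError("unimodal intensity distribution and no "
                             "absolute floor configured")
        return float((v > abs_floor).mean())
    cut = threshold_otsu(v, nbins=128)
    return float((v > cut).mean())


def caspase_fold_activation(treated: Sequence[float],
                            control: Sequence[float],
                            norm_treated: Optional[Sequence[float]] = None,
                            norm_control: Optional[Sequence[float]] = None,
                            ) -> Tuple[float, float, float]:
    """Caspase-3/7 activity fold change with a two-sample t-test.

    Readings are plate-reader absorbances per lysate, optionally divided by
    per-lysate protein normalization factors.  Returns
    ``(fold, t_statistic, p_value)``.
    """
    t_arr = np.asarray(list(treated), dtype=float)
    c_arr = np.asarray(list(control), dtype=float)
    if t_arr.size < 3 or c_arr.size < 3:
        raise ValueError("need >= 3 readings per arm")
    if norm_treated is not None:
        t_arr = t_arr / np.asarray(list(norm_treated), dtype=float)
    if norm_control is not None:
        c_arr = c_arr / np.asarray(list(norm_control), dtype=float)
    if c_arr.mean() <= 0:
        raise ValueError("control mean must be > 0")
    fold = float(t_arr.mean() / c_arr.mean())
    if np.allclose(t_arr.std(), 0) and np.allclose(c_arr.std(), 0):
        tt, p = (0.0, 1.0) if np.allclose(t_arr.mean(), c_arr.mean()) \
            else (np.inf, 0.0)
    else:
        tt, p = stats.ttest_ind(t_arr, c_arr, equal_var=True)
    return fold, float(tt), float(p)


def analyze_spheroid_midplane(stack: SpheroidStack,
                              seg_params: Optional[SegmentationParams] = None,
                              ring_px: int = 4,
                              abs_floor: Optional[float] = None
                              ) -> Tuple[Optional[float], pd.DataFrame]:
    """Apoptotic (cleaved-caspase-3-positive) cell fraction at the mid-plane.

    Takes slice floor(n_slices/2), segments nuclei, measures per-cell
    caspase-3 over the nucleus-plus-ring footprint, and calls positives by
    an Otsu cut (absolute-floor fallback for all-negative / all-positive
    slices).  Returns ``(fraction, per_cell)``; the fraction is None when no
    cells are found.
    """
    if stack.n_slices < 3:
        raise ValueError("need >= 3 slices")
    mid = stack.midplane_index
    nuc_img = stack.nuclei[mid]
    casp_img = stack.casp3[mid].astype(float)
    labels = detect_nuclei(nuc_img, seg_params)
    if labels.max() == 0:
        logger.warning("spheroid mid-plane has no segmented cells")
        return None, pd.DataFrame(columns=["cell_id", "casp3_mean"])
    # footprint = nucleus + ring, assigned by nearest nucleus
    nuc_mask = labels > 0
    dilated = ndi.binary_dilation(nuc_mask, structure=disk(ring_px))
    _, (ir, ic) = ndi.distance_transform_edt(~nuc_mask, return_indices=True)
    foot_labels = np.where(dilated, np.where(nuc_mask, labels, labels[ir, ic]), 0)
    ids = np.unique(foot_labels[foot_labels > 0])
    means = ndi.mean(casp_img, labels=foot_labels, index=ids)
    per_cell = pd.DataFrame({"cell_id": ids.astype(int), "casp3_mean": means})
    if abs_floor is None:
        bg = image_background(casp_img, foot_labels)
        abs_floor = 3.0 * max(bg, 1.0)
    frac = positive_fraction(per_cell["casp3_mean"], abs_floor=abs_floor)
    return frac, per_cell
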