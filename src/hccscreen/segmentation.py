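"""Nuclei detection, per-cell marker measurement and two-marker classification.

Cells are classified from CHALV1 and AFP immunofluorescence: double-positive
cells are called HCC, double-negative cells hepatocyte, single-positive cells
ambiguous (excluded from both population counts so that boundary cells never
inflate either denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops_table
from skimage.morphology import disk
from skimage.segmentation import watershed

LABEL_HCC = "HCC"
LABEL_HEPATOCYTE = "HEPATOCYTE"
LABEL_AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class SegmentationParams:
    """Nuclei-detection knobs.

    smoothing_sigma : Gaussian pre-smoothing, px.
    min_area_px : discard labels smaller than this; defaults to the area of a
        disk of half the expected mean nucleus radius.
    peak_min_distance : minimum separation of watershed seeds, px.
    ring_px : width of the cytoplasmic ring (nucleus dilation) used for
        CHALV1/AFP measurement.
    """

    smoothing_sigma: float = 2.0
    expected_radius_px: float = 6.0
    min_area_px: Optional[int] = None
    peak_min_distance: Optional[int] = None
    ring_px: int = 4

    @property
    def resolved_min_area(self) -> int:
        if self.min_area_px is not None:
            return self.min_area_px
        return max(4, int(np.pi * (self.expected_radius_px / 2) ** 2))

    @property
    def resolved_peak_distance(self) -> int:
        if self.peak_min_distance is not None:
            return self.peak_min_distance
        return max(2, int(round(0.8 * self.expected_radius_px)))


def detect_nuclei(hoechst: np.ndarray,
                  params: Optional[SegmentationParams] = None) -> np.ndarray:
    """Label nuclei in a Hoechst image.

    Gaussian smoothing, global Otsu threshold, then distance-transform
    watershed to split touching nuclei; regions below the minimum area are
    dropped and labels compacted.  The Otsu split runs on log intensity:
    fluorescent nuclei span a wide dynamic range against a dim background,
    and a linear-domain split sits so high that small, dim nuclei fall under
    the minimum-area filter.  A constant image yields zero labels.  Label
    order follows scan order of the seed maxima, so repeated runs are
    identical.
    """
    params = params or SegmentationParams()
    img = np.asarray(hoechst, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_nuclei expects a single 2-D channel")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    mask = smooth > np.exp(threshold_otsu(np.log(smooth + 1.0)))
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=params.resolved_peak_distance,
                           labels=mask, exclude_border=False)
    seeds = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    labels = watershed(-dist, markers=seeds, mask=mask)
    # drop small regions, relabel consecutively (lowest label wins ordering)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= params.resolved_min_area]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1)
    return lut[labels]


def measure_markers(label_map: np.ndarray,
                    channel_images: Dict[str, np.ndarray],
                    ring_px: int = 4) -> pd.DataFrame:
    """Per-label mean intensities over the nucleus mask and the dilation ring.

    Returns one row per label with columns ``cell_id, centroid_row,
    centroid_col, nucleus_area_px`` and, per channel, ``<ch>_nucleus`` and
    ``<ch>_ring``.
    """
    label_map = np.asarray(label_map)
    for name, img in channel_images.items():
        if img.shape != label_map.shape:
            raise ValueError(f"channel {name!r} shape {img.shape} does not "
                             f"match label map {label_map.shape}")
    n = int(label_map.max())
    if n == 0:
        cols = ["cell_id", "centroid_row", "centroid_col", "nucleus_area_px"]
        for ch in channel_images:
            cols += [f"{ch}_nucleus", f"{ch}_ring"]
        return pd.DataFrame(columns=cols)
    props = regionprops_table(label_map, properties=("label", "area", "centroid"))
    out = pd.DataFrame({
        "cell_id": props["label"].astype(int),
        "centroid_row": props["centroid-0"],
        "centroid_col": props["centroid-1"],
        "nucleus_area_px": props["area"].astype(int),
    })
    # ring label map: dilate each nucleus, assign ring pixels to the nearest
    # nucleus (by EDT index), excluding all nucleus pixels
    nuc_mask = label_map > 0
    dilated = ndi.binary_dilation(nuc_mask, structure=disk(ring_px))
    _, (ir, ic) = ndi.distance_transform_edt(~nuc_mask, return_indices=True)
    ring_labels = np.where(dilated & ~nuc_mask, label_map[ir, ic], 0)
    idx = np.arange(1, n + 1)
    for ch, img in channel_images.items():
        img = np.asarray(img, dtype=float)
        out[f"{ch}_nucleus"] = ndi.mean(img, labels=label_map, index=idx)
        ring_mean = ndi.mean(img, labels=ring_labels, index=idx)
        # a nucleus flush against the border can have an empty ring
        out[f"{ch}_ring"] = np.nan_to_num(ring_mean, nan=0.0)
    return out


@dataclass(frozen=True)
class ClassThresholds:
    """Per-marker intensity cutoffs and how they were obtained."""

    chalv1: float
    afp: float
    method: str = "fixed"  # or "otsu_on_controls"

    def __post_init__(self):
        if self.chalv1 <= 0 or self.afp <= 0:
            raise ValueError("thresholds must be > 0")


def derive_thresholds_from_controls(control_features: pd.DataFrame,
                                    markers: Tuple[str, str] = ("chalv1", "afp"),
                                    intensity_suffix: str = "_nucleus",
                                    fallback: Optional[ClassThresholds] = None,
                                    min_cells: int = 50,
                                    valley_ratio: float = 0.7,
                                    bins: int = 64) -> ClassThresholds:
    """Otsu split of pooled negative-control intensities, per marker.

    The split runs on log-intensity (marker distributions are log-normal).
    When the pooled distribution is unimodal — the histogram valley between
    the two Otsu classes is not deep enough (valley count > ``valley_ratio``
    times the smaller mode) — the configured fixed cutoffs are returned
    instead.
    """
    if len(control_features) < min_cells:
        raise ValueError(
            f"need >= {min_cells} pooled control cells to derive thresholds "
            f"(got {len(control_features)})")
    cuts = {}
    for m in markers:
        col = f"{m}{intensity_suffix}"
        if col not in control_features:
            raise ValueError(f"missing marker column {col!r}")
        vals = np.log(np.clip(control_features[col].to_numpy(float), 1e-9, None))
        t = threshold_otsu(vals, nbins=bins)
        hist, edges = np.histogram(vals, bins=bins)
        centers = (edges[:-1] + edges[1:]) / 2
        lo_peak = hist[centers <= t].max(initial=0)
        hi_peak = hist[centers > t].max(initial=0)
        in_valley = hist[np.abs(centers - t) <= (edges[1] - edges[0]) * 2]
        valley = int(in_valley.min()) if in_valley.size else np.inf
        bimodal = (lo_peak > 0 and hi_peak > 0
                   and valley <= valley_ratio * min(lo_peak, hi_peak))
        if not bimodal:
            if fallback is None:
                raise ValueError(
                    f"marker {m!r} control distribution is unimodal and no "
                    "fixed fallback thresholds are configured")
            return ClassThresholds(chalv1=fallback.chalv1, afp=fallback.afp,
                                   method="fixed")
        cuts[m] = float(np.exp(t))
    return ClassThresholds(chalv1=cuts[markers[0]], afp=cuts[markers[1]],
                           method="otsu_on_controls")


def classify_cells(features: pd.DataFrame, thresholds: ClassThresholds,
                   intensity_suffix: str = "_nucleus"
                   ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Assign HCC / HEPATOCYTE / AMBIGUOUS labels from the two markers.

    HCC iff both CHALV1 and AFP exceed their cutoffs; hepatocyte iff both are
    at or below; anything single-positive is ambiguous and excluded from both
    population counts.

    Classification defaults to the nucleus-mask means: both markers cover the
    whole cell footprint, and the nucleus mask always sits inside it, whereas
    the dilation ring of a generously segmented nucleus spills into
    background and dilutes both markers at once for small, dim cells.
    """
    for m in ("chalv1", "afp"):
        if f"{m}{intensity_suffix}" not in features:
            raise ValueError(f"missing marker column {m}{intensity_suffix!r}")
    out = features.copy()
    ch = out[f"chalv1{intensity_suffix}"].to_numpy(float)
    af = out[f"afp{intensity_suffix}"].to_numpy(float)
    hi = (ch > thresholds.chalv1) & (af > thresholds.afp)
    lo = (ch <= thresholds.chalv1) & (af <= thresholds.afp)
    out["class_label"] = np.where(hi, LABEL_HCC,
                                  np.where(lo, LABEL_HEPATOCYTE, LABEL_AMBIGUOUS))
    counts = {
        LABEL_HCC: int(hi.sum()),
        LABEL_HEPATOCYTE: int(lo.sum()),
        LABEL_AMBIGUOUS: int(len(out) - hi.sum() - lo.sum()),
    }
    return out, counts


def qc_well(features: pd.DataFrame, min_cells: int = 100) -> Tuple[bool, str]:
    """Well QC: pass only when strictly more than ``min_cells`` cells."""
    n = len(features)
    if n > min_cells:
        return True, f"{n} cells"
    return False, f"only {n} cells (need > {min_cells})"


def segment_well(images: Dict[Tuple[int, str], np.ndarray],
                 params: Optional[SegmentationParams] = None) -> pd.DataFrame:
    """Run detection + measurement on every field of one well.

    ``images`` maps (field, channel) to arrays; the Hoechst channel drives
    segmentation and every other channel is measured per cell.  Returns the
    per-well cell table with a ``field`` column.
    """
    params = params or SegmentationParams()
    fields = sorted({f for f, _ in images})
    tables: List[pd.DataFrame] = []
    for f in fields:
        chans = {ch: img for (ff, ch), img in images.items() if ff == f}
        if "hoechst" not in chans:
            raise ValueError(f"field {f} has no hoechst channel")
        labels = detect_nuclei(chans["hoechst"], params)
        feats = measure_markers(labels,
                                {k: v for k, v in chans.items() if k != "hoechst"},
                                ring_px=params.ring_px)
        feats.insert(0, "field", f)
        tables.append(feats)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)
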