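"""Dual-population inhibition, plate Z' and the dual-threshold hit rule.

A compound is a pilot-screen hit when it inhibits the HCC population by
strictly more than 50% while inhibiting the hepatocyte population by strictly
less than 20%, both measured as image-based cell-count reductions relative to
the plate's DMSO wells.  Plate quality is gated on the Z'-factor
Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n| computed on per-well HCC counts
of the sorafenib (positive) and DMSO (negative) control wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_TEST, WellRecord
from .segmentation import (
    LABEL_AMBIGUOUS,
    LABEL_HCC,
    LABEL_HEPATOCYTE,
    ClassThresholds,
    SegmentationParams,
    classify_cells,
    derive_thresholds_from_controls,
    qc_well,
    segment_well,
)


class AssayWindowError(RuntimeError):
    """Raised when controls give no usable assay window."""


def percent_inhibition(count: float, negative_control_counts: Sequence[float]
                       ) -> float:
    """100 * (1 - count / mean(negative controls)); negative = stimulation."""
    controls = np.asarray(list(negative_control_counts), dtype=float)
    if controls.size < 3:
        raise ValueError("need >= 3 QC-passing negative-control wells")
    mean = controls.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("negative-control mean is zero or undefined")
    return float(100.0 * (1.0 - count / mean))


def compute_zprime(positive_values: Sequence[float],
                   negative_values: Sequence[float]) -> float:
    """Z' = 1 - 3(sd_p + sd_n)/|mean_p - mean_n|; always <= 1."""
    pos = np.asarray(list(positive_values), dtype=float)
    neg = np.asarray(list(negative_values), dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise AssayWindowError("no assay window: need >= 2 wells per control arm")
    window = abs(pos.mean() - neg.mean())
    if window == 0:
        raise AssayWindowError("no assay window: control means are equal")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / window)


def call_hits(compound_table: pd.DataFrame,
              huh7_min_inhib: float = 50.0,
              fa2n4_max_inhib: float = 20.0) -> pd.DataFrame:
    """Apply the strict dual-threshold hit rule to per-compound mean inhibitions.

    Expects columns ``compound, hcc_inhibition_pct, hep_inhibition_pct``
    (already averaged over replicate wells).  Both thresholds are strict, so
    a compound sitting exactly on either boundary is not a hit.
    """
    out = compound_table.copy()
    out["hit"] = ((out["hcc_inhibition_pct"] > huh7_min_inhib)
                  & (out["hep_inhibition_pct"] < fa2n4_max_inhib))
    return out


@dataclass
class ScreenResult:
    """Pilot-screen output: per-well and per-compound tables plus plate QC."""

    wells: pd.DataFrame
    compounds: pd.DataFrame
    zprime: float
    thresholds: ClassThresholds
    qc_excluded: List[str] = field(default_factory=list)
    aborted: bool = False
    abort_reason: str = ""
    report: str = ""

    @property
    def hits(self) -> List[str]:
        if self.aborted or self.compounds.empty:
            return []
        return sorted(self.compounds.loc[self.compounds["hit"], "compound"])


def _classify_plate(records: Dict[str, WellRecord],
                    layout: pd.DataFrame,
                    seg_params: SegmentationParams,
                    fixed_thresholds: Optional[ClassThresholds],
                    min_cells: int) -> Tuple[pd.DataFrame, ClassThresholds, List[str]]:
    # segment everything once
    for rec in records.values():
        if rec.cells is None:
            rec.cells = segment_well(rec.images, seg_params)
    neg_wells = layout.loc[layout["role"] == ROLE_NEGATIVE, "well"]
    pooled = pd.concat(
        [records[w].cells for w in neg_wells if w in records and
         records[w].cells is not None and len(records[w].cells)],
        ignore_index=True) if len(neg_wells) else pd.DataFrame()
    if pooled.empty:
        raise AssayWindowError("no assay window: no negative-control cells")
    thresholds = derive_thresholds_from_controls(
        pooled, fallback=fixed_thresholds)
    rows = []
    excluded: List[str] = []
    for entry in layout.itertuples(index=False):
        rec = records.get(entry.well)
        if rec is None:
            continue
        feats, counts = classify_cells(rec.cells, thresholds)
        rec.cells = feats
        passed, reason = qc_well(feats, min_cells=min_cells)
        if not passed:
            excluded.append(f"{entry.well}: {reason}")
        rows.append({
            "plate": entry.plate, "well": entry.well, "role": entry.role,
            "compound": entry.compound, "dose_M": entry.dose_M,
            "replicate": entry.replicate, "n_cells": len(feats),
            "n_hcc": counts[LABEL_HCC], "n_hep": counts[LABEL_HEPATOCYTE],
            "n_ambiguous": counts[LABEL_AMBIGUOUS], "qc_pass": passed,
        })
    return pd.DataFrame(rows), thresholds, excluded


def run_pilot_screen(records: Dict[str, WellRecord],
                     layout: pd.DataFrame,
                     seg_params: Optional[SegmentationParams] = None,
                     fixed_thresholds: Optional[ClassThresholds] = None,
                     min_cells: int = 100,
                     zprime_gate: float = 0.5,
                     huh7_min_inhib: float = 50.0,
                     fa2n4_max_inhib: float = 20.0,
                     replicate_disagreement_pp: float = 30.0) -> ScreenResult:
    """End-to-end pilot screen: segment, classify, Z'-gate, inhibition, hits.

    ``records`` maps well name to a :class:`WellRecord` holding field images
    (or pre-computed cell tables).  The result is deterministic given the
    inputs.  When plate Z' falls below the gate the screen is aborted: the
    per-well table and report are still produced, but no hits are called.
    """
    seg_params = seg_params or SegmentationParams()
    wells, thresholds, excluded = _classify_plate(
        records, layout, seg_params, fixed_thresholds, min_cells)

    ok = wells[wells["qc_pass"]]
    neg = ok[ok["role"] == ROLE_NEGATIVE]
    pos = ok[ok["role"] == ROLE_POSITIVE]
    zprime = compute_zprime(pos["n_hcc"], neg["n_hcc"])

    neg_hcc = neg["n_hcc"].to_numpy(float)
    neg_hep = neg["n_hep"].to_numpy(float)
    wells["hcc_inhibition_pct"] = [
        percent_inhibition(c, neg_hcc) if q else np.nan
        for c, q in zip(wells["n_hcc"], wells["qc_pass"])]
    wells["hep_inhibition_pct"] = [
        percent_inhibition(c, neg_hep) if q else np.nan
        for c, q in zip(wells["n_hep"], wells["qc_pass"])]

    lines = [f"plate: {wells['plate'].iloc[0] if len(wells) else '?'}",
             f"wells analyzed: {len(wells)}",
             f"thresholds: chalv1={thresholds.chalv1:.1f} "
             f"afp={thresholds.afp:.1f} ({thresholds.method})",
             f"Z' (HCC count, pos vs neg controls): {zprime:.3f}",
             f"QC-excluded wells: {len(excluded)}"]
    lines += [f"  {e}" for e in excluded]

    if zprime < zprime_gate:
        report = "\n".join(lines + [
            f"SCREEN ABORTED: Z' {zprime:.3f} below gate {zprime_gate}"])
        return ScreenResult(wells=wells, compounds=pd.DataFrame(),
                            zprime=zprime, thresholds=thresholds,
                            qc_excluded=excluded, aborted=True,
                            abort_reason=f"Z' {zprime:.3f} < gate {zprime_gate}",
                            report=report)

    test = wells[(wells["role"] == ROLE_TEST) & wells["qc_pass"]]
    dropped = (wells[(wells["role"] == ROLE_TEST) & ~wells["qc_pass"]]
               .groupby("compound").size())
    agg_rows = []
    for comp, sub in test.groupby("compound"):
        spread = sub["hcc_inhibition_pct"].max() - sub["hcc_inhibition_pct"].min()
        agg_rows.append({
            "compound": comp,
            "n_wells": len(sub),
            "hcc_inhibition_pct": sub["hcc_inhibition_pct"].mean(),
            "hep_inhibition_pct": sub["hep_inhibition_pct"].mean(),
            "replicate_disagreement": spread > replicate_disagreement_pp,
        })
    compounds = call_hits(pd.DataFrame(agg_rows), huh7_min_inhib, fa2n4_max_inhib) \
        if agg_rows else pd.DataFrame(
            columns=["compound", "n_wells", "hcc_inhibition_pct",
                     "hep_inhibition_pct", "replicate_disagreement", "hit"])

    zero_pass = sorted(set(dropped.index) - set(compounds["compound"]))
    hits = sorted(compounds.loc[compounds["hit"], "compound"]) \
        if len(compounds) else []
    lines.append(f"compounds evaluated: {len(compounds)}")
    if zero_pass:
        lines.append(f"compounds excluded (no QC-passing wells): {zero_pass}")
    flagged = sorted(compounds.loc[compounds["replicate_disagreement"],
                                   "compound"]) if len(compounds) else []
    if flagged:
        lines.append(f"replicate disagreement > {replicate_disagreement_pp} pp: "
                     f"{flagged}")
    lines.append(f"hits (> {huh7_min_inhib}% HCC and < {fa2n4_max_inhib}% "
                 f"hepatocyte inhibition): {hits}")
    return ScreenResult(wells=wells, compounds=compounds, zprime=zprime,
                        thresholds=thresholds, qc_excluded=excluded,
                        report="\n".join(lines))
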