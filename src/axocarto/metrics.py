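"""Volumetric and centerline-aware segmentation metrics.

For tubular structures a voxel-overlap Dice score under-reports topological
errors, so alongside Dice this module provides the centerline family: with
S(·) the extracted skeleton and V(·) the volume mask,

* ClPrecision = |S(P) ∩ V(G)| / |S(P)| — how much of the predicted
  centerline lies inside the true structure;
* ClRecall    = |S(G) ∩ V(P)| / |S(G)| — how much of the true centerline
  is recovered by the prediction;
* ClDice      = harmonic mean of the two.

Skeletons reuse :func:`axocarto.autolabel.skeletonize_mask` so metric and
annotation share a single centerline definition.  Empty-mask conventions:
both masks (or both skeletons) empty → perfect score 1; exactly one empty
→ 0, so predicting empty where the truth is empty is not penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autolabel import skeletonize_mask
from .synthgen import RegionTable
from .volio import LabelVolume

__all__ = [
    "MetricReport",
    "dice",
    "cl_scores",
    "region_dice_report",
    "landmark_deviation",
]


def _binary(name, m):
    m = np.asarray(m)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
        m = m.astype(bool)
    return m


def dice(pred, gt) -> float:
    """Dice score ``2|P∩G| / (|P|+|G|)``; both masks empty → 1."""
    p = _binary("pred", pred)
    g = _binary("gt", gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def cl_scores(pred, gt) -> tuple[float, float, float]:
    """Centerline scores ``(cl_dice, cl_precision, cl_recall)``.

    Skeletons are extracted from the raw masks by 3-D thinning.  If both
    skeletons are empty all three scores are 1; if exactly one is empty they
    are 0.
    """
    p = _binary("pred", pred)
    g = _binary("gt", gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    sp = skeletonize_mask(p)
    sg = skeletonize_mask(g)
    np_, ng = int(sp.sum()), int(sg.sum())
    if np_ == 0 and ng == 0:
        return 1.0, 1.0, 1.0
    if np_ == 0 or ng == 0:
        return 0.0, 0.0, 0.0
    prec = int((sp & g).sum()) / np_
    rec = int((sg & p).sum()) / ng
    cl = 0.0 if prec + rec == 0 else 2.0 * prec * rec / (prec + rec)
    return cl, prec, rec


@dataclass
class MetricReport:
    """Per-item scores plus region medians and the average of medians."""

    items: pd.DataFrame                      # columns: item, region_id, acronym, dice
    region_medians: pd.Series                # index region_id
    average_median: float
    notes: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        out = self.region_medians.rename("median_dice").to_frame()
        out.loc["average"] = self.average_median
        return out


def region_dice_report(pred_labels, gt_labels, regions: RegionTable) -> MetricReport:
    """Per-region binary Dice across one or more brains.

    ``pred_labels``/``gt_labels`` may be single :class:`LabelVolume` objects
    or equal-length lists of them (one per brain).  For each region the
    median Dice across brains is reported, plus the mean of the per-region
    medians.  Regions absent from both grids of every brain are omitted with
    a note.
    """
    if isinstance(pred_labels, LabelVolume):
        pred_labels = [pred_labels]
    if isinstance(gt_labels, LabelVolume):
        gt_labels = [gt_labels]
    if len(pred_labels) != len(gt_labels):
        raise ValueError("need as many predictions as ground-truth label volumes")
    rows = []
    notes = []
    for i, (pv, gv) in enumerate(zip(pred_labels, gt_labels)):
        if pv.shape != gv.shape:
            raise ValueError(f"brain {i}: label grids not congruent")
        for rid in regions.ids:
            p = pv.data == rid
            g = gv.data == rid
            if not p.any() and not g.any():
                continue
            rows.append({"item": i, "region_id": rid,
                         "acronym": regions.acronym(rid), "dice": dice(p, g)})
    items = pd.DataFrame(rows, columns=["item", "region_id", "acronym", "dice"])
    for rid in regions.ids:
        if rid not in set(items["region_id"]):
            notes.append(f"region {regions.acronym(rid)} ({rid}) absent from all grids; omitted")
    medians = items.groupby("region_id")["dice"].median()
    avg = float(medians.mean()) if len(medians) else float("nan")
    return MetricReport(items=items, region_medians=medians,
                        average_median=avg, notes=notes)


def landmark_deviation(a, b, spacing=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Euclidean distance in physical units (µm) between matched landmark
    pairs; returns per-landmark distances with mean and median attached as
    DataFrame attrs."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError(f"landmark lists differ in shape: {a.shape} vs {b.shape}")
    sp = np.asarray(spacing, dtype=np.float64)
    d = np.sqrt((((a - b) * sp) ** 2).sum(axis=1))
    out = pd.DataFrame({"distance_um": d})
    out.attrs["mean"] = float(d.mean()) if d.size else 0.0
    out.attrs["median"] = float(np.median(d)) if d.size else 0.0
    return out
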