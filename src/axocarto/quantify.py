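"""Region-wise axon density quantification in atlas space.

Given a binary whole-brain axon mask registered to a labeled reference and
a hierarchical region table, this module counts axon voxels per region,
reports the density (axon-voxel fraction of the region volume — both the
raw counts and the normalized densities are emitted), rolls counts up
through the region hierarchy, counts detected points (e.g., cell centroids)
per region, and renders Gaussian-smoothed density heatmap volumes with
per-view maximum-intensity projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthgen import RegionTable
from .volio import LabelVolume, Volume

__all__ = [
    "RegionDensityTable",
    "region_axon_density",
    "aggregate_hierarchy",
    "count_points_by_region",
    "density_heatmap",
    "UNKNOWN_REGION_ID",
    "OUT_OF_BOUNDS_ID",
]

UNKNOWN_REGION_ID = -1      # labels present in the grid but absent from the table
OUT_OF_BOUNDS_ID = -2       # points outside the label grid


@dataclass
class RegionDensityTable:
    """Per-region axon-voxel counts, region volumes and densities.

    ``rows`` columns: region_id, acronym, depth, region_voxels,
    axon_voxels, density (= axon_voxels / region_voxels), rolled_up.
    After :func:`aggregate_hierarchy`, parent rows carry the sums of their
    descendants plus their own voxels, with densities recomputed.
    """

    rows: pd.DataFrame

    def density(self, region_id: int) -> float:
        hit = self.rows.loc[self.rows["region_id"] == region_id, "density"]
        if hit.empty:
            raise KeyError(f"region {region_id} not in table")
        return float(hit.iloc[0])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def region_axon_density(axons: Volume, labels: LabelVolume,
                        table: RegionTable) -> RegionDensityTable:
    """Count axon voxels and region support per label (label 0 excluded).

    ``axons`` must be a binary volume congruent with ``labels``.  Labels
    not present in the table are pooled under an ``unknown`` row with a
    warning.
    """
    ax = np.asarray(axons.data)
    if ax.shape != labels.shape:
        raise ValueError(f"shape mismatch: axons {ax.shape} vs labels {labels.shape}")
    if not np.isin(np.unique(ax), (0, 1)).all():
        raise ValueError("axon volume must be binary")
    ax = ax.astype(bool)
    lab = labels.data
    max_id = int(lab.max()) if lab.size else 0
    support = np.bincount(lab.ravel(), minlength=max_id + 1)
    axcount = np.bincount(lab.ravel(), weights=ax.ravel(), minlength=max_id + 1)
    known = set(table.ids)
    rows = []
    unknown_sup = unknown_ax = 0
    for rid in range(1, max_id + 1):
        if support[rid] == 0:
            continue
        if rid in known:
            rows.append({"region_id": rid, "acronym": table.acronym(rid),
                         "depth": table.depth(rid),
                         "region_voxels": int(support[rid]),
                         "axon_voxels": int(axcount[rid])})
        else:
            unknown_sup += int(support[rid])
            unknown_ax += int(axcount[rid])
    for rid in table.ids:
        if rid <= max_id and support[rid] > 0:
            continue
        rows.append({"region_id": rid, "acronym": table.acronym(rid),
                     "depth": table.depth(rid), "region_voxels": 0, "axon_voxels": 0})
    if unknown_sup:
        warnings.warn(f"{unknown_sup} voxels carry labels absent from the region table",
                      stacklevel=2)
        rows.append({"region_id": UNKNOWN_REGION_ID, "acronym": "unknown",
                     "depth": 0, "region_voxels": unknown_sup,
                     "axon_voxels": unknown_ax})
    df = pd.DataFrame(rows, columns=["region_id", "acronym", "depth",
                                     "region_voxels", "axon_voxels"])
    df["density"] = np.where(df["region_voxels"] > 0,
                             df["axon_voxels"] / df["region_voxels"].clip(lower=1), 0.0)
    df["rolled_up"] = False
    return RegionDensityTable(df.sort_values("region_id").reset_index(drop=True))


def aggregate_hierarchy(t: RegionDensityTable, table: RegionTable) -> RegionDensityTable:
    """Sum counts bottom-up through the region forest and recompute
    densities at every node.  Idempotent: rolled-up counts are kept per
    node as own + descendant totals derived from the stored own counts."""
    df = t.rows.copy()
    own_sup = {}
    own_ax = {}
    for _, row in df.iterrows():
        rid = int(row["region_id"])
        if rid < 0:
            continue
        if row.get("rolled_up", False):
            # recover own counts by subtracting previously rolled-up children
            continue
        own_sup[rid] = int(row["region_voxels"])
        own_ax[rid] = int(row["axon_voxels"])
    if df.get("rolled_up", pd.Series(dtype=bool)).any():
        # rows are already totals; rolling up again must be the identity
        return RegionDensityTable(df)

    ids = [int(r) for r in df["region_id"] if r > 0]
    total_sup = dict(own_sup)
    total_ax = dict(own_ax)
    # children-before-parents order via depth (deepest first)
    for rid in sorted(ids, key=lambda r: -table.depth(r)):
        parent = table.parent(rid)
        if parent is not None:
            if parent not in total_sup:
                total_sup[parent] = 0
                total_ax[parent] = 0
            total_sup[parent] += total_sup.get(rid, 0)
            total_ax[parent] += total_ax.get(rid, 0)
    out = df[df["region_id"] > 0].copy()
    out["region_voxels"] = [total_sup.get(int(r), 0) for r in out["region_id"]]
    out["axon_voxels"] = [total_ax.get(int(r), 0) for r in out["region_id"]]
    out["density"] = np.where(out["region_voxels"] > 0,
                              out["axon_voxels"] / out["region_voxels"].clip(lower=1),
                              0.0)
    out["rolled_up"] = True
    unknown = df[df["region_id"] < 0]
    out = pd.concat([out, unknown], ignore_index=True)
    return RegionDensityTable(out.sort_values("region_id").reset_index(drop=True))


def count_points_by_region(points, labels: LabelVolume) -> dict[int, int]:
    """Count points per region id by direct label lookup; out-of-bounds
    points are pooled under ``OUT_OF_BOUNDS_ID`` with a warning."""
    counts: dict[int, int] = {}
    shape = labels.shape
    n_oob = 0
    for p in points:
        if isinstance(p, tuple) and len(p) == 2 and isinstance(p[0], tuple):
            p = p[0]        # (voxel, region_id) pairs from scatter_points
        voxel = tuple(int(round(c)) for c in p)
        if any(c < 0 or c >= s for c, s in zip(voxel, shape)):
            n_oob += 1
            counts[OUT_OF_BOUNDS_ID] = counts.get(OUT_OF_BOUNDS_ID, 0) + 1
            continue
        rid = int(labels.data[voxel])
        counts[rid] = counts.get(rid, 0) + 1
    if n_oob:
        warnings.warn(f"{n_oob} points fall outside the label grid", stacklevel=2)
    return counts


def density_heatmap(axons: Volume, sigma: float = 0.0):
    """Gaussian-smoothed axon density volume plus per-view maximum-intensity
    projections.  ``sigma`` is in voxels; sigma 0 returns the input density
    unchanged.  Returns ``(Volume, {"horizontal"|"coronal"|"sagittal": 2-D})``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    ax = np.asarray(axons.data, dtype=np.float64)
    smoothed = ax if sigma == 0 else ndimage.gaussian_filter(ax, sigma)
    vol = Volume(smoothed.astype(np.float32), spacing=axons.spacing)
    projections = {
        "horizontal": smoothed.max(axis=0),   # project along z
        "coronal": smoothed.max(axis=1),      # project along y
        "sagittal": smoothed.max(axis=2),     # project along x
    }
    return vol, projections
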