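"""Synthetic axon cubes, artifact cubes and phantom brains with exact truth.

The generator emulates the objects the pipeline consumes from light-sheet
microscopy at desk scale:

* **axon cubes** — branching random-walk centerline trees rasterized as
  tubes with a Gaussian radial intensity profile over a noisy background;
  the centerline voxels are the exact ground-truth skeleton and the tube
  mask the ground-truth annotation;
* **artifact cubes** — bright non-axonal structures (thick vessels,
  Gaussian bright spots, planar edge bands) whose true annotation is empty;
* **phantom brains** — an ellipsoidal "brain" containing non-overlapping
  ellipsoidal regions with distinct mean intensities, an integer label
  volume, a hierarchical region table and landmarks at region centroids,
  standing in for an atlas-annotated brain in registration and
  quantification tests.

All randomness flows from one explicit integer seed; there is no global
random state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .losses import AffineTransform, DeformationField, sample_displaced
from .volio import AnnotationCube, IntensityCube, LabelVolume, Volume

__all__ = [
    "CubePair",
    "RegionTable",
    "PhantomBrain",
    "default_region_table",
    "make_axon_cube",
    "make_artifact_cube",
    "make_phantom_brain",
    "deform_phantom",
    "scatter_points",
]

BACKGROUND_LEVEL = 100.0
NOISE_SD = 20.0


@dataclass
class CubePair:
    """An intensity cube with its binary axon annotation, optional exact
    centerline skeleton, provenance and the seed/operator chain that made it."""

    intensity: IntensityCube
    annotation: AnnotationCube
    skeleton: np.ndarray | None = None
    provenance: str = "synthetic"  # synthetic | auto_annotated | augmented
    seed: int | None = None
    chain: tuple = ()

    def __post_init__(self):
        if self.intensity.shape != self.annotation.shape:
            raise ValueError("intensity and annotation must be congruent")
        if self.skeleton is not None:
            self.skeleton = np.asarray(self.skeleton).astype(bool)
            if self.skeleton.shape != self.intensity.shape:
                raise ValueError("skeleton must be congruent with the cube")
            if (self.skeleton & ~self.annotation.data.astype(bool)).any():
                raise ValueError("skeleton must be a subset of the annotation")
        if self.provenance not in ("synthetic", "auto_annotated", "augmented"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


DEFAULT_REGIONS = [
    # six major regions
    (1, "CTX", None),
    (2, "CP", None),
    (3, "HPF", None),
    (4, "BS", None),
    (5, "CB", None),
    (6, "CBX", 5),
    # five small structures (synthetic parent links)
    (7, "act", 1),
    (8, "fr", 4),
    (9, "mtt", 4),
    (10, "Hb", 4),
    (11, "IPN", 4),
]


@dataclass
class RegionTable:
    """Hierarchical region table: rows of (region_id, acronym, parent_id).

    Ids are unique positive integers; 0 is reserved for outside-brain;
    parent links must form a forest.
    """

    rows: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.rows, columns=["region_id", "acronym", "parent_id"]).copy()
        df["region_id"] = df["region_id"].astype(int)
        if (df["region_id"] <= 0).any():
            raise ValueError("region ids must be positive (0 is outside-brain)")
        if df["region_id"].duplicated().any():
            raise ValueError("region ids must be unique")
        ids = set(df["region_id"])
        parents = {}
        for rid, pid in zip(df["region_id"], df["parent_id"]):
            pid = None if pd.isna(pid) else int(pid)
            if pid is not None and pid not in ids:
                raise ValueError(f"parent {pid} of region {rid} not in table")
            parents[rid] = pid
        # forest check: following parents must terminate
        for rid in ids:
            seen = set()
            node = rid
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle in parent links at region {rid}")
                seen.add(node)
                node = parents[node]
        self.rows = df.reset_index(drop=True)
        self._parents = parents

    @property
    def ids(self) -> list[int]:
        return list(self.rows["region_id"])

    def acronym(self, region_id: int) -> str:
        hit = self.rows.loc[self.rows["region_id"] == region_id, "acronym"]
        if hit.empty:
            raise KeyError(f"region id {region_id} not in table")
        return str(hit.iloc[0])

    def parent(self, region_id: int) -> int | None:
        return self._parents[region_id]

    def children(self, region_id: int) -> list[int]:
        return [r for r, p in self._parents.items() if p == region_id]

    def depth(self, region_id: int) -> int:
        d, node = 0, self._parents[region_id]
        while node is not None:
            d += 1
            node = self._parents[node]
        return d

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        df = pd.read_csv(path)
        return cls(df[["region_id", "acronym", "parent_id"]])


def default_region_table() -> RegionTable:
    return RegionTable(pd.DataFrame(DEFAULT_REGIONS,
                                    columns=["region_id", "acronym", "parent_id"]))


@dataclass
class PhantomBrain:
    """Synthetic brain: intensity volume, region labels, table, landmarks."""

    intensity: Volume
    labels: LabelVolume
    table: RegionTable
    landmarks: np.ndarray  # (n, 3) float voxel coordinates

    def __post_init__(self):
        if self.intensity.shape != self.labels.shape:
            raise ValueError("labels must be congruent with intensity")
        present = set(int(i) for i in np.unique(self.labels.data)) - {0}
        known = set(self.table.ids)
        if not present <= known:
            raise ValueError(f"labels {sorted(present - known)} missing from table")
        self.landmarks = np.atleast_2d(np.asarray(self.landmarks, dtype=np.float64))


# ---------------------------------------------------------------------------
# Axon cubes
# ---------------------------------------------------------------------------


def _grow_trees(extent: int, n_trees: int, rng: np.random.Generator) -> np.ndarray:
    """Rasterize branching random-walk centerlines into a boolean grid."""
    grid = np.zeros((extent,) * 3, dtype=bool)

    def draw_walk(pos: np.ndarray, direction: np.ndarray, n_steps: int, depth: int):
        for _ in range(n_steps):
            nxt = pos + direction
            if ((nxt < 1) | (nxt > extent - 2)).any():
                return
            # dense sub-steps so the digital curve stays connected
            for t in (0.34, 0.67, 1.0):
                p = np.rint(pos + t * direction).astype(int)
                grid[tuple(p)] = True
            pos = nxt
            direction = direction + rng.normal(0.0, 0.25, 3)
            direction /= max(np.linalg.norm(direction), 1e-9)
            if depth < 2 and rng.random() < 0.015:
                branch_dir = direction + rng.normal(0.0, 0.8, 3)
                branch_dir /= max(np.linalg.norm(branch_dir), 1e-9)
                draw_walk(pos.copy(), branch_dir, n_steps // 2, depth + 1)

    for _ in range(n_trees):
        start = rng.uniform(0.15 * extent, 0.85 * extent, 3)
        direction = rng.normal(0.0, 1.0, 3)
        direction /= max(np.linalg.norm(direction), 1e-9)
        draw_walk(start, direction, int(2.5 * extent), 0)
    return grid


def make_axon_cube(extent: int = 64, n_trees: int = 2, radius_vox: float = 2.0,
                   snr: float = 10.0, seed: int = 0) -> CubePair:
    """Generate a synthetic axon cube with exact skeleton and annotation.

    Centerline trees are branching random walks; the annotation is every
    voxel within ``radius_vox`` of a centerline; the intensity is
    ``peak · exp(-d²/2σ²)`` (σ tied to the tube radius, mimicking the
    light-sheet point-spread falloff) over a noisy background, with
    ``peak = snr · noise σ``.
    """
    if extent < 16:
        raise ValueError(f"extent must be >= 16, got {extent}")
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    if radius_vox < 1:
        raise ValueError(f"radius_vox must be >= 1, got {radius_vox}")
    if snr <= 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    rng = np.random.default_rng(seed)
    path = _grow_trees(extent, n_trees, rng)
    if not path.any():
        raise ValueError("generated zero axon voxels; adjust parameters")
    skeleton = skeletonize(path)  # thin rasterization clumps to 1-voxel width
    if not skeleton.any():
        skeleton = path
    dist = ndimage.distance_transform_edt(~skeleton)
    annotation = dist <= radius_vox
    sigma = max(radius_vox / 1.5, 0.8)
    peak = snr * NOISE_SD
    intensity = (BACKGROUND_LEVEL
                 + peak * np.exp(-(dist ** 2) / (2 * sigma ** 2))
                 + rng.normal(0.0, NOISE_SD, path.shape))
    data = np.clip(intensity, 0, 65535).astype(np.uint16)
    return CubePair(
        intensity=IntensityCube(data),
        annotation=AnnotationCube(annotation.astype(np.uint8)),
        skeleton=skeleton,
        provenance="synthetic",
        seed=seed,
        chain=(("make_axon_cube", extent, n_trees, radius_vox, snr, seed),),
    )


# ---------------------------------------------------------------------------
# Artifact cubes
# ---------------------------------------------------------------------------

ARTIFACT_KINDS = ("vessel", "bright_spot", "edge")


def make_artifact_cube(extent: int = 64, kind: str = "vessel", seed: int = 0) -> IntensityCube:
    """Generate a cube of non-axonal bright structure; its ground-truth
    annotation is all-zero (artifact cubes contain no axons)."""
    if extent < 16:
        raise ValueError(f"extent must be >= 16, got {extent}")
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; choose from {ARTIFACT_KINDS}")
    rng = np.random.default_rng(seed)
    img = np.full((extent,) * 3, BACKGROUND_LEVEL, dtype=np.float64)
    if kind == "vessel":
        # thick, gently curving tube — radius far above an axon's
        pos = rng.uniform(0.2 * extent, 0.8 * extent, 3)
        direction = rng.normal(0.0, 1.0, 3)
        direction /= max(np.linalg.norm(direction), 1e-9)
        centerline = np.zeros_like(img, dtype=bool)
        for _ in range(3 * extent):
            p = np.rint(pos).astype(int)
            if ((p < 0) | (p >= extent)).any():
                break
            centerline[tuple(p)] = True
            direction = direction + rng.normal(0.0, 0.08, 3)
            direction /= max(np.linalg.norm(direction), 1e-9)
            pos = pos + 0.7 * direction
        radius = max(4.0, extent / 12.0)
        dist = ndimage.distance_transform_edt(~centerline)
        img += 10.0 * NOISE_SD * np.exp(-(dist ** 2) / (2 * (radius / 1.5) ** 2))
    elif kind == "bright_spot":
        zz, yy, xx = np.indices(img.shape)
        for _ in range(rng.integers(3, 8)):
            c = rng.uniform(0.1 * extent, 0.9 * extent, 3)
            s = rng.uniform(1.5, 4.0)
            d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            img += 10.0 * NOISE_SD * np.exp(-d2 / (2 * s ** 2))
    else:  # edge: bright planar band near one face
        axis = int(rng.integers(0, 3))
        near_low = bool(rng.integers(0, 2))
        width = max(2, extent // 8)
        coord = np.indices(img.shape)[axis]
        edge_pos = width if near_low else extent - 1 - width
        img += 8.0 * NOISE_SD * np.exp(-((coord - edge_pos) ** 2) / (2 * (width / 1.2) ** 2))
    img += rng.normal(0.0, NOISE_SD, img.shape)
    data = np.clip(img, 0, 65535).astype(np.uint16)
    return IntensityCube(data, parent_id=f"artifact:{kind}:{seed}")


# ---------------------------------------------------------------------------
# Phantom brains
# ---------------------------------------------------------------------------


def make_phantom_brain(shape=(80, 114, 132), n_regions: int = 6,
                       seed: int = 0) -> PhantomBrain:
    """Build an ellipsoidal phantom brain with ``n_regions`` non-overlapping
    ellipsoidal regions, distinct per-region mean intensities, and landmarks
    at the region centroids.

    The default shape matches the coarsest level of the registration pyramid
    so registration tests run quickly.
    """
    shape = tuple(int(s) for s in shape)
    if n_regions < 2:
        raise ValueError(f"n_regions must be >= 2, got {n_regions}")
    table = default_region_table()
    if n_regions > len(table.ids):
        extra = [(i, f"R{i}", None) for i in range(max(table.ids) + 1,
                                                   max(table.ids) + 1 + n_regions - len(table.ids))]
        table = RegionTable(pd.concat([table.rows,
                                       pd.DataFrame(extra, columns=table.rows.columns)]))
    ids = table.ids[:n_regions]
    rng = np.random.default_rng(seed)

    center = np.array(shape, dtype=np.float64) / 2.0
    brain_semi = 0.44 * np.array(shape, dtype=np.float64)
    zz, yy, xx = np.indices(shape, dtype=np.float64)
    coords = np.stack([zz, yy, xx])
    brain = ((coords - center[:, None, None, None]) ** 2
             / (brain_semi[:, None, None, None] ** 2)).sum(axis=0) <= 1.0

    # region centers on a ring in the two longest axes, jittered by seed
    order = np.argsort(shape)          # shortest ... longest axis
    a1, a2 = order[-1], order[-2]
    angles = 2 * np.pi * (np.arange(n_regions) + rng.uniform(0, 1)) / n_regions
    ring = min(brain_semi[a1], brain_semi[a2]) * 0.55
    region_semi = np.full(3, max(2.5, ring * np.sin(np.pi / max(n_regions, 3)) * 0.75))
    region_semi = np.minimum(region_semi, 0.4 * brain_semi)
    if (region_semi < 2.0).any():
        raise ValueError(f"shape {shape} too small to host {n_regions} regions")

    labels = np.zeros(shape, dtype=np.int32)
    landmarks = []
    for rid, ang in zip(ids, angles):
        c = center.copy()
        c[a1] += ring * np.cos(ang)
        c[a2] += ring * np.sin(ang)
        c += rng.uniform(-1.0, 1.0, 3)
        mask = ((coords - c[:, None, None, None]) ** 2
                / (region_semi[:, None, None, None] ** 2)).sum(axis=0) <= 1.0
        mask &= brain
        if not mask.any():
            raise ValueError(f"shape {shape} too small to host {n_regions} regions")
        labels[mask] = rid
        landmarks.append(ndimage.center_of_mass(mask))

    intensity = np.full(shape, 20.0)
    intensity[brain] = 150.0
    for k, rid in enumerate(ids):
        intensity[labels == rid] = 300.0 + 120.0 * k
    intensity = ndimage.gaussian_filter(intensity, sigma=1.0)
    intensity += rng.normal(0.0, 5.0, shape)
    return PhantomBrain(
        intensity=Volume(intensity.astype(np.float32)),
        labels=LabelVolume(labels),
        table=table,
        landmarks=np.asarray(landmarks, dtype=np.float64),
    )


def deform_phantom(p: PhantomBrain, t, noise_sd: float = 0.0,
                   seed: int = 0) -> PhantomBrain:
    """Warp a phantom through an affine transform or deformation field.

    Intensity is resampled with linear interpolation, labels with nearest
    neighbor, and the landmarks are mapped through the transform (exactly
    for affines; by fixed-point inversion of the pull field otherwise).
    Additive Gaussian noise is applied to the intensity afterwards.
    """
    rng = np.random.default_rng(seed)
    shape = p.intensity.shape
    if isinstance(t, AffineTransform):
        t.require_invertible()
        inv = t.inverse()
        warped = ndimage.affine_transform(np.asarray(p.intensity.data, np.float64),
                                          inv.A, offset=inv.b, order=1, mode="nearest")
        labels = ndimage.affine_transform(p.labels.data, inv.A, offset=inv.b,
                                          order=0, mode="constant", cval=0,
                                          output=p.labels.data.dtype)
        landmarks = t.apply_points(p.landmarks)
    elif isinstance(t, DeformationField):
        if t.grid_shape != shape:
            raise ValueError("field grid must match the phantom shape")
        warped = sample_displaced(np.asarray(p.intensity.data, np.float64), t, order=1)
        labels = sample_displaced(p.labels.data.astype(np.float64), t,
                                  order=0).astype(p.labels.data.dtype)
        # invert the pull map for points: solve y + Φ(y) = lm
        landmarks = np.array(p.landmarks, dtype=np.float64)
        for _ in range(30):
            disp = np.stack([
                ndimage.map_coordinates(t.phi[c], landmarks.T, order=1, mode="nearest")
                for c in range(3)
            ], axis=1)
            landmarks = p.landmarks - disp
    else:
        raise TypeError("t must be an AffineTransform or DeformationField")
    if noise_sd > 0:
        warped = warped + rng.normal(0.0, noise_sd, shape)
    return PhantomBrain(
        intensity=Volume(warped.astype(np.float32), spacing=p.intensity.spacing),
        labels=LabelVolume(labels, spacing=p.labels.spacing),
        table=p.table,
        landmarks=landmarks,
    )


def scatter_points(labels: LabelVolume, counts: dict[int, int],
                   seed: int = 0) -> list[tuple[tuple[int, int, int], int]]:
    """Place exactly ``counts[r]`` points uniformly at random inside each
    requested region ``r``, returning (voxel, region_id) pairs."""
    rng = np.random.default_rng(seed)
    out = []
    for rid, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for region {rid}")
        idx = np.flatnonzero(labels.data == rid)
        if idx.size == 0:
            raise ValueError(f"region {rid} is empty or absent from the label volume")
        if n == 0:
            continue
        chosen = rng.choice(idx, size=n, replace=True)
        for flat in chosen:
            voxel = np.unravel_index(int(flat), labels.data.shape)
            out.append((tuple(int(v) for v in voxel), int(rid)))
    return out
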