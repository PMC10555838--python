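"""Volume and cube I/O, cube extraction, whole-brain tiling and stitching.

Conventions used throughout the package:

* arrays are 3-D with axis order ``(z, y, x)`` = (depth, height, width),
  matching the storage order of per-slice TIFF stacks;
* voxel coordinates are 0-based; ranges are half-open ``[low, low + extent)``;
* spacing is the physical voxel size in micrometres per axis.

A whole brain is tiled into fixed-size cubes (default 150 voxels per side,
the unit at which axons are annotated and segmented), per-cube predictions
are computed independently, and :func:`stitch_cubes` reassembles them into a
whole-brain volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from . import _nrrd

DEFAULT_CUBE_EXTENT = 150

__all__ = [
    "DEFAULT_CUBE_EXTENT",
    "Volume",
    "LabelVolume",
    "IntensityCube",
    "AnnotationCube",
    "CubeCoord",
    "read_volume",
    "write_volume",
    "extract_cube",
    "tile_volume",
    "stitch_cubes",
]


class VolumeFormatError(ValueError):
    """Raised when a volume on disk cannot be assembled or parsed."""


def _as_triple(value, name, cast=float):
    out = tuple(cast(v) for v in value)
    if len(out) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(out)}")
    return out


@dataclass
class Volume:
    """A whole-brain scalar intensity grid.

    Parameters
    ----------
    data
        3-D array, axis order (z, y, x).
    spacing
        Voxel size in µm per axis, same order.
    origin
        Physical offset of voxel (0, 0, 0) in µm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume(Volume):
    """Integer region-label grid; 0 is reserved for outside-brain."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.data.dtype}")

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.data)
        return ids[ids != 0]


@dataclass
class IntensityCube:
    """A cube cut out of a parent :class:`Volume`.

    ``offset`` is the voxel coordinate of the cube's low corner inside the
    parent; ``padded`` flags cubes whose requested window ran past the parent
    bounds and was zero-filled there.
    """

    data: np.ndarray
    offset: tuple[int, int, int] = (0, 0, 0)
    parent_id: str | None = None
    padded: bool = False
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D")
        if min(self.data.shape) < 1:
            raise ValueError("all cube extents must be >= 1")
        self.offset = _as_triple(self.offset, "offset", cast=int)
        self.spacing = _as_triple(self.spacing, "spacing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class AnnotationCube:
    """Binary voxel mask congruent with an :class:`IntensityCube`; 1 = axon."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("annotation data must be 3-D")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"annotation values must be in {{0,1}}, got {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class CubeCoord:
    """Half-open tile window ``[low, low + extent)`` inside a tiled volume."""

    low: tuple[int, int, int]
    extent: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, lo + ext) for lo, ext in zip(self.low, self.extent))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SUPPORTED_DTYPES = (np.uint8, np.int16, np.uint16, np.int32, np.uint32, np.float32, np.float64)


def _check_dtype(arr, path):
    if not any(arr.dtype == np.dtype(d) for d in _SUPPORTED_DTYPES):
        raise VolumeFormatError(f"{path}: unsupported dtype {arr.dtype}")
    return arr


def read_volume(path, spacing=None) -> Volume:
    """Read a volume from a multi-page TIFF, a directory of per-slice TIFFs
    (stacked in sorted filename order), or an NRRD file.

    ``spacing`` (µm per axis, (z, y, x) order) overrides any header value.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise VolumeFormatError(f"{path}: no TIFF slices found")
        slices = []
        shape = None
        for f in files:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise VolumeFormatError(f"{f}: expected a 2-D slice, got ndim={arr.ndim}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise VolumeFormatError(
                    f"{f}: slice shape {arr.shape} differs from first slice {shape}"
                )
            slices.append(arr)
        data = _check_dtype(np.stack(slices, axis=0), path)
        return Volume(data, spacing=spacing or (1.0, 1.0, 1.0))
    if not path.exists():
        raise VolumeFormatError(f"{path}: no such file")
    if path.suffix.lower() == ".nrrd":
        data, header = _nrrd.read_nrrd(path)
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected a 3-D NRRD, got ndim={data.ndim}")
        _check_dtype(data, path)
        sp = spacing or _nrrd.parse_spacings(header) or (1.0, 1.0, 1.0)
        return Volume(data, spacing=sp)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected a 3-D TIFF stack, got ndim={data.ndim}")
        _check_dtype(data, path)
        return Volume(np.ascontiguousarray(data), spacing=spacing or (1.0, 1.0, 1.0))
    raise VolumeFormatError(f"{path}: unsupported volume format {path.suffix!r}")


def write_volume(v: Volume, path, format: str | None = None) -> None:
    """Write a volume as multi-page TIFF or NRRD; readable back bit-identically."""
    path = Path(path)
    fmt = format or {".nrrd": "nrrd", ".tif": "tiff", ".tiff": "tiff"}.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format from {path.suffix!r}; pass format=")
    if fmt == "tiff":
        tifffile.imwrite(path, v.data)
    elif fmt == "nrrd":
        _nrrd.write_nrrd(path, v.data, spacing=v.spacing)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# Cube extraction / tiling / stitching
# ---------------------------------------------------------------------------


def extract_cube(v: Volume, center, extent: int = DEFAULT_CUBE_EXTENT,
                 parent_id: str | None = None) -> IntensityCube:
    """Extract a cube of side ``extent`` centred at ``center`` (voxel triple).

    Portions of the window outside the volume are zero-padded and the cube is
    flagged ``padded``; ``offset`` records the low corner in parent
    coordinates (possibly negative when padding occurs on the low side).
    """
    if extent < 1:
        raise ValueError(f"extent must be >= 1, got {extent}")
    center = _as_triple(center, "center", cast=int)
    shape = v.shape
    if any(c < 0 or c >= s for c, s in zip(center, shape)):
        raise ValueError(f"center {center} lies outside volume of shape {shape}")
    low = tuple(c - extent // 2 for c in center)
    out = np.zeros((extent,) * 3, dtype=v.data.dtype)
    src = []
    dst = []
    padded = False
    for lo, s in zip(low, shape):
        a, b = max(lo, 0), min(lo + extent, s)
        src.append(slice(a, b))
        dst.append(slice(a - lo, b - lo))
        if a != lo or b != lo + extent:
            padded = True
    out[tuple(dst)] = v.data[tuple(src)]
    return IntensityCube(out, offset=low, parent_id=parent_id, padded=padded,
                         spacing=v.spacing)


def tile_volume(shape, cube_extent: int, stride: int | None = None) -> list[CubeCoord]:
    """Tile ``shape`` with cubes of side ``cube_extent`` stepped by ``stride``.

    Every voxel is covered at least once.  The last tile along each axis is
    shifted inward so that all tiles are full-sized.  Coordinates are emitted
    in deterministic z-major (then y, then x) order.
    """
    shape = _as_triple(shape, "shape", cast=int)
    if stride is None:
        stride = cube_extent
    if not (0 < stride <= cube_extent):
        raise ValueError(f"stride must satisfy 0 < stride <= cube_extent, got {stride}")
    if any(cube_extent > s for s in shape):
        raise ValueError(f"cube_extent {cube_extent} exceeds volume shape {shape}")

    def axis_starts(n: int) -> list[int]:
        starts = list(range(0, n - cube_extent + 1, stride))
        if starts[-1] + cube_extent < n:
            starts.append(n - cube_extent)
        return starts

    zs, ys, xs = (axis_starts(s) for s in shape)
    ext = (cube_extent,) * 3
    return [CubeCoord((z, y, x), ext) for z in zs for y in ys for x in xs]


def stitch_cubes(cubes: Iterable[tuple[CubeCoord, np.ndarray]], shape,
                 blend: str = "max", spacing=(1.0, 1.0, 1.0)) -> Volume:
    """Reassemble per-cube grids into a whole volume.

    Overlapping voxels are combined by ``blend``: ``"max"`` (default — axon
    probabilities are never diluted by empty overlap) or ``"mean"``.
    Voxels touched by no cube are 0.
    """
    shape = _as_triple(shape, "shape", cast=int)
    if blend not in ("max", "mean"):
        raise ValueError(f"blend must be 'max' or 'mean', got {blend!r}")
    acc = np.zeros(shape, dtype=np.float64)
    if blend == "mean":
        count = np.zeros(shape, dtype=np.int64)
    first_dtype = None
    for coord, grid in cubes:
        grid = np.asarray(grid)
        if first_dtype is None:
            first_dtype = grid.dtype
        if tuple(grid.shape) != tuple(coord.extent):
            raise ValueError(
                f"grid shape {grid.shape} does not match coord extent {coord.extent}"
            )
        if any(lo < 0 or lo + ext > s for lo, ext, s in zip(coord.low, coord.extent, shape)):
            raise ValueError(f"coord {coord} exceeds stitched shape {shape}")
        sl = coord.slices()
        if blend == "max":
            np.maximum(acc[sl], grid, out=acc[sl])
        else:
            acc[sl] += grid
            count[sl] += 1
    if first_dtype is None:
        raise ValueError("no cubes to stitch")
    if blend == "mean":
        np.divide(acc, count, out=acc, where=count > 0)
    if np.issubdtype(first_dtype, np.integer):
        out = np.rint(acc).astype(first_dtype)
    else:
        out = acc.astype(first_dtype)
    return Volume(out, spacing=spacing)
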