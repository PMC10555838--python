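"""Data augmentation for annotated axon cubes.

Three bespoke operators simulate the variability of stained whole-brain
data — CutMix (pasting a random sub-box of an artifact cube into an axon
cube), background histogram matching that preserves annotated axon voxels,
and local contrast changes on randomly chosen axon components — plus the
standard geometric/photometric set (rotation, scaling, Gaussian noise,
blur, brightness).  :func:`augment_pool` expands an annotated pool with a
deterministic recipe: with the defaults, 100 axon cubes and 100 artifact
cubes yield more than 1,000 annotated training cubes.

Every output records the operator chain that produced it; replaying the
chain from the same sources reproduces the output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthgen import CubePair
from .volio import AnnotationCube, IntensityCube

__all__ = [
    "AugmentRecipe",
    "STANDARD_OPS",
    "cutmix",
    "histogram_match_aug",
    "local_contrast_aug",
    "standard_aug",
    "augment_pool",
    "replay_chain",
]

STANDARD_OPS = ("rotation", "scaling", "gaussian_noise", "blur", "brightness")


@dataclass
class AugmentRecipe:
    """Per-axon-cube counts of each augmentation operator and the parameter
    ranges of the standard ops.  The defaults produce 10 derived cubes per
    axon cube."""

    cutmix: int = 2
    histogram_match: int = 2
    local_contrast: int = 2
    standard: int = 4
    cutmix_frac: tuple[float, float] = (0.2, 0.5)
    contrast_range: tuple[float, float] = (0.6, 1.6)
    scale_range: tuple[float, float] = (0.8, 1.25)
    rotation_deg: tuple[float, float] = (-180.0, 180.0)
    noise_sd_range: tuple[float, float] = (5.0, 25.0)
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    brightness_range: tuple[float, float] = (0.7, 1.3)
    master_seed: int = 0

    def __post_init__(self):
        for name in ("cutmix", "histogram_match", "local_contrast", "standard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")
        if not (0 < self.cutmix_frac[0] <= self.cutmix_frac[1] < 1):
            raise ValueError("cutmix_frac must lie inside (0, 1)")
        if self.scale_range[0] <= 0 or self.contrast_range[0] <= 0:
            raise ValueError("scale and contrast ranges must be positive")

    @property
    def per_cube(self) -> int:
        return self.cutmix + self.histogram_match + self.local_contrast + self.standard


# ---------------------------------------------------------------------------
# Bespoke operators
# ---------------------------------------------------------------------------


def _random_box(shape, frac: float, rng: np.random.Generator):
    """Axis-aligned box with independently drawn per-axis extents whose
    relative volume is approximately ``frac``."""
    side = frac ** (1.0 / 3.0)
    slices = []
    for n in shape:
        ext = int(round(np.clip(rng.uniform(0.75, 1.25) * side, 0.0, 1.0) * n))
        ext = min(max(ext, 0), n)
        lo = int(rng.integers(0, n - ext + 1)) if ext < n else 0
        slices.append(slice(lo, lo + ext))
    return tuple(slices)


def cutmix(axon: CubePair, artifact: CubePair, frac: float = 0.3,
           seed: int = 0) -> CubePair:
    """Paste a random sub-box of the artifact cube into the axon cube.

    The pasted box has relative volume ≈ ``frac``; annotation voxels inside
    it are cleared (the pasted region contains no axons).
    """
    if axon.intensity.shape != artifact.intensity.shape:
        raise ValueError("axon and artifact cubes must be congruent")
    if not (0 <= frac < 1):
        raise ValueError(f"frac must lie in [0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    out_int = np.array(axon.intensity.data)
    out_ann = np.array(axon.annotation.data)
    out_skel = None if axon.skeleton is None else np.array(axon.skeleton)
    if frac > 0:
        box = _random_box(out_int.shape, frac, rng)
        out_int[box] = artifact.intensity.data[box]
        out_ann[box] = 0
        if out_skel is not None:
            out_skel[box] = False
    return CubePair(
        intensity=IntensityCube(out_int, spacing=axon.intensity.spacing),
        annotation=AnnotationCube(out_ann),
        skeleton=out_skel,
        provenance="augmented",
        seed=seed,
        chain=axon.chain + (("cutmix", frac, seed),),
    )


def histogram_match_aug(pair: CubePair, reference: IntensityCube,
                        seed: int = 0) -> CubePair:
    """Match the cube's *background* histogram to the reference cube's
    histogram through a monotone quantile mapping, leaving annotated axon
    voxels bit-identical.  The annotation is unchanged."""
    ref = np.asarray(reference.data, dtype=np.float64).ravel()
    if np.unique(ref).size < 2:
        raise ValueError("reference must contain at least 2 distinct values")
    src = np.asarray(pair.intensity.data, dtype=np.float64)
    bg = pair.annotation.data == 0
    out = np.array(pair.intensity.data)
    if bg.any():
        values = src[bg]
        # monotone mapping: source background quantiles -> reference quantiles
        src_sorted = np.sort(np.unique(values))
        src_quant = np.searchsorted(np.sort(values), src_sorted, side="right") / values.size
        ref_sorted = np.sort(ref)
        mapped = np.interp(src_quant, np.arange(1, ref.size + 1) / ref.size, ref_sorted)
        remapped = np.interp(values, src_sorted, mapped)
        if np.issubdtype(out.dtype, np.integer):
            info = np.iinfo(out.dtype)
            remapped = np.clip(np.rint(remapped), info.min, info.max)
        out[bg] = remapped.astype(out.dtype)
    return CubePair(
        intensity=IntensityCube(out, spacing=pair.intensity.spacing),
        annotation=AnnotationCube(np.array(pair.annotation.data)),
        skeleton=None if pair.skeleton is None else np.array(pair.skeleton),
        provenance="augmented",
        seed=seed,
        chain=pair.chain + (("histogram_match", getattr(reference, "parent_id", None), seed),),
    )


def local_contrast_aug(pair: CubePair, factor_range: tuple[float, float] = (0.6, 1.6),
                       seed: int = 0) -> CubePair:
    """Scale the intensity of a random subset of annotated axon components
    (26-connected) by factors drawn from ``factor_range``; everything else,
    including the annotation, is untouched."""
    lo, hi = factor_range
    if lo <= 0:
        raise ValueError("factor_range lower bound must be > 0")
    rng = np.random.default_rng(seed)
    ann = pair.annotation.data.astype(bool)
    out = np.asarray(pair.intensity.data, dtype=np.float64).copy()
    if not ann.any():
        warnings.warn("empty annotation: local contrast augmentation is a no-op",
                      stacklevel=2)
        comp_ids = np.zeros(0, dtype=int)
        labeled = np.zeros_like(pair.annotation.data, dtype=np.int32)
    else:
        labeled, n = ndimage.label(ann, structure=np.ones((3, 3, 3), dtype=bool))
        pick = rng.random(n) < 0.5
        if not pick.any():
            pick[rng.integers(0, n)] = True  # always touch at least one axon
        comp_ids = np.flatnonzero(pick) + 1
    for cid in comp_ids:
        factor = rng.uniform(lo, hi)
        sel = labeled == cid
        out[sel] *= factor
    dtype = pair.intensity.data.dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return CubePair(
        intensity=IntensityCube(out.astype(dtype), spacing=pair.intensity.spacing),
        annotation=AnnotationCube(np.array(pair.annotation.data)),
        skeleton=None if pair.skeleton is None else np.array(pair.skeleton),
        provenance="augmented",
        seed=seed,
        chain=pair.chain + (("local_contrast", factor_range, seed),),
    )


# ---------------------------------------------------------------------------
# Standard operators
# ---------------------------------------------------------------------------


def _geometric(pair: CubePair, transform) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Apply a geometric transform identically to intensity (linear) and
    annotation/skeleton (nearest, re-binarized)."""
    inten = transform(np.asarray(pair.intensity.data, np.float64), 1)
    ann = transform(pair.annotation.data.astype(np.float64), 0) > 0.5
    skel = None
    if pair.skeleton is not None:
        skel = transform(pair.skeleton.astype(np.float64), 0) > 0.5
        skel &= ann  # keep the subset invariant at interpolation borders
    return inten, ann, skel


def _fit_to_shape(arr: np.ndarray, shape, order: int) -> np.ndarray:
    """Center-crop or zero-pad ``arr`` back to ``shape``."""
    out = np.zeros(shape, dtype=arr.dtype)
    src, dst = [], []
    for n_in, n_out in zip(arr.shape, shape):
        if n_in >= n_out:
            lo = (n_in - n_out) // 2
            src.append(slice(lo, lo + n_out))
            dst.append(slice(0, n_out))
        else:
            lo = (n_out - n_in) // 2
            src.append(slice(0, n_in))
            dst.append(slice(lo, lo + n_in))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def standard_aug(pair: CubePair, op: str, params: dict | None = None,
                 seed: int = 0) -> CubePair:
    """One standard augmentation: geometric ops transform intensity and
    annotation congruently; photometric ops leave the annotation untouched.

    Parameters per op (all optional, drawn from the seed otherwise):
    ``rotation``: angle (deg), axes pair; ``scaling``: factor;
    ``gaussian_noise``: sd; ``blur``: sigma; ``brightness``: factor.
    """
    if op not in STANDARD_OPS:
        raise ValueError(f"unknown op {op!r}; choose from {STANDARD_OPS}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    shape = pair.intensity.shape
    dtype = pair.intensity.data.dtype
    skel = pair.skeleton

    if op == "rotation":
        angle = float(params.get("angle", rng.uniform(-180.0, 180.0)))
        axes = tuple(params.get("axes", (1, 2)))
        tf = lambda a, order: ndimage.rotate(a, angle, axes=axes, reshape=False,
                                             order=order, mode="constant", cval=0.0)
        inten, ann, skel = _geometric(pair, tf)
    elif op == "scaling":
        factor = float(params.get("factor", rng.uniform(0.8, 1.25)))
        if factor <= 0:
            raise ValueError("scaling factor must be > 0")
        tf = lambda a, order: _fit_to_shape(
            ndimage.zoom(a, factor, order=order, mode="constant", cval=0.0),
            shape, order)
        inten, ann, skel = _geometric(pair, tf)
    elif op == "gaussian_noise":
        sd = float(params.get("sd", rng.uniform(5.0, 25.0)))
        inten = np.asarray(pair.intensity.data, np.float64) + rng.normal(0.0, sd, shape)
        ann = pair.annotation.data.astype(bool)
    elif op == "blur":
        sigma = float(params.get("sigma", rng.uniform(0.5, 1.5)))
        inten = ndimage.gaussian_filter(np.asarray(pair.intensity.data, np.float64), sigma)
        ann = pair.annotation.data.astype(bool)
    else:  # brightness
        factor = float(params.get("factor", rng.uniform(0.7, 1.3)))
        inten = np.asarray(pair.intensity.data, np.float64) * factor
        ann = pair.annotation.data.astype(bool)

    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        inten = np.clip(np.rint(inten), info.min, info.max)
    return CubePair(
        intensity=IntensityCube(inten.astype(dtype), spacing=pair.intensity.spacing),
        annotation=AnnotationCube(ann.astype(np.uint8)),
        skeleton=skel,
        provenance="augmented",
        seed=seed,
        chain=pair.chain + ((op, tuple(sorted(params.items())), seed),),
    )


# ---------------------------------------------------------------------------
# Pool expansion
# ---------------------------------------------------------------------------


def augment_pool(axon_pairs: list[CubePair], artifact_pairs: list[CubePair],
                 recipe: AugmentRecipe | None = None) -> list[CubePair]:
    """Expand an annotated pool with the recipe's per-cube operator counts.

    The output contains the source axon pairs followed by the derived cubes
    (CutMix partners and all parameters drawn deterministically from the
    recipe's master seed), so the default recipe turns 100 axon cubes plus
    100 artifact cubes into 1,100 annotated cubes.
    """
    recipe = recipe or AugmentRecipe()
    if not axon_pairs:
        return []
    if recipe.cutmix > 0 and not artifact_pairs:
        raise ValueError("cutmix requested but the artifact pool is empty")
    rng = np.random.default_rng(recipe.master_seed)
    out: list[CubePair] = []
    if recipe.per_cube > 0:
        out.extend(axon_pairs)
    for pair in axon_pairs:
        for _ in range(recipe.cutmix):
            partner = artifact_pairs[int(rng.integers(0, len(artifact_pairs)))]
            frac = float(rng.uniform(*recipe.cutmix_frac))
            out.append(cutmix(pair, partner, frac=frac, seed=int(rng.integers(2 ** 31))))
        for _ in range(recipe.histogram_match):
            donor_pool = axon_pairs + artifact_pairs
            donor = donor_pool[int(rng.integers(0, len(donor_pool)))]
            out.append(histogram_match_aug(pair, donor.intensity,
                                           seed=int(rng.integers(2 ** 31))))
        for _ in range(recipe.local_contrast):
            out.append(local_contrast_aug(pair, recipe.contrast_range,
                                          seed=int(rng.integers(2 ** 31))))
        for _ in range(recipe.standard):
            op = STANDARD_OPS[int(rng.integers(0, len(STANDARD_OPS)))]
            out.append(standard_aug(pair, op, seed=int(rng.integers(2 ** 31))))
    return out


def replay_chain(sources: dict, chain: tuple) -> CubePair:
    """Re-run a recorded operator chain from its source cubes.

    ``sources`` maps the chain's first entry (a generator call tuple) or
    names used by the operators (``"pair"``, ``"artifact"``, ``"reference"``)
    to the concrete inputs.  Bit-exact reproduction of the chained output.
    """
    pair = sources["pair"]
    for step in chain:
        name = step[0]
        if name in ("make_axon_cube", "annotate_axon_cube", "annotate_artifact_cube"):
            continue  # provenance of the source itself
        if name == "cutmix":
            _, frac, seed = step
            pair = cutmix(pair, sources["artifact"], frac=frac, seed=seed)
        elif name == "histogram_match":
            _, _ref_id, seed = step
            pair = histogram_match_aug(pair, sources["reference"], seed=seed)
        elif name == "local_contrast":
            _, factor_range, seed = step
            pair = local_contrast_aug(pair, factor_range, seed=seed)
        elif name in STANDARD_OPS:
            op, params, seed = step
            pair = standard_aug(pair, op, dict(params), seed=seed)
        else:
            raise ValueError(f"unknown chain step {step!r}")
    return pair
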