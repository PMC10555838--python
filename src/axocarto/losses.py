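"""The pipeline's loss family as pure, side-effect-free numeric functions.

Covers the axon-segmentation weighted sigmoid BCE, the style-transfer losses
(adversarial, cycle-consistency, outline segmentation BCE), the multiview
semi-supervised losses, and the registration losses: the three channel
similarities (mutual information, local cross-correlation, root-mean-square
difference), the affine identity and scaling penalties, displacement-field
smoothness, the first-order approximate field inverse and the inverse
consistency term.  Sign convention is unified so that every function returns
a quantity to *minimize* (MI and CC are negated).

These functions serve both as test oracles for the training objectives and
as the direct-optimization objective of :mod:`axocarto.register`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AffineTransform",
    "DeformationField",
    "SimilaritySpec",
    "axon_bce",
    "gan_loss",
    "cycle_loss",
    "outline_bce",
    "semi_multiview_loss",
    "sim_mi",
    "sim_lcc",
    "sim_mse",
    "affine_identity_penalty",
    "affine_scaling_penalty",
    "field_smoothness",
    "approx_inverse_field",
    "inverse_consistency",
    "multiconstraint_objective",
    "sample_displaced",
]


# ---------------------------------------------------------------------------
# Transform types
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """Affine map ``p -> A @ p + b`` in voxel coordinates (z, y, x order).

    Valid transforms are orientation-preserving: ``det(A) > 0``.
    """

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.A.shape != (3, 3) or self.b.shape != (3,):
            raise ValueError("AffineTransform needs a 3x3 matrix and a 3-offset")
        if not (np.isfinite(self.A).all() and np.isfinite(self.b).all()):
            raise ValueError("affine entries must be finite")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.A))

    def require_invertible(self) -> "AffineTransform":
        if self.det <= 0:
            raise ValueError(f"affine must have det(A) > 0, got {self.det:g}")
        return self

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        return pts @ self.A.T + self.b

    def inverse(self) -> "AffineTransform":
        self.require_invertible()
        Ainv = np.linalg.inv(self.A)
        return AffineTransform(Ainv, -Ainv @ self.b)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map ``p -> self(other(p))``."""
        return AffineTransform(self.A @ other.A, self.A @ other.b + self.b)


@dataclass
class DeformationField:
    """Per-voxel displacement field Φ in voxels, components stacked as
    ``phi[c, z, y, x]`` with c = (Δz, Δy, Δx).

    Applied in the pull sense: a warped image samples its source at
    ``p + Φ(p)``.
    """

    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.phi.ndim != 4 or self.phi.shape[0] != 3:
            raise ValueError(f"field must have shape (3, Z, Y, X), got {self.phi.shape}")
        if not np.isfinite(self.phi).all():
            raise ValueError("field displacements must be finite")

    @classmethod
    def zeros(cls, shape) -> "DeformationField":
        return cls(np.zeros((3, *shape)))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.phi.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.phi ** 2).sum(axis=0))


@dataclass
class SimilaritySpec:
    """Which similarity a registration channel uses, and its weight."""

    kind: str  # "mi" | "lcc" | "mse"
    weight: float = 1.0
    mi_bins: int = 32
    lcc_window: int = 9

    def __post_init__(self):
        if self.kind not in ("mi", "lcc", "mse"):
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("channel weight must be >= 0")

    def evaluate(self, X: np.ndarray, Y: np.ndarray) -> float:
        if self.kind == "mi":
            return sim_mi(X, Y, bins=self.mi_bins)
        if self.kind == "lcc":
            return sim_lcc(X, Y, s=self.lcc_window)
        return sim_mse(X, Y)


# ---------------------------------------------------------------------------
# Segmentation / style-transfer / multiview losses
# ---------------------------------------------------------------------------

_EPS = 1e-7


def _congruent(*arrays):
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"arrays must be congruent, got shapes {sorted(shapes)}")


def axon_bce(logits, target, w_pos: float = 3.0, reduction: str = "mean") -> float:
    """Weighted sigmoid binary cross-entropy for axon segmentation.

    Per voxel: ``-w [y log σ(x) + (1-y) log(1-σ(x))]`` with ``w = w_pos``
    on axon voxels (y = 1) and ``w = 1`` on background, averaged over the N
    voxels (``reduction="sum"`` gives the unnormalized total).  Computed from
    raw logits with stabilized log-sigmoids.
    """
    x = np.asarray(logits, dtype=np.float64)
    y = np.asarray(target)
    _congruent(x, y)
    if not np.isin(np.unique(y), (0, 1)).all():
        raise ValueError("target must be binary (0/1)")
    y = y.astype(np.float64)
    # log σ(x) = -softplus(-x); log(1-σ(x)) = -softplus(x)
    per_voxel = y * np.logaddexp(0.0, -x) + (1.0 - y) * np.logaddexp(0.0, x)
    w = np.where(y == 1.0, float(w_pos), 1.0)
    total = float((w * per_voxel).sum())
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total / x.size
    raise ValueError(f"unknown reduction {reduction!r}")


def gan_loss(d_real, d_fake) -> float:
    """Adversarial value ``E[log D(real)] + E[log(1 - D(fake))]`` from
    discriminator score arrays (scores strictly inside (0, 1))."""
    dr = np.asarray(d_real, dtype=np.float64)
    df = np.asarray(d_fake, dtype=np.float64)
    for name, a in (("d_real", dr), ("d_fake", df)):
        if a.size == 0 or (a <= 0).any() or (a >= 1).any():
            raise ValueError(f"{name} scores must lie strictly in (0, 1)")
    return float(np.log(dr).mean() + np.log1p(-df).mean())


def cycle_loss(x, x_rec, y, y_rec) -> float:
    """Cycle-consistency: mean L1 between each domain's originals and their
    round-trip reconstructions, summed over both directions."""
    x, x_rec = np.asarray(x, float), np.asarray(x_rec, float)
    y, y_rec = np.asarray(y, float), np.asarray(y_rec, float)
    _congruent(x, x_rec)
    _congruent(y, y_rec)
    return float(np.abs(x - x_rec).mean() + np.abs(y - y_rec).mean())


def outline_bce(pred, gt, reduction: str = "sum") -> float:
    """Brain-outline segmentation BCE, summed over voxels as printed.

    ``pred`` holds probabilities; values at exactly 0 or 1 are clamped to
    ``[eps, 1-eps]`` with a warning.
    """
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    _congruent(p, g)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("pred must lie in [0, 1]")
    if (p <= 0).any() or (p >= 1).any():
        warnings.warn("predictions at exactly 0/1 clamped by eps", stacklevel=2)
        p = np.clip(p, _EPS, 1 - _EPS)
    per = -(g * np.log(p) + (1 - g) * np.log1p(-p))
    total = float(per.sum())
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total / p.size
    raise ValueError(f"unknown reduction {reduction!r}")


def semi_multiview_loss(sup_pred, sup_gt, unsup_pred, unsup_pred_rot,
                        cor3d, hor3d_in_cor) -> dict[str, float]:
    """Multiview semi-supervised segmentation loss components.

    * ``l_sup`` — supervised BCE (summed) over annotated slices;
    * ``l_qua`` — consistency Σ(ŷ - ŷ')² between the prediction and the
      prediction for the π-rotated image mapped back;
    * ``l_3d`` — Σ of squared differences between the coronal-view 3-D
      prediction and the horizontal-view prediction transformed into the
      coronal frame;
    * ``l_cor``/``l_hor`` — per-view totals ``l_sup + l_qua``;
    * ``total`` — ``l_cor + l_hor + l_3d``.
    """
    l_sup = outline_bce(sup_pred, sup_gt, reduction="sum")
    up = np.asarray(unsup_pred, dtype=np.float64)
    ur = np.asarray(unsup_pred_rot, dtype=np.float64)
    _congruent(up, ur)
    l_qua = float(((up - ur) ** 2).sum())
    c3 = np.asarray(cor3d, dtype=np.float64)
    h3 = np.asarray(hor3d_in_cor, dtype=np.float64)
    _congruent(c3, h3)
    l_3d = float(((c3 - h3) ** 2).sum())
    l_view = l_sup + l_qua
    return {
        "l_sup": l_sup,
        "l_qua": l_qua,
        "l_3d": l_3d,
        "l_cor": l_view,
        "l_hor": l_view,
        "total": 2 * l_view + l_3d,
    }


# ---------------------------------------------------------------------------
# Registration similarities
# ---------------------------------------------------------------------------


def sim_mi(X, Y, bins: int = 32) -> float:
    """Negative mutual information from the joint intensity histogram
    (equal-width bins, natural log).  Lower = more similar."""
    x = np.asarray(X, dtype=np.float64).ravel()
    y = np.asarray(Y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("grids must be congruent")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("degenerate single-valued input; MI = 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())
    return -mi


def sim_lcc(X, Y, s: int = 9) -> float:
    """Negative mean local cross-correlation over s×s×s windows δⱼ.

    Windows where either image has zero local variance contribute 0.  The
    result lies in [-1, 1]; -1 means perfect local linear dependence.
    """
    if s < 3 or s % 2 == 0:
        raise ValueError(f"window size must be odd and >= 3, got {s}")
    x = np.asarray(X, dtype=np.float64)
    y = np.asarray(Y, dtype=np.float64)
    _congruent(x, y)
    if any(s > e for e in x.shape):
        raise ValueError(f"window {s} exceeds grid extents {x.shape}")
    mean = lambda a: ndimage.uniform_filter(a, size=s, mode="reflect")
    mx, my = mean(x), mean(y)
    cov = mean(x * y) - mx * my
    vx = np.maximum(mean(x * x) - mx * mx, 0.0)
    vy = np.maximum(mean(y * y) - my * my, 0.0)
    denom = np.sqrt(vx * vy)
    cc = np.zeros_like(cov)
    good = denom > 1e-12
    cc[good] = cov[good] / denom[good]
    return -float(cc.mean())


def sim_mse(X, Y) -> float:
    """Root-mean-square intensity difference (the printed √MSE form)."""
    x = np.asarray(X, dtype=np.float64)
    y = np.asarray(Y, dtype=np.float64)
    _congruent(x, y)
    return float(np.sqrt(((x - y) ** 2).mean()))


# ---------------------------------------------------------------------------
# Transform penalties and field operations
# ---------------------------------------------------------------------------


def affine_identity_penalty(t: AffineTransform) -> float:
    """``||A - I||_F² + ||b||²`` — distance of the affine from identity."""
    return float(((t.A - np.eye(3)) ** 2).sum() + (t.b ** 2).sum())


def affine_scaling_penalty(t: AffineTransform, mode: str = "det") -> float:
    """Scaling constraint on the affine matrix.

    ``mode="det"`` (default): ``|det(A) - 1|`` — penalizes volume change,
    matching the constraint's stated purpose.  ``mode="literal_rank"``:
    ``|rank(A) - 1|`` exactly as printed (integer-valued and equal to 2 for
    any invertible A; retained for reference).
    """
    if mode == "det":
        return abs(t.det - 1.0)
    if mode == "literal_rank":
        return float(abs(np.linalg.matrix_rank(t.A) - 1))
    raise ValueError(f"unknown mode {mode!r}")


def field_smoothness(f: DeformationField) -> float:
    """Mean L1 norm of the forward-difference spatial gradient ``||∇Φ||₁``.

    Averaged over all 9 (component, axis) difference arrays; 0 iff the field
    is spatially constant.
    """
    total = 0.0
    count = 0
    for c in range(3):
        for axis in range(3):
            d = np.diff(f.phi[c], axis=axis)
            total += float(np.abs(d).sum())
            count += d.size
    return total / count if count else 0.0


def sample_displaced(arr: np.ndarray, f: DeformationField, order: int = 1) -> np.ndarray:
    """Resample ``arr`` at the Φ-displaced positions: out(p) = arr(p + Φ(p)).

    Positions outside the grid are clamped to the nearest edge voxel.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape != f.grid_shape:
        raise ValueError(f"array shape {arr.shape} != field grid {f.grid_shape}")
    coords = np.indices(arr.shape, dtype=np.float64) + f.phi
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def approx_inverse_field(f: DeformationField) -> DeformationField:
    """First-order approximate inverse ``Φ⁻¹ = (-Φz⊙Φ, -Φy⊙Φ, -Φx⊙Φ)``:
    each component is interpolated at the Φ-displaced positions and negated.

    Exact for constant translations; for smooth small fields the composition
    residual is O(|Φ|²)."""
    inv = np.stack([-sample_displaced(f.phi[c], f) for c in range(3)])
    return DeformationField(inv)


def inverse_consistency(Y, f: DeformationField) -> float:
    """RMS difference between Y and Y resampled through the approximate
    inverse field: ``sqrt(mean((Y - Y⊙Φ⁻¹)²))``."""
    y = np.asarray(Y, dtype=np.float64)
    if y.shape != f.grid_shape:
        raise ValueError("Y must be congruent with the field grid")
    resampled = sample_displaced(y, approx_inverse_field(f))
    return float(np.sqrt(((y - resampled) ** 2).mean()))


# ---------------------------------------------------------------------------
# Combined multi-constraint objective
# ---------------------------------------------------------------------------


def multiconstraint_objective(channels, stage: str, t: AffineTransform | None = None,
                              f: DeformationField | None = None,
                              scaling_mode: str = "det",
                              identity_weight: float = 1.0,
                              scaling_weight: float = 1.0,
                              smooth_weight: float = 1.0,
                              inv_weight: float = 1.0) -> float:
    """Weighted sum of per-channel similarities plus stage penalties.

    ``channels`` is a list of ``(X, Y, SimilaritySpec)``; channel weights
    must sum to 1 (the default split is 0.70 for the original brain, 0.15
    for the style-proxy brain and 0.15 divided across region masks).  Stage
    ``"affine"`` adds the identity and scaling penalties of ``t``;
    ``"deformable"`` adds field smoothness and inverse consistency of ``f``
    (evaluated on the highest-weighted channel's moving image).
    """
    if stage not in ("rigid", "affine", "deformable"):
        raise ValueError(f"unknown stage {stage!r}")
    if not channels:
        raise ValueError("at least one channel required")
    wsum = sum(spec.weight for _, _, spec in channels)
    if abs(wsum - 1.0) > 1e-6:
        raise ValueError(f"channel weights must sum to 1, got {wsum}")
    total = 0.0
    for X, Y, spec in channels:
        if spec.weight == 0:
            continue
        total += spec.weight * spec.evaluate(X, Y)
    if stage == "affine":
        if t is None:
            raise ValueError("affine stage requires t")
        total += (identity_weight * affine_identity_penalty(t)
                  + scaling_weight * affine_scaling_penalty(t, mode=scaling_mode))
    elif stage == "deformable":
        if f is None:
            raise ValueError("deformable stage requires f")
        total += smooth_weight * field_smoothness(f)
        if inv_weight > 0:
            lead = max(channels, key=lambda ch: ch[2].weight)
            total += inv_weight * inverse_consistency(np.asarray(lead[1], float), f)
    return float(total)
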