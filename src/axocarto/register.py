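"""Desk-scale multiscale, multi-constraint 3-D whole-brain registration.

The registration input is a multi-channel bundle: the original brain
(compared by mutual information), an intensity-normalized style-proxy brain
(local cross-correlation) and per-region binary masks (RMS difference on
softened masks), weighted 70% / 15% / 15% in the combined objective.  A
three-level image pyramid is built by average-downsampling; a rigid
(rotation + translation) and then a full affine transform are fitted at the
coarsest level by direct optimization of the combined objective and applied
unchanged at finer levels; a control-point displacement field is then
optimized coarse-to-fine under the same objective plus field-smoothness and
inverse-consistency penalties, each coarser solution initializing the next
level.

The published pipeline realizes the deformable stage with a trained
convolutional predictor; here the identical objective is minimized directly
per pair, which exercises the objective itself at desk scale without
training data.  Rigid/affine parameters are optimized derivative-free
(Powell); the deformable stage takes analytic descent directions from the
differentiable channels and accepts steps only when the full objective
decreases, so per-stage objective traces are non-increasing by
construction.

Usage follows the model/results idiom::

    model = RegistrationModel(src_bundle, ref_bundle, RegistrationConfig())
    result = model.fit()
    print(result.summary())
    warped = result.warped
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .losses import (AffineTransform, DeformationField, SimilaritySpec,
                     multiconstraint_objective, sample_displaced)
from .synthgen import PhantomBrain
from .volio import LabelVolume, Volume

__all__ = [
    "RegistrationBundle",
    "RegistrationConfig",
    "RegistrationResult",
    "RegistrationModel",
    "build_pyramid",
    "fit_rigid",
    "fit_affine",
    "fit_deformable",
    "apply_transform",
    "register_brain",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class RegistrationBundle:
    """Multi-channel registration input: original intensity volume,
    optional style-proxy volume, per-region binary masks, optional
    landmarks (voxel coordinates)."""

    original: Volume
    style_proxy: Volume | None = None
    region_masks: dict[int, np.ndarray] = dc_field(default_factory=dict)
    landmarks: np.ndarray | None = None

    def __post_init__(self):
        shape = self.original.shape
        if self.style_proxy is not None and self.style_proxy.shape != shape:
            raise ValueError("style_proxy must be congruent with original")
        self.region_masks = {int(k): np.asarray(v).astype(bool)
                             for k, v in self.region_masks.items()}
        for rid, m in self.region_masks.items():
            if m.shape != shape:
                raise ValueError(f"region mask {rid} not congruent with original")
        if self.landmarks is not None:
            self.landmarks = np.atleast_2d(np.asarray(self.landmarks, float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.original.shape

    @classmethod
    def from_phantom(cls, p: PhantomBrain) -> "RegistrationBundle":
        """Build a bundle from a phantom: the style proxy is the min-max
        normalized intensity; masks are one binary volume per region."""
        inten = np.asarray(p.intensity.data, dtype=np.float64)
        lo, hi = inten.min(), inten.max()
        proxy = (inten - lo) / (hi - lo) if hi > lo else np.zeros_like(inten)
        masks = {int(r): p.labels.data == r for r in np.unique(p.labels.data) if r != 0}
        return cls(original=p.intensity,
                   style_proxy=Volume(proxy.astype(np.float32),
                                      spacing=p.intensity.spacing),
                   region_masks=masks,
                   landmarks=p.landmarks)


@dataclass
class RegistrationConfig:
    """Knobs of the registration pipeline.

    Channel weights default to 0.70 (original, MI) / 0.15 (style proxy,
    LCC) / 0.15 split evenly across region-mask channels (MSE); weights of
    absent channels are renormalized over the present ones.
    """

    pyramid_levels: int = 3
    downsample_factor: int = 2
    weight_original: float = 0.70
    weight_style: float = 0.15
    weight_regions: float = 0.15
    mi_bins: int = 32
    lcc_window: int = 9
    mask_blur_sigma: float = 1.0
    rigid_maxiter: int = 60
    affine_maxiter: int = 60
    deform_iters: tuple[int, ...] = (40, 25, 0)   # coarsest level first
    control_spacing: int = 4
    smooth_weight: float = 0.1
    inv_weight: float = 0.05
    identity_weight: float = 0.01
    scaling_weight: float = 0.01
    scaling_mode: str = "det"
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.downsample_factor < 2:
            raise ValueError("downsample_factor must be >= 2")
        total = self.weight_original + self.weight_style + self.weight_regions
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"channel weights must sum to 1, got {total}")


@dataclass
class RegistrationResult:
    """Fitted transforms, per-stage objective traces and the warped bundle.

    ``rigid`` and ``affine`` are pull maps on the reference grid (the
    incremental affine composes after the rigid stage); ``field`` is the
    voxel-resolution displacement field at the reference resolution.
    """

    rigid: AffineTransform
    affine: AffineTransform
    field: DeformationField
    traces: dict[str, list[float]]
    warped: RegistrationBundle | None
    config: RegistrationConfig

    @property
    def combined_affine(self) -> AffineTransform:
        """The total linear pull map rigid ∘ affine."""
        return self.rigid.compose(self.affine)

    def summary(self) -> str:
        lines = ["Multi-constraint registration result",
                 "=" * 38]
        A, b = self.combined_affine.A, self.combined_affine.b
        lines.append(f"linear map det(A) = {self.combined_affine.det:.4f}")
        lines.append("A =")
        for row in A:
            lines.append("   [" + "  ".join(f"{v:8.4f}" for v in row) + "]")
        lines.append("b = [" + "  ".join(f"{v:8.3f}" for v in b) + "] voxels")
        mag = self.field.magnitude()
        lines.append(f"field |Φ|: mean {mag.mean():.3f}, "
                     f"p99 {np.percentile(mag, 99):.3f} voxels")
        for stage, tr in self.traces.items():
            if tr:
                lines.append(f"{stage:10s} objective: {tr[0]:.5f} -> {tr[-1]:.5f} "
                             f"({len(tr)} evals)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Pyramid
# ---------------------------------------------------------------------------


def _downsample(arr: np.ndarray, factor: int, majority: bool = False) -> np.ndarray:
    """Average-pool by ``factor`` per axis with edge padding; extents become
    ceil(n/factor).  ``majority`` thresholds the mean at 0.5 (for masks)."""
    a = np.asarray(arr, dtype=np.float64)
    pads = [(0, (-s) % factor) for s in a.shape]
    a = np.pad(a, pads, mode="edge")
    sh = []
    for s in a.shape:
        sh.extend([s // factor, factor])
    pooled = a.reshape(sh).mean(axis=(1, 3, 5))
    if majority:
        return pooled > 0.5
    return pooled


def build_pyramid(b: RegistrationBundle, levels: int = 3,
                  factor: int = 2) -> list[RegistrationBundle]:
    """Level 0 is the input; each next level is average-downsampled by
    ``factor`` per axis (masks by majority vote, staying binary)."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out = [b]
    for _ in range(1, levels):
        prev = out[-1]
        if any(s // factor < 1 for s in prev.shape):
            raise ValueError(f"downsampling {prev.shape} by {factor} reaches extent 0")
        spacing = tuple(s * factor for s in prev.original.spacing)
        nxt = RegistrationBundle(
            original=Volume(_downsample(prev.original.data, factor).astype(np.float32),
                            spacing=spacing),
            style_proxy=None if prev.style_proxy is None else Volume(
                _downsample(prev.style_proxy.data, factor).astype(np.float32),
                spacing=spacing),
            region_masks={r: _downsample(m, factor, majority=True)
                          for r, m in prev.region_masks.items()},
            landmarks=None if prev.landmarks is None else prev.landmarks / factor,
        )
        out.append(nxt)
    return out


# ---------------------------------------------------------------------------
# Channels and parameterization
# ---------------------------------------------------------------------------


def _channel_images(bundle: RegistrationBundle, cfg: RegistrationConfig):
    """(image, spec) list for one bundle; masks are blurred to soft masks so
    the MSE channel has gradient support."""
    present_regions = sorted(bundle.region_masks)
    w_orig, w_style, w_reg = cfg.weight_original, cfg.weight_style, cfg.weight_regions
    if bundle.style_proxy is None:
        w_style = 0.0
    if not present_regions:
        w_reg = 0.0
    total = w_orig + w_style + w_reg
    orig = np.asarray(bundle.original.data, np.float64)
    lo, hi = orig.min(), orig.max()
    if hi > lo:   # normalize so RMS-based penalties share the mask channels' scale
        orig = (orig - lo) / (hi - lo)
    channels = [(orig,
                 SimilaritySpec("mi", weight=w_orig / total, mi_bins=cfg.mi_bins))]
    if bundle.style_proxy is not None:
        channels.append((np.asarray(bundle.style_proxy.data, np.float64),
                         SimilaritySpec("lcc", weight=w_style / total,
                                        lcc_window=cfg.lcc_window)))
    for rid in present_regions:
        soft = ndimage.gaussian_filter(bundle.region_masks[rid].astype(np.float64),
                                       cfg.mask_blur_sigma)
        channels.append((soft, SimilaritySpec(
            "mse", weight=w_reg / total / len(present_regions))))
    return channels


def _params_to_affine(params: np.ndarray, shape, rigid_only: bool) -> AffineTransform:
    """Map optimizer parameters to a center-based pull affine.

    Rigid: Euler angles (z–y–x, radians) + translation.  Affine: the 9
    matrix entries + translation.  The returned transform is in global
    form ``p -> A p + (c - A c + t)`` with c the grid center.
    """
    c = (np.asarray(shape, np.float64) - 1.0) / 2.0
    if rigid_only:
        az, ay, ax = params[:3]
        t = params[3:6]
        cz, sz = np.cos(az), np.sin(az)
        cy, sy = np.cos(ay), np.sin(ay)
        cx, sx = np.cos(ax), np.sin(ax)
        Rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])   # rotation about z-axis index
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
        A = Rz @ Ry @ Rx
    else:
        A = params[:9].reshape(3, 3)
        t = params[9:12]
    return AffineTransform(A, c - A @ c + np.asarray(t, np.float64))


def _center_decompose(t: AffineTransform, shape) -> tuple[np.ndarray, np.ndarray]:
    """Recover (A, center-based translation) from a global-form transform."""
    c = (np.asarray(shape, np.float64) - 1.0) / 2.0
    return t.A, t.b - c + t.A @ c


def _rescale_affine(t: AffineTransform, shape_from, shape_to,
                    k: float) -> AffineTransform:
    """Re-express a center-based affine fitted on ``shape_from`` in the
    coordinates of ``shape_to`` (voxels ``k`` times smaller): the matrix is
    unchanged and the center-based translation scales by ``k``."""
    A, tc = _center_decompose(t, shape_from)
    c = (np.asarray(shape_to, np.float64) - 1.0) / 2.0
    return AffineTransform(A, c - A @ c + k * tc)


def _warp_affine(img: np.ndarray, t: AffineTransform, order: int = 1) -> np.ndarray:
    return ndimage.affine_transform(img, t.A, offset=t.b, order=order, mode="nearest")


def _objective_affine(params, src_channels, ref_channels, shape, stage, cfg,
                      rigid_only):
    t = _params_to_affine(np.asarray(params, float), shape, rigid_only)
    if t.det <= 1e-6:
        return 1e6
    channels = []
    for (src_img, _), (ref_img, spec) in zip(src_channels, ref_channels):
        channels.append((ref_img, _warp_affine(src_img, t), spec))
    # penalties use the center-based decomposition so pure rotation about the
    # volume center is not charged a spurious translation
    _, tb = _center_decompose(t, shape)
    pen_t = AffineTransform(t.A, tb)
    return multiconstraint_objective(channels, stage, t=pen_t,
                                     scaling_mode=cfg.scaling_mode,
                                     identity_weight=cfg.identity_weight,
                                     scaling_weight=cfg.scaling_weight)


def _minimize_powell(fun, x0, maxiter):
    trace = [float(fun(x0))]

    def cb(xk):
        trace.append(float(fun(xk)))

    res = optimize.minimize(fun, x0, method="Powell", callback=cb,
                            options={"maxiter": maxiter, "xtol": 1e-4,
                                     "ftol": 1e-7})
    best = np.asarray(res.x, float)
    if float(fun(best)) > trace[0]:
        best = np.asarray(x0, float)   # never return worse than the start
    # report the monotone envelope of the per-iteration values
    trace = list(np.minimum.accumulate(trace))
    return best, trace


def fit_rigid(src: RegistrationBundle, ref: RegistrationBundle,
              cfg: RegistrationConfig | None = None) -> AffineTransform:
    """Fit rotation + translation (6 parameters) at the given (coarsest)
    level by direct minimization of the multi-constraint objective."""
    cfg = cfg or RegistrationConfig()
    if src.shape != ref.shape:
        raise ValueError("bundles must be congruent at the fitting level")
    src_ch = _channel_images(src, cfg)
    ref_ch = _channel_images(ref, cfg)
    fun = lambda p: _objective_affine(p, src_ch, ref_ch, src.shape, "rigid", cfg, True)
    x, trace = _minimize_powell(fun, np.zeros(6), cfg.rigid_maxiter)
    if not np.isfinite(trace[-1]):
        raise RuntimeError(f"non-finite rigid objective; trace={trace}")
    t = _params_to_affine(x, src.shape, True)
    t.trace = trace  # type: ignore[attr-defined]
    return t


def fit_affine(src: RegistrationBundle, ref: RegistrationBundle,
               cfg: RegistrationConfig | None = None,
               init: AffineTransform | None = None) -> AffineTransform:
    """Fit the full 12-parameter affine, started from ``init`` (typically
    the rigid fit); adds the identity and scaling penalties to the
    objective.  Returns the total linear pull map."""
    cfg = cfg or RegistrationConfig()
    if src.shape != ref.shape:
        raise ValueError("bundles must be congruent at the fitting level")
    init = init or AffineTransform.identity()
    A0, t0 = _center_decompose(init.require_invertible(), src.shape)
    x0 = np.concatenate([A0.ravel(), t0])
    src_ch = _channel_images(src, cfg)
    ref_ch = _channel_images(ref, cfg)
    fun = lambda p: _objective_affine(p, src_ch, ref_ch, src.shape, "affine", cfg, False)
    x, trace = _minimize_powell(fun, x0, cfg.affine_maxiter)
    t = _params_to_affine(x, src.shape, False).require_invertible()
    t.trace = trace  # type: ignore[attr-defined]
    return t


# ---------------------------------------------------------------------------
# Deformable stage
# ---------------------------------------------------------------------------


def _upsample_field(ctrl: np.ndarray, shape) -> np.ndarray:
    """Tri-linearly upsample a (3, cz, cy, cx) control grid to a voxel grid."""
    out = np.empty((3, *shape))
    for c in range(3):
        zoom = [s / cs for s, cs in zip(shape, ctrl.shape[1:])]
        out[c] = ndimage.zoom(ctrl[c], zoom, order=1, mode="nearest",
                              grid_mode=True)
    return out


def _downsample_to_ctrl(vox: np.ndarray, ctrl_shape) -> np.ndarray:
    out = np.empty((3, *ctrl_shape))
    for c in range(3):
        zoom = [cs / s for cs, s in zip(ctrl_shape, vox.shape[1:])]
        out[c] = ndimage.zoom(vox[c], zoom, order=1, mode="nearest", grid_mode=True)
    return out


def _surrogate_gradient(channels, fieldobj: DeformationField, coords,
                        grads_src, cfg) -> np.ndarray:
    """Analytic descent direction from the differentiable channels (MSE and
    LCC) plus the smoothness subgradient; the MI channel and inverse
    consistency enter only through the line-search acceptance test."""
    shape = fieldobj.grid_shape
    g = np.zeros((3, *shape))
    n = float(np.prod(shape))
    for (X, Ysrc, spec), grad_src in zip(channels, grads_src):
        W = sample_displaced(Ysrc, fieldobj)
        if spec.kind == "mi":
            # MI itself is histogram-based and non-differentiable; use the
            # gradient of global negative correlation as a descent surrogate
            # (the step is accepted against the true MI-bearing objective)
            Xc = X - X.mean()
            Wc = W - W.mean()
            sx = np.sqrt((Xc ** 2).mean())
            sw = np.sqrt((Wc ** 2).mean())
            if sx < 1e-12 or sw < 1e-12:
                continue
            corr = (Xc * Wc).mean() / (sx * sw)
            dldw = -(Xc / (sx * sw) - corr * Wc / (sw ** 2)) / n
        elif spec.kind == "mse":
            resid = W - X
            L = np.sqrt((resid ** 2).mean())
            if L < 1e-12:
                continue
            dldw = resid / (n * L)
        else:  # lcc
            s = spec.lcc_window
            mean = lambda a: ndimage.uniform_filter(a, size=s, mode="reflect")
            mX, mW = mean(X), mean(W)
            cov = mean(X * W) - mX * mW
            vX = np.maximum(mean(X * X) - mX * mX, 1e-12)
            vW = np.maximum(mean(W * W) - mW * mW, 1e-12)
            cc = cov / np.sqrt(vX * vW)
            dldw = -((X - mX) / np.sqrt(vX * vW) - cc * (W - mW) / vW) / n
        samp = [ndimage.map_coordinates(gc, coords, order=1, mode="nearest")
                for gc in grad_src]
        for c in range(3):
            g[c] += spec.weight * dldw * samp[c]
    # smoothness subgradient (adjoint of the forward difference)
    count = sum(np.diff(fieldobj.phi[c], axis=a).size
                for c in range(3) for a in range(3))
    for c in range(3):
        for a in range(3):
            sgn = np.sign(np.diff(fieldobj.phi[c], axis=a))
            pad_lo = [(0, 0)] * 3
            pad_lo[a] = (1, 0)
            pad_hi = [(0, 0)] * 3
            pad_hi[a] = (0, 1)
            g[c] += cfg.smooth_weight * (np.pad(sgn, pad_lo) - np.pad(sgn, pad_hi)) / count
    return g


def fit_deformable(src_pyramid, ref_pyramid, cfg: RegistrationConfig | None = None,
                   init: AffineTransform | None = None) -> DeformationField:
    """Optimize a control-point displacement field coarse-to-fine.

    ``src_pyramid``/``ref_pyramid`` are bundle pyramids (level 0 finest);
    ``init`` is the total linear pull map fitted at the coarsest level of a
    grid whose coordinates match level ``len(pyramid)-1``.  The coarsest
    field initializes the next level (displacements scaled by the factor).
    Returns the field at level-0 voxel resolution, with the per-level
    objective traces attached as ``field.traces``.
    """
    cfg = cfg or RegistrationConfig()
    init = init or AffineTransform.identity()
    levels = len(src_pyramid)
    iters = list(cfg.deform_iters) + [0] * levels
    ctrl = None
    traces: list[list[float]] = []
    factor = cfg.downsample_factor
    for depth, lvl in enumerate(range(levels - 1, -1, -1)):
        src, ref = src_pyramid[lvl], ref_pyramid[lvl]
        shape = src.shape
        scale = factor ** (levels - 1 - lvl)
        lin = _rescale_affine(init, src_pyramid[-1].shape, shape, scale)
        src_ch_raw = _channel_images(src, cfg)
        ref_ch = _channel_images(ref, cfg)
        channels = [( ref_img, _warp_affine(src_img, lin), spec)
                    for (src_img, _), (ref_img, spec) in zip(src_ch_raw, ref_ch)]
        ctrl_shape = tuple(max(2, int(np.ceil(s / cfg.control_spacing)) + 1)
                           for s in shape)
        if ctrl is None:
            ctrl = np.zeros((3, *ctrl_shape))
        else:
            ctrl = _downsample_to_ctrl(ctrl * factor, ctrl_shape)
        n_iter = iters[depth]
        trace = []
        lead = max(range(len(channels)), key=lambda i: channels[i][2].weight)

        def objective(ctrl_arr):
            f = DeformationField(_upsample_field(ctrl_arr, shape))
            chans = [(X, sample_displaced(Y, f), spec) for X, Y, spec in channels]
            from .losses import field_smoothness, inverse_consistency
            val = sum(spec.weight * spec.evaluate(X, Yw) for X, Yw, spec in chans)
            val += cfg.smooth_weight * field_smoothness(f)
            if cfg.inv_weight > 0:
                val += cfg.inv_weight * inverse_consistency(channels[lead][1], f)
            return float(val)

        current = objective(ctrl)
        trace.append(current)
        if n_iter > 0:
            base = np.indices(shape, dtype=np.float64)
            grads_src = [np.gradient(Y) for _, Y, _ in channels]
            step = 1.0
            stalled = 0
            for _ in range(n_iter):
                f = DeformationField(_upsample_field(ctrl, shape))
                coords = base + f.phi
                g_vox = _surrogate_gradient(channels, f, coords, grads_src, cfg)
                g_ctrl = _downsample_to_ctrl(g_vox, ctrl_shape)
                gmax = np.abs(g_ctrl).max()
                if gmax < 1e-14:
                    break
                improved = False
                while step >= 1e-3:
                    cand = ctrl - (step / gmax) * g_ctrl
                    val = objective(cand)
                    if val < current - 1e-12:
                        ctrl, current, improved = cand, val, True
                        trace.append(current)
                        step = min(step * 1.3, 4.0)
                        break
                    step *= 0.5
                if improved:
                    stalled = 0
                else:
                    stalled += 1
                    step = 0.25     # restart the line search with a fresh gradient
                    if stalled >= 2:
                        break
        traces.append(trace)
    field = DeformationField(_upsample_field(ctrl, src_pyramid[0].shape))
    field.traces = traces  # type: ignore[attr-defined]
    return field


# ---------------------------------------------------------------------------
# Applying transforms
# ---------------------------------------------------------------------------


def _compose_pull(rigid, affine) -> AffineTransform:
    r = rigid or AffineTransform.identity()
    a = affine or AffineTransform.identity()
    return r.compose(a)


def apply_transform(x, rigid: AffineTransform | None = None,
                    affine: AffineTransform | None = None,
                    field: DeformationField | None = None,
                    interp: str = "linear"):
    """Apply the composed registration (rigid → affine → field) to a
    Volume, LabelVolume or point array.

    Volumes are resampled through the pull maps; points are mapped forward
    (exactly through the affine inverses; by fixed-point inversion of the
    field).  Labels must use nearest-neighbor interpolation.
    """
    C = _compose_pull(rigid, affine)
    if isinstance(x, LabelVolume):
        if interp == "linear":
            raise ValueError("label volumes require interp='nearest'")
        order = 0
    elif isinstance(x, Volume):
        order = 0 if interp == "nearest" else 1
    else:  # points
        pts = np.atleast_2d(np.asarray(x, dtype=np.float64))
        Cinv = C.inverse()
        if field is None:
            return Cinv.apply_points(pts)
        targets = Cinv.apply_points(pts)     # solve y + Φ(y) = C⁻¹(p)
        y = targets.copy()
        for _ in range(30):
            disp = np.stack([ndimage.map_coordinates(field.phi[c], y.T, order=1,
                                                     mode="nearest")
                             for c in range(3)], axis=1)
            y = targets - disp
        return y

    data = np.asarray(x.data, dtype=np.float64)
    shape = data.shape
    base = np.indices(shape, dtype=np.float64)
    if field is not None:
        if field.grid_shape != shape:
            raise ValueError("field grid must match the volume shape")
        pos = base + field.phi
    else:
        pos = base
    coords = np.einsum("ij,j...->i...", C.A, pos) + C.b[:, None, None, None]
    out = ndimage.map_coordinates(data, coords, order=order,
                                  mode="constant" if order == 0 else "nearest",
                                  cval=0.0)
    if isinstance(x, LabelVolume):
        return LabelVolume(out.astype(x.data.dtype), spacing=x.spacing, origin=x.origin)
    return Volume(out.astype(np.float32 if np.issubdtype(x.data.dtype, np.floating)
                             else x.data.dtype),
                  spacing=x.spacing, origin=x.origin)


# ---------------------------------------------------------------------------
# Model / results facade
# ---------------------------------------------------------------------------


class RegistrationModel:
    """Rigid → affine → deformable registration of a source bundle onto a
    reference bundle; ``fit()`` returns a :class:`RegistrationResult`."""

    def __init__(self, src: RegistrationBundle, ref: RegistrationBundle,
                 cfg: RegistrationConfig | None = None):
        if src.shape != ref.shape:
            raise ValueError("source and reference bundles must share a grid; "
                             "resample the source to the reference grid first")
        self.src = src
        self.ref = ref
        self.cfg = cfg or RegistrationConfig()

    def fit(self) -> RegistrationResult:
        cfg = self.cfg
        src_pyr = build_pyramid(self.src, cfg.pyramid_levels, cfg.downsample_factor)
        ref_pyr = build_pyramid(self.ref, cfg.pyramid_levels, cfg.downsample_factor)
        coarse_src, coarse_ref = src_pyr[-1], ref_pyr[-1]
        rigid = fit_rigid(coarse_src, coarse_ref, cfg)
        full_affine = fit_affine(coarse_src, coarse_ref, cfg, init=rigid)
        field = fit_deformable(src_pyr, ref_pyr, cfg, init=full_affine)
        scale = cfg.downsample_factor ** (cfg.pyramid_levels - 1)
        # rescale the coarsest-level linear maps to level-0 coordinates
        coarse_shape, fine_shape = coarse_src.shape, self.src.shape
        rigid0 = _rescale_affine(rigid, coarse_shape, fine_shape, scale)
        full0 = _rescale_affine(full_affine, coarse_shape, fine_shape, scale)
        incr = rigid0.inverse().compose(full0)
        traces = {
            "rigid": list(getattr(rigid, "trace", [])),
            "affine": list(getattr(full_affine, "trace", [])),
        }
        for i, tr in enumerate(getattr(field, "traces", [])):
            traces[f"deformable_l{i}"] = list(tr)
        warped = self._warp_bundle(rigid0, incr, field)
        return RegistrationResult(rigid=rigid0, affine=incr, field=field,
                                  traces=traces, warped=warped, config=cfg)

    def _warp_bundle(self, rigid, affine, field) -> RegistrationBundle:
        warped_orig = apply_transform(self.src.original, rigid, affine, field)
        warped_style = None
        if self.src.style_proxy is not None:
            warped_style = apply_transform(self.src.style_proxy, rigid, affine, field)
        masks = {}
        for rid, m in self.src.region_masks.items():
            mv = LabelVolume(m.astype(np.int32), spacing=self.src.original.spacing)
            masks[rid] = apply_transform(mv, rigid, affine, field,
                                         interp="nearest").data.astype(bool)
        lms = None
        if self.src.landmarks is not None:
            lms = apply_transform(self.src.landmarks, rigid, affine, field)
        return RegistrationBundle(original=warped_orig, style_proxy=warped_style,
                                  region_masks=masks, landmarks=lms)


def register_brain(src: RegistrationBundle, ref: RegistrationBundle,
                   cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Functional wrapper: ``RegistrationModel(src, ref, cfg).fit()``."""
    return RegistrationModel(src, ref, cfg).fit()
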