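# Methods

This note documents the models and procedures implemented in `axocarto`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinate and data conventions

All grids are 3-D arrays in `(z, y, x)` = (depth, height, width) order,
matching slice-stack storage; voxel coordinates are 0-based and ranges are
half-open. Spacing is µm per axis. Annotations are binary with 1 = axon.
Affine transforms map points as `p → A p + b`; deformation fields Φ are
per-voxel displacements in voxels applied in the *pull* sense (a warped
image samples its source at `p + Φ(p)`), the convention under which the
transform fitted by registration is directly comparable to the transform
used to perturb a phantom.

## Synthetic data generator

The generator emulates the objects the pipeline consumes, not the physics
of light-sheet imaging.

* **Axon cubes.** Centerlines are branching random walks (unit steps,
  Gaussian direction jitter σ = 0.25 rad-equivalent per step, branch
  probability 1.5% per step up to depth 2), rasterized densely and thinned
  to single-voxel 26-connected curves. A voxel belongs to the annotation
  iff its Euclidean distance to the centerline is ≤ `radius_vox` (default
  2). Intensity is `background + peak·exp(−d²/2σ²) + N(0, σ_noise)` with
  σ tied to the tube radius — a Gaussian radial falloff standing in for
  the microscope point-spread function — with `peak = snr · σ_noise`
  (defaults: background 100, σ_noise 20, snr 10, two trees per 64³ cube).
  These defaults produce sparse cubes (≲1% axon voxels) comparable to
  sparsely innervated tissue.
* **Artifact cubes** contain one of three bright non-axonal structures:
  a thick curving tube (radius ≥ 4 voxels, far above the axon scale),
  Gaussian blobs, or a planar band near a face, each ~8–10 noise σ above
  background. Their true annotation is empty by definition.
* **Phantom brains** are an ellipsoidal "brain" (semi-axes 0.44 × shape)
  holding `n_regions` non-overlapping ellipsoidal regions placed on a ring
  in the two longest axes, each with a distinct mean intensity, plus
  landmarks at region centroids. The default shape (80, 114, 132) equals
  the coarsest level of the registration pyramid so whole-pipeline
  registration runs in minutes on one CPU.

What the generator does **not** model: stripe/shadow artifacts, depth-
dependent attenuation, anisotropic PSFs, autofluorescence texture, or
realistic atlas geometry. Tests passing on these phantoms demonstrate that
the algorithms are implemented correctly and recover known ground truth
under controlled noise — not that they reach any particular accuracy on
real brains.

All randomness flows from explicit integer seeds; no global state.

## Automated annotation

`binarize → connect → skeletonize → thicken`:

1. **Binarization.** Gaussian smoothing with a (kernel)³ support (default
   3×3×3, σ = (k−1)/4 truncated at the kernel radius), then a difference
   of Gaussians with σ = (1.0, 2.5) voxels — a band-pass admitting 1–3
   voxel-wide structures — thresholded. The automatic threshold is Otsu's
   value over the DoG response at nonzero voxels, floored at 5 robust
   (MAD-estimated) σ of the response: Otsu assumes a bimodal histogram and
   can cut inside the noise mode when axons occupy a tiny voxel fraction,
   and the floor rejects that failure mode without touching well-separated
   cubes (where Otsu exceeds it).
2. **Fragment connection** is ball dilation (default radius 1) to bridge
   gaps that thresholding opens along dim axon stretches.
3. **Skeletonization** is topology-preserving 3-D thinning
   (`skimage.morphology.skeletonize`, the Lee–Kashyap–Chu family).
4. **Thickening** dilates every centerline voxel by the 6-neighborhood
   cross (±1 along each axis, clipped at faces), yielding annotations of
   uniform thickness.

Dense cubes (explicit `dense_mode` flag — no automatic density cutoff is
imposed) keep the binarized-and-connected mask instead, since skeletons of
dense tangles no longer reflect axon structure.

## Augmentation

* **CutMix** pastes an axis-aligned box from an artifact cube into an axon
  cube; per-axis extents are drawn independently around `frac^(1/3)` of
  each dimension, so the box volume is ≈ `frac` of the cube. Annotation
  inside the box is cleared. Only artifact-into-axon pasting is performed.
* **Histogram matching** computes a monotone quantile mapping from the
  *background* voxels (annotation = 0) of the source to the reference
  histogram and applies it to background voxels only; annotated axon
  intensities and the annotation itself are untouched, bit-exactly.
* **Local contrast** scales the intensities of a random subset (each
  component with probability ½, at least one) of the 26-connected
  annotation components by a factor from `factor_range`.
* **Standard ops**: rotation and scaling act identically on intensity
  (linear interpolation) and annotation (nearest, re-binarized; scaling is
  followed by center crop/pad back to the cube shape); noise, blur and
  brightness never touch the annotation.

The default recipe applies 2 CutMix + 2 histogram + 2 contrast + 4 standard
derivatives per axon cube and keeps the sources, so a pool of 100 + 100
cubes yields 1,100 annotated cubes. Every output records its operator
chain; replaying the chain from the sources reproduces it bit-exactly.

## Metrics

Empty-mask conventions: both masks (or skeletons) empty → score 1, exactly
one empty → 0, so an empty prediction of an empty truth is not penalized.
Centerline scores are computed on *raw* (unthickened) skeletons extracted
by the same thinning used for annotation, so metric and annotation share
one centerline definition. Dice is exactly invariant to congruent axis
permutations; centerline scores inherit a small scan-order asymmetry from
thinning and are permutation-stable only up to a few voxels of skeleton.

## Loss functions

All losses are pure functions returning quantities to minimize; MI and
local cross-correlation are negated accordingly. Reductions follow the
defining forms: the axon BCE is a mean over voxels, the outline BCE and
the multiview consistency terms are sums, and each exposes an explicit
`reduction` option where both forms are useful. MI uses 32 equal-width
bins and natural logarithms; LCC uses s = 9 windows (reflecting at
borders) with zero-variance windows contributing 0. The affine scaling
constraint defaults to `|det(A) − 1|`; the literal `|rank(A) − 1|` form is
retained behind `mode="literal_rank"` but is integer-valued and equals 2
for every invertible matrix, which defeats its stated purpose of
constraining scale. The approximate field inverse is first-order —
`Φ⁻¹ = −Φ` resampled at the Φ-displaced positions — exact for constant
translations and accurate to O(|Φ|²) for smooth fields.

## Registration

The deformable stage of the original pipeline is a trained convolutional
predictor; what is exercisable at desk scale without training data is the
*objective*, so registration here minimizes the identical multi-constraint
objective directly per pair. Design points:

* **Channels.** Original brain → MI (weight 0.70); style-proxy brain
  (any intensity-normalized stand-in for a style-transferred brain) → LCC
  (0.15); per-region masks → RMS difference on masks blurred with σ = 1
  voxel so the term has gradient support (0.15 split evenly; weights of
  absent channels are renormalized over the present ones). Intensity
  channels are min–max normalized before similarity computation: MI and
  LCC are invariant to this, and it puts the RMS-based inverse-consistency
  penalty on the same O(1) scale as the mask channels — on raw 16-bit
  intensities that term is several orders of magnitude larger than any
  similarity gain and freezes the field at zero.
* **Pyramid.** Average-downsampling by 2 per level (masks by majority),
  three levels by default; rigid (6 parameters, Euler z–y–x + translation
  about the grid center) and affine (12 parameters) are fitted at the
  coarsest level only and re-expressed, not re-optimized, at finer levels.
* **Optimizer.** Rigid/affine use Powell's derivative-free method: the MI
  term is histogram-based and piecewise flat under sub-bin parameter
  changes, which makes finite-difference gradients unreliable, and at the
  coarsest level the objective is cheap enough for direct search. The
  per-iteration trace is reported as its monotone envelope and a result
  worse than the start is never returned.
* **Deformable stage.** A control-point displacement field (spacing 4
  voxels) is tri-linearly upsampled to voxel resolution and optimized
  coarse-to-fine (40/25/0 iterations by default — the full-resolution
  level is initialized from below and not re-optimized). Descent
  directions are analytic gradients of the differentiable terms (RMS
  channels, LCC via the standard slowly-varying-window approximation, a
  global-correlation surrogate for the MI channel, and the smoothness
  subgradient); every step is accepted only if the *full* objective —
  including true MI and inverse consistency — decreases, with a
  backtracking step size, so per-level traces are non-increasing by
  construction and divergence cannot occur.
* **Penalty weights.** Identity 0.01, scaling 0.01, smoothness 0.1,
  inverse consistency 0.05, all exposed in `RegistrationConfig`. No
  weighting between similarity and penalty terms is prescribed by the
  objective's published form; these defaults keep the affine stage's
  identity bias below the 2% scale-recovery error observed on phantoms
  and leave the recovered fields diffeomorphism-friendly (positive
  Jacobian at ≥ 99% of voxels) while still letting the deformable stage
  move.

On (80, 114, 132) phantoms with six regions, rigid perturbations of 5° /
3 voxels are recovered within 0.3° / 0.1 voxel, affine scale factors of
(1.10, 0.95, 1.05) within 1.4%, and a combined rigid + 4-voxel smooth
nonrigid perturbation is reduced from mean region Dice 0.79 to 0.95 and
mean landmark deviation 3.0 to 0.7 voxels, in roughly 90 s on one CPU.
These problem sizes — 64³ cubes, (80, 114, 132) phantoms, 3-level
pyramids — are the package's standard test conditions.

## Quantification

Region density is the axon-voxel fraction of the region's voxel support
(unit-free); raw counts are emitted alongside so either normalization can
be used downstream. Hierarchy rollups sum counts bottom-up through the
region forest and recompute densities at each node; the operation is
idempotent. Labels present in a grid but absent from the table are pooled
under an `unknown` row; out-of-bounds points under a sentinel id. Heatmaps
are Gaussian-smoothed density volumes (mass-conserving away from borders)
with per-view maximum-intensity projections.

## Known limitations

* Whole brains are processed in memory; there is no out-of-core path for
  full-resolution (≈10¹⁰-voxel) volumes.
* The deformable optimizer is a local method: it refines after a correct
  rigid/affine initialization but will not recover large-displacement or
  topology-changing warps.
* The literal inverse-consistency term measures a volume against itself
  through Φ⁻¹; it regularizes field invertibility but is not a true
  source–target symmetry constraint.
* Style transfer itself (the generative model producing "atlas-style"
  brains) is out of scope; the style-proxy channel accepts any
  pre-computed normalized volume.
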