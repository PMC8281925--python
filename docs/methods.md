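# Methods

## Problem and model

Saccular intracranial aneurysms are monitored over years of follow-up
imaging; whether an aneurysm will grow is a surrogate for its rupture
risk. This package implements a baseline-shape-only prediction pipeline:
from a 3D angiographic volume it extracts a vascular surface mesh, from
an isolated aneurysm dome it computes five morphologic indices, and it
compares four classifier families — univariate thresholding of a single
index, a random forest, a multilayer perceptron, and a point-cloud deep
network — under a common stratified cross-validation protocol with
ROC/AUC reporting. Because clinical growth-surveillance cohorts are
small and rarely shared, the package includes a synthetic cohort
generator that reproduces the statistical structure such an analysis
assumes: two classes that differ in surface irregularity but not in
size.

## Morphologic indices

For a dome mesh open at the neck, with neck plane fitted to the boundary
loop by total least squares:

- **HMAX** (mm): maximal distance from the neck centroid to any dome
  vertex. An alternative size reading, perpendicular height, is the AR
  numerator, so both conventions are available.
- **V** (mm³): divergence-theorem volume of the dome closed by a
  triangle fan over the neck loop.
- **SA** (mm²): area of the open dome surface only. The fan cap is an
  artefact of closure and is excluded; including it would move the
  hemisphere's NSI from 0 to 1/3.
- **NSI** = 1 − (18π)^(1/3) · V^(2/3) / SA. With the conventions above
  an exact hemispherical dome scores 0 (the identity
  (18π)^(1/3)(2πr³/3)^(2/3) = 2πr² holds exactly); elongation, surface
  roughness and lobulations raise it.
- **AR**: perpendicular dome height over neck width, where neck width is
  the caliper (maximal pairwise projected) diameter of the neck loop —
  robust to non-circular necks.

All five are rigid-motion invariant; V, SA, HMAX scale as s³, s², s and
NSI, AR are scale-free. Each definition sits behind its own function so
a different convention can be swapped in.

## Segmentation

`vesselness_filter` computes scale-normalised Hessian eigenvalues in
physical units (anisotropic spacing handled by per-axis sigmas) and by
default applies the volume-ratio response, which is bounded in [0, 1]
and — deliberately — keeps rounded, aneurysm-like bright structures
enhanced rather than suppressing them as classic tubularity filters do.
A Frangi-style response with blob suppression is available as
`response="frangi"`. The original and filtered images are thresholded
(explicit values, or Otsu for non-interactive runs) and merged by
logical OR; 26-connected components with fewer than 60 voxels are
removed (exactly 60 survives); marching cubes at iso-level 0.5 plus
Taubin smoothing (λ = 0.5, ν = 0.53, 10 iterations) extracts the
surface. The Taubin pair is "non-shrinking" in the operational sense
that enclosed volume changes by well under 2% at these defaults; the
test suite checks this on a rasterized sphere. Note that the OR-merge
dilates masks by roughly the filter scale (the response is high in a
halo around bright structures); thresholds near 1 keep the halo thin.

## Synthetic cohort generator

A dome is a unit-sphere cap cut at the plane that realises the requested
neck-to-diameter ratio, perturbed radially by (i) a smooth random field
(sum of six low-frequency plane-wave cosines, unit RMS) scaled by the
irregularity amplitude and (ii) a configurable number of Gaussian bumps
(lobulations) whose amplitude scales with the same parameter. The
perturbation is tapered to zero at the neck, so the neck stays an exact
planar circle, and the dome is rescaled afterwards so that its maximal
extent from the neck centroid equals the sampled size — irregularity
changes shape, never size, which makes the two classes size-matched by
construction and the size distribution class-independent.

Cohort defaults emulate a small surveillance cohort: 25 growing / 19
stable, sizes log-uniform over 1.4–12.2 mm, neck ratios 0.55–0.95,
0–3 lobulations. Per-case irregularity is the class amplitude
(growing 0.24, stable 0.07) times a Gamma(2, 1/2) multiplier (mean 1),
giving within-class heterogeneity; these amplitudes were chosen so that
an NSI threshold separates the classes only moderately (univariate AUC
around 0.6–0.7 on a 200-case cohort), i.e. the univariate regime the
analysis is designed to probe, while remaining configurable upward for
network experiments. Optionally each dome is fused onto a straight
parent-vessel tube by boolean union on a shared occupancy grid followed
by surface re-extraction — robust where mesh CSG fails on near-tangent
contact.

What the generator does **not** emulate: imaging noise and modality
intensity statistics, segmentation artefacts, anatomical vessel trees,
patient covariates, or any longitudinal change — class difference is
encoded purely as baseline-shape difference. Passing tests therefore
demonstrate that the pipeline recovers shape-encoded class structure,
not clinical performance.

`rasterize` voxelises a watertight mesh by crossing-parity of voxel
centres along z-columns (exact up to grid resolution); a tiny irrational
origin offset avoids rays through vertices or edges.

## Classifiers

- **Univariate threshold**: candidates are midpoints between consecutive
  sorted unique values plus both extremes, both directions; the accuracy
  maximiser wins, ties broken toward the smaller threshold then the ≥
  direction; a value equal to the threshold predicts growing. This is
  exactly equivalent to exhaustive search (property-tested). The
  headline univariate numbers are fitted in-sample on all cases for
  comparability with common practice — optimistically biased, and
  flagged as such; a cross-validated variant is also provided.
- **Random forest**: 100 trees, depth 3, information-gain (entropy)
  splits, bootstrap sampling, aggregated leaf posteriors
  (scikit-learn).
- **MLP**: two hidden layers of 100 units, LBFGS, learning-rate
  parameter 1e-4, behind a training-fold StandardScaler (quasi-Newton
  fitting over mm³-scale volumes next to unitless indices is otherwise
  ill-conditioned).
- **Point-cloud network**: implemented directly on NumPy (forward and
  analytic backprop). Surfaces are resampled by area-weighted face
  sampling with uniform barycentric placement; each point carries its
  face normal. Inputs are centred and scaled to the unit sphere (scale
  invariance by construction) and randomly rotated (full SO(3)) each
  epoch. Set-abstraction levels use farthest-point sampling seeded at
  the point farthest from the centroid (so sampling depends only on the
  point set, not its order), radius grouping capped at K nearest
  neighbours, shared linear-BatchNorm-ReLU stacks, and per-group max
  pooling; a global max-pool yields a 1024-d descriptor fed to a
  three-layer head with log-softmax output. Optimisation: momentum SGD
  (0.9), learning rate 0.005, weight decay 1e-4 ("decay rate" read as
  L2 weight decay, the conventional companion of momentum SGD; an LR
  schedule is the plausible alternative), negative log-likelihood loss,
  fresh surface resampling every epoch. Max pooling makes the output
  permutation invariant up to floating-point reduction order.

Two profiles: **full** (2048 points, two set-abstraction levels
(256 centroids, r 0.2, K 32) and (64, 0.4, 32), widths 6→64→…→1024,
head 512/256, batch 32, 200 epochs) and **desk** (256 points, one
set-abstraction level (64, 0.3, 16), same 1024-d descriptor, batch 16,
≤50 epochs) sized for single-CPU runs; architecture details beyond the
64-d local / 1024-d global widths are free choices recorded in
`NetworkConfig`. Grouping radii are in normalised units.

## Evaluation protocol

Stratified k-fold (default 4) assignment deals the class-permuted cases
round-robin with a counter shared across classes, so 44 cases (25/19)
give four folds of exactly 11 with growing counts {7,6,6,6}. Splitting
is case-level (the fold arithmetic implies it); when several aneurysms
share a patient this is a known leakage risk, and a patient-level
grouping can be layered on by the caller. Every model sees the same
folds and hyperparameters; out-of-fold scores are aggregated. ROC is
swept over all thresholds with tied scores grouped, so the trapezoidal
AUC equals the Mann-Whitney concordance (ties = ½; property-tested).
The reported accuracy/sensitivity/specificity triple is the
best-accuracy operating point on the aggregated test scores, with
accuracy ties broken toward higher sensitivity (growing is the positive
class; a missed future-growing aneurysm is the costlier error). Because
the threshold is chosen post hoc on test scores, this triple is an
optimistic summary; AUC is the threshold-free metric.

## Numerical choices and degenerate inputs

- Neck-plane fit rejects collinear loops; domes must have exactly one
  boundary loop (inferred from edges used by a single face).
- `volume` refuses open meshes and points the caller to `close_dome`.
- Vesselness treats curvature magnitudes below 1e-8 of the image
  dynamic range as flat (a constant image scores 0 everywhere).
- Rasterisation requires watertight input and errors on empty
  interiors; batch norm layers are never hit with a batch smaller than
  two (trailing mini-batches are merged).
- Seeds propagate through `numpy.random.SeedSequence`; every generator
  and training routine is a pure function of its arguments including
  the seed.

## Scaled-down study sizes

The bundled acceptance study uses a 120-case cohort (68/52) with
irregularity contrast 0.25 vs 0.0, the desk network profile, and 4-fold
CV, plus a permuted-label null through the identical pipeline; these
sizes keep a full run in the minutes range on one CPU while leaving the
class-recovery signal far from the decision boundaries. The test suite
re-computes its statistical checks at similar or smaller sizes with
fixed seeds.

## Known limitations

- The synthetic classes are separable by construction at high contrast;
  absolute metric values on synthetic cohorts say nothing about
  clinical cohorts.
- The in-sample univariate protocol and the post-hoc operating point
  are optimistically biased (kept for comparability, labelled in the
  report).
- The volume-ratio vesselness response saturates inside and around any
  bright structure; segmentation quality depends on threshold choice,
  which the package exposes rather than hides.
- The NumPy network trains on CPU only; the full 2048-point profile is
  functional but slow, and the desk profile is the default for
  experimentation.
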