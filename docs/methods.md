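# Methods

`wmgm4d` segments white matter (WM) and gray matter (GM) in contrast-enhanced
4D CT of the brain. The pipeline has four stages — intracranial segmentation,
coarse CSF/vessel masking, per-voxel feature extraction, and SVM voxel
classification — all operating on, or around, a single low-noise 3D image
derived from the 4D series: the exposure-weighted temporal average (WTA).
A synthetic 4D head phantom with exact voxel truth makes every stage testable
without patient data. This note records the models, the defaults, and the
numerical and design choices, so that what the test suite does and does not
demonstrate is explicit.

## Weighted temporal average

A 4D protocol acquires N volumes with exposures E_i. Quantum noise dominates
clinical CT and its standard deviation scales as σ_i ∝ 1/√E_i. For weights
ω_i on the simplex, the averaged image has variance σ²_WTA = Σ ω_i² σ_i²,
minimised by reciprocal-variance weighting ω_i = (1/σ_i²)/Σ(1/σ_j²), which
under the 1/√E law reduces to exposure weighting ω_i = E_i/ΣE_i and gives

    σ²_WTA = 1 / Σ_i (1/σ_i²)  =  k²/ΣE_i   (for σ_i = k/√E_i).

Two consequences are exposed as tested properties: no simplex weighting beats
the optimal weights (checked against 10⁵ random weight vectors), and σ_WTA
depends only on the *total* exposure, not on how it is split across
acquisitions (checked analytically and by simulation at 10⁵ voxels). The
squared form σ²_WTA = 1/Σσ_i⁻² is the only dimensionally consistent one and
is used throughout (a variance, not a standard deviation, is harmonically
averaged).

## Acquisition protocol

The stroke protocol is built in: one 200 mAs volume at t = 0; after 4 s,
13 volumes every 2 s at 100 mAs; then 5 or (with the late contrast phase) 10
volumes every 5 s at 75 mAs — 19 or 24 acquisitions, 1875 or 2250 mAs total.

## Digital head phantom

The generator emulates the properties the pipeline depends on, with simple
nested-ellipsoid geometry (default 96×96×64 voxels at 1 mm isotropic):

* skull shell (1000 HU, 4 mm thick) around the intracranial space;
* subarachnoid CSF layer (1.5 mm) plus two ventricles, joined by thin
  channels into one 26-connected CSF space, as in real anatomy;
* a 4 mm cortical GM ribbon and two deep GM nuclei around a WM core
  (baselines 45 / 35 HU — the small soft-tissue contrast that makes the
  problem hard in CT);
* three tubular vessels (~1 % of the intracranial volume);
* gamma-variate enhancement curves per tissue — peak `amplitude` at
  `ttp`, sharpness set by `(ttp/width)²`; GM enhances more and earlier than
  WM (12 HU at 14 s vs 6 HU at 16 s), vessels strongly (150 HU at 12 s);
* per-volume zero-mean Gaussian noise with σ = k/√E_i, k = 50 HU·√mAs,
  i.e. σ ≈ 3.5/5/5.8 HU at 200/100/75 mAs and σ_WTA ≈ 1.15 HU for the
  19-acquisition protocol. Gaussian is an adequate model for quantum noise
  at clinical photon counts; only the σ–exposure relation is load-bearing.

HU baselines sit in standard radiological ranges (air −1000, water 0,
CSF ≈ 4, WM ≈ 35, GM ≈ 45, blood ≈ 50 HU). Tissue fractions matter: the
coarse CSF threshold μ − 1.96σ (below) can only sit above the CSF mode if
the CSF fraction f of the intracranial histogram satisfies f < 1/1.96²,
since σ² ≥ f·(μ − CSF)². The defaults give f ≈ 0.14, matching the ~10–15 %
CSF fraction of real heads; a phantom with a much thicker CSF layer would
make that thresholding rule infeasible on principle, not merely fail here.

A variant generator (`temporal_contrast_only_spec`) equalises WM/GM baselines
and rescales the WM enhancement so both tissues have the same
exposure-weighted mean enhancement: the WTA then carries no WM/GM intensity
contrast and only the curve *shapes* (and spatial context) separate the
classes. It is the controlled condition for quantifying what temporal
features add.

What the phantom does **not** emulate: cortical folding, partial-volume
mixing at tissue interfaces, beam hardening, scanner PSF, streak/ring
artifacts, pathology, or anatomical variability. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise and
contrast model, not clinical-grade accuracy; the phantom's crisp boundaries
and exact labels make the classification task easier than patient data.

## Rigid and affine registration on bone

Each time point is rigidly aligned to the first on the skull: threshold at
600 HU, keep the largest 26-connected component, then minimise the
mean-squared intensity difference inside the (slightly dilated) fixed bone
mask with a 4-level Gaussian pyramid (8/4/2/1 voxel shrink), centre-of-gravity
initialisation and regular-step gradient descent (≤500 iterations/level),
via SimpleITK. An affine variant (200 HU mask, 5 levels) stands in for
inter-subject alignment. If optimisation does not improve on the identity,
the identity is returned with a warning. Random perturbations within
±4 voxels/±5° are recovered within 0.5 voxel/1° on the default phantom even
across time points with different noise and contrast. HU volumes are
resampled linearly (out-of-grid → −1000 HU), label masks with nearest
neighbour.

## Geodesic active contour refinement

The intracranial mask is refined as the zero set of a levelset Φ (negative
inside) evolved with propagation, curvature regularisation and edge
attraction, driven by the speed g(I) = exp(−(‖∇I‖/γ)²) with Gaussian
derivatives at scale 1 voxel and γ = 80 (an HU/mm gradient scale: soft-tissue
edges of tens of HU/mm keep g ≈ 1, the ~400 HU/mm skull edge sends g → 0).
Defaults: curvature weight ε = 1, advection weight α = 5, erosion radius 3,
≤250 iterations, RMS stop 0.001, narrow band 9 voxels.

Numerical choices (none are prescribed by the model itself):

* **Sign conventions.** With Φ < 0 inside and an initialisation *eroded
  inside* the target, propagation is outward: Φ_t includes −g|∇Φ|. The
  curvature term enters as +εgκ|∇Φ| (κ = div(∇Φ/|∇Φ|) is positive on convex
  interiors in this convention, and smoothing must oppose outward motion
  there), and the advection term as +α∇g·∇Φ — the *attracting* form, which
  pulls the front into minima of g from both sides and holds it at the edge
  centre. The opposite advection sign turns the edge into a soft barrier the
  front stalls against ~2 voxels early; the attracting form is what the
  canonical implementations integrate and what reproduces sub-voxel boundary
  locking (intracranial Dice > 0.99 on the phantom).
* **Discretisation.** Osher–Sethian upwind for propagation and advection,
  central differences for curvature (κ clipped to ±1/voxel); replicated
  edges at the grid border; grid units are voxels, assuming near-isotropic
  spacing.
* **Time step.** CFL-bounded: dt = 0.45 / (3·g_max + 6ε·g_max + α·Σ_axis
  max|∂g|) — hyperbolic, parabolic and advective contributions.
* **Narrow band.** Updates are restricted to |Φ| ≤ 9 voxels; on a 32³
  problem the banded and full-grid evolutions agree to <0.01 near the zero
  set.
* **Reinitialisation.** Every 20 iterations Φ is restored toward a signed
  distance by ten Godunov upwind sweeps of Φ_τ = sign(Φ)(1−|∇Φ|). A
  binarise-and-distance-transform reinit would quantise the interface to
  voxel boundaries and, at dt ≈ 0.02, erase all sub-voxel progress each
  period — the PDE form preserves the interface position.
* **Degenerate outcomes.** Zero speed converges at iteration 1 with Φ
  unchanged; an empty interior is returned with an explicit
  `ContourCollapseWarning`, never silently.

## Coarse CSF and vessel masks

Within the refined intracranial mask, μ and σ of the WTA histogram restricted
to [0, 400] HU define an upper CSF threshold μ − 1.96σ and a lower vessel
threshold μ + 1.96σ. Each threshold mask is eroded by a radius-1 ball
(removing isolated noise voxels) and re-grown to every 26-connected
thresholded voxel; the CSF mask is additionally closed (radius 1). Slight
over-segmentation is by design — what remains must be pure WM/GM. The two
masks are disjoint by construction (thresholds 3.92σ apart). On the phantom
the CSF and vessel recalls exceed 0.99.

## Feature extraction (10 + 6 + 104 = 120)

Per soft-tissue voxel: intensity features of the WTA (raw; Gaussian scale
space at 1/2/4 mm; gradient magnitude at 1/2/3 mm; local contrast-limited
adaptive histogram equalisation at window radii 5/10/15 voxels, clip limit
α = 0.3 blended with weight β = 0.5 onto a fixed 0–100 HU display
normalisation); contextual features (per-axial-slice 2D distance to skull
[WTA > 200 HU, largest component], CSF and vessels, each normalised by the
slice's maximum distance over intracranial voxels and clipped to [0, 1],
with empty-structure slices set to 1; cumulative intracranial volume
fraction along x, y, z); temporal features from the first 14 time points
(each time point raw and spatially smoothed at 1/2/4 mm = 56; temporally
smoothed at 1/2/4 s = 42; area under the temporal-gradient-magnitude curve
at derivative scales 1/2/4/6/8 s by the trapezoidal rule = 5; time to first
peak = 1). Restricting to 14 time points keeps the feature count identical
across protocol variants.

Temporal filtering operates on curves first linearly resampled to a uniform
1 s grid (times in absolute seconds from the first acquisition), since the
protocol is irregularly sampled; smoothed values are read back at the
acquisition times. Time-to-first-peak is the first interior local maximum of
the 1 s-smoothed curve, falling back to the global maximum for monotone
curves — an interpretation choice; unsmoothed curves give noise peaks.

Features are z-scored with *training-set* statistics; test matrices always
use the stored training mean/std (zero-variance columns clamp std to 1 with
a warning). Column order is fixed and carried in the feature names so
trained models remain applicable.

## Voxel classification

A soft-margin SVM with Gaussian RBF kernel (squared-norm form, the LIBSVM
kernel) labels WM as background (0) and GM as foreground (1). Defaults
C = 2¹⁰, γ = 2⁻¹¹. Probabilities come from the sigmoid (Platt) calibration
fitted to decision values — for two classes the pairwise coupling degenerates
to that sigmoid. Training uses a stratified 1 % voxel subsample (minimum 10
per class, seed-reproducible). Hardening thresholds P(GM) at 0.5, so WM and
GM partition the soft-tissue mask. The exhaustive grid search covers
C ∈ 2⁴…2¹⁵ × γ ∈ 2⁻¹⁶…2⁻⁵ (144 stages) on an 80/20 split of one training
fold, scoring A_z on decision values (monotone-equivalent to calibrated
probabilities and cheaper than per-stage calibration).

## Evaluation

Per structure: Dice; absolute volume difference (% of reference); and
boundary distances in mm between boundary voxels (voxels with a
face-adjacent background neighbour — 4-adjacency in 2D, 6 in 3D): Hausdorff
(max of directed maxima), modified Hausdorff (max of directed means), 95th
percentile HD, and contour mean distance implemented as the symmetric mean
of the two directed means (the directed/symmetric ambiguity is resolved
symmetric). All distance metrics match an all-pairs brute-force oracle to
1e−9 and scale exactly with voxel spacing. For slice-based references the
metrics are computed per axial slice in 2D and aggregated by mean (DC, CMD,
AVD) or maximum (HD, MHD, HD95); slices with an empty mask on either side
are skipped and logged. Folds are reported as mean ± std.

ROC analysis pools the per-fold soft classifications into one curve
(trapezoidal A_z). Bootstrap comparison of two feature sets resamples voxels
with replacement (50 000 resamples by default; paired indices when both
score the same voxels), reports 95 % percentile intervals, and a two-sided
p-value from the tail mass of the ΔA_z distribution around zero with a
+1/(B+1) correction.

## Pipeline and cross-validation

`process_case` runs phantom/series → (optional motion correction) → WTA →
GAC intracranial refinement (initialised from the case's coarse mask — for
phantoms, the truth intracranial mask standing in for an atlas propagation)
→ coarse masks → feature images → raw feature matrix. Intermediate volumes
are cached beside a provenance stamp (hash of the image-stage configuration
plus seed); re-running reloads them bit-identically and a changed
configuration invalidates the cache. Leave-one-out cross-validation samples
training voxels, fits normalization statistics and the SVM on the training
folds only (verified by recomputing the statistics independently of the test
case), evaluates the held-out case slice-wise, and pools fold probabilities
into the merged ROC. Fold seeds derive deterministically from the global
seed and fold index. The `no_temporal` variant drops the 104 temporal
features (16 remain).

## Problem sizes and defaults used in validation

The validation suite and the reproduction script use the default 96×96×64
phantom for levelset, registration and cross-validation experiments
(3 cases, ~126 000 soft-tissue voxels each), 48³ phantoms for unit-level
checks, 10⁵-voxel noise fields for the exposure-split simulation, 10⁵ random
weight vectors for the optimality check, and 1000–2000 bootstrap resamples
in tests (the library default remains 50 000). On these conditions the
pipeline reaches intracranial Dice > 0.99, held-out voxel AUC > 0.99 and
WM/GM Dice ≈ 0.99, and the full feature set strictly exceeds the no-temporal
variant on temporal-contrast-only phantoms (≈ 1.00 vs ≈ 0.99 AUC) — numbers
that reflect the phantom's idealised geometry, not expected clinical
performance.

## Known limitations

* The phantom's crisp label boundaries avoid the partial-volume mixing that
  dominates errors in real WM/GM segmentation; absolute metric values are
  optimistic.
* The levelset assumes near-isotropic voxels (units are voxels).
* The affine inter-subject path is exercised structurally but no atlas is
  shipped; phantom truth substitutes for atlas propagation.
* Distal vessels below the erosion radius and CSF thinner than ~2 voxels
  survive only through connectivity to larger CSF/vessel structures.
* `SVC(probability=True)` carries scikit-learn's internal 5-fold Platt
  calibration; probabilities are therefore not strictly monotone in the
  decision values at the 1e−3 level (the hardened masks and A_z are
  unaffected).
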