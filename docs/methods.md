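# Methods

This note documents the models, conventions, and design choices behind
`subsolidseg`, in the spirit of a methods appendix: what the pipeline
assumes, which knobs matter, what the synthetic phantoms do and do not
emulate, and where the numerical edges are.

## Problem statement and model

Given a CT volume `I` (Hounsfield units, arbitrary source spacing) and a
binary nodule mask on the same grid, every nodule voxel is assigned one of
three tissue classes: **vessel** (1), **solid core** (2), **ground-glass**
(3). Two priors drive the design:

* *Appearance*: ground-glass is hazy attenuation (≈ −600 HU) through which
  vessels stay visible; vessels and cores share soft-tissue attenuation
  (≈ 0–100 HU) and are separable mainly by 3D shape — tubes versus blobs —
  captured by the Hessian eigenvalue spectrum at multiple scales.
* *Anatomy*: a vessel inside a nodule must connect to a vessel entering the
  nodule, and its calibre cannot exceed that of the entering vessel, because
  vascular trees taper smoothly from hilum to periphery.

The classifier handles appearance; the vascular-continuity step enforces the
anatomical prior as a post-hoc attenuation of the vessel likelihood.

## Conventions

* Arrays are indexed `(z, y, x)`; `spacing`/`origin` tuples use the same
  order. SimpleITK's `(x, y, z)` metadata is converted only at the IO
  boundary.
* Grids are node-aligned: voxel `i` sits at `origin + i * spacing`.
  Resampling to target spacing `t` produces `round(extent / t)` samples per
  axis and clamps out-of-range coordinates to the edge; the rule is recorded
  in `Volume.meta`.
* Label legend is fixed package-wide: 0 background, 1 vessel, 2 core,
  3 ground-glass.
* Argmax ties break by class priority ground-glass > vessel > core:
  ground-glass is the default tissue of a subsolid nodule, and conservative
  core calls match the method's specificity-leaning behaviour.
* Connectivity: 26-connectivity for detection components and for
  inner-to-outer vessel adjacency (boundary voxels meet diagonally after
  resampling); 6-connectivity for splitting the inner vessel set (stricter,
  so thin diagonal contacts do not merge distinct vessels).

## Standardization

Scans are resampled to 0.5 mm isotropic (trilinear; labels nearest-neighbour)
and band-normalized. The band decomposition uses difference-of-Gaussian
bands at σ = 0.5, 1, 2, 4 mm plus the coarsest low-pass as residual; the sum
of bands and residual reconstructs the input exactly, so an all-ones gain
profile is the identity. Band gains are estimated from a sharp-kernel and a
soft-kernel reference population as the square-root energy ratio, refined by
a short fixed-point iteration so that *applying* the profile reproduces the
reference band energies (adjacent DoG bands overlap; without the refinement
the plain ratio absorbs cross-band leakage — measured as a spurious 1.6×
"gain" on an untouched band). Energy is the sum of squared band values,
restricted to a body mask when one is supplied, since air outside the body
otherwise dominates. The profile is stored with the trained model so
training and test scans are normalized symmetrically.

## Features

17 per-voxel features on the standardized grid: per scale σ ∈ {1, 2, 4} mm
the Hessian eigenvalues sorted by decreasing magnitude (signs retained —
bright tubes have two large negative eigenvalues, bright blobs three) and
the gradient magnitude (12 columns); raw HU; smoothed HU per scale (3); and
the standard deviation over the 26-neighbourhood including the centre voxel
(27 values; edge voxels use what exists). Derivatives are Gaussian
derivatives at physical scale, truncated at 4σ; the volume mean is
subtracted before Hessian filtering because the sampled second-derivative
kernels do not sum exactly to zero and would otherwise leak a constant
offset into the eigenvalues. The gradient block is interpreted as gradient
*magnitude* per scale, keeping the descriptor rotation-robust.

## Classifier and operating point

Training samples are balanced by downsampling every class without
replacement to the minority-class size, with per-nodule quotas as equal as
the per-nodule availability permits (water-filling; remainder spread one at
a time). The classifier is kNN with k = 150 over z-scored features and
Euclidean distance; posteriors are neighbour class fractions. Feature
scaling and the distance metric are package choices (HU and eigenvalue
scales differ by orders of magnitude, making unscaled distances degenerate)
and are stored with the model. For small training sets k is clipped to the
sample count with a logged warning.

The operating point (w_v, w_c, w_g) scales the posteriors before the
argmax. It is found by exhaustive search over the simplex lattice with step
0.01, minimizing hard-label disagreement on out-of-fold posteriors from
grouped (per-patient / per-phantom) cross-validation; ties prefer the triple
nearest uniform, then lexicographic order. Two aspects of the objective are
deliberate:

* **Reference.** The phantom training harness scores the grid search against
  the *full* truth maps of held-out training nodules rather than the sparse
  annotations: equal-per-class annotations oversample thin classes relative
  to their voxel share and would bias the operating point towards
  over-calling them.
* **Class damping.** Each reference voxel of class c is weighted by
  `1 / n_c^0.3`. The exponent interpolates between pure voxel-population
  risk (α = 0, which under-calls thin vessels because ground-glass dominates
  the count) and fully class-balanced risk (α = 1, which over-calls them);
  0.3 was tuned empirically on held-out phantom experiments, in the same way
  the continuity cutoff a = 3 is an empirically tuned constant. It is a
  `PipelineConfig` field.

Solitary-voxel smoothing runs once, on a snapshot, in lexicographic order: a
masked voxel with no same-label neighbour in its masked 26-neighbourhood
takes the majority neighbour label; majority ties go to the largest summed
likelihood among the tied classes.

## Vascular continuity

The initial vessel set is split into 6-connected components with
deterministic ids (ordered by first voxel in scan order). Outside vessels
are 26-connected components of the outer vessel mask; the *vascular tree* is
the set of outer components with at least 10% of the largest component's
voxels — large enough to exclude segmentation noise while admitting several
major vessels. An entering vessel must be 26-adjacent to the inner
component and belong to the tree; among candidates the largest mean calibre
near the nodule border wins (ties: more voxels, then smaller id).

Diameters use the local-thickness definition: `d(x) = 2·max{r(y) :
|x−y| ≤ r(y)}` over the inscribed-sphere radii `r` from the Euclidean
distance transform of the union of inner and outer vessel voxels (the union
keeps calibre from being clipped at the nodule boundary). `d_out` averages
the thickness over the entering vessel's voxels within 2 mm of the nodule
border, restricted to the central voxels (distance transform at least half
the local maximum): the surface shell of a digitized tube otherwise biases
the estimate low, which would spuriously penalize true vessels. With this
estimator a constant-calibre tube gets `d_in ≈ d_out` on its axis and
`d_in < d_out` at its surface, so w_vc = 1 across the tube.

Components with no entering vessel receive w_vc = 0 (configurable): the
continuity premise makes unattached soft-tissue blobs anatomically
implausible as vessels. Voxels never labeled vessel keep w_vc = 1. The
final labels re-run the weighted argmax with `L_v = w_v · w_vc · P_v`
(core and ground-glass unchanged — hence the final vessel set is a subset of
the initial one before smoothing) and smoothing is re-applied.

The default outside-vessel segmenter is a multi-scale Sato tubularity filter
(σ = 0.75, 1.25, 2 mm) thresholded at 60 with a −600 HU guard, restricted to
the ROI minus the nodule. It is a simple built-in adequate for
high-contrast vessels; any external binary vessel segmentation supplied via
`vessel_mask` bypasses it and takes precedence.

## Pipeline grids

All label logic — Eq-style weighted argmax, smoothing, continuity — runs on
the standardized isotropic grid, where diameter estimation is well defined.
Posteriors are then interpolated trilinearly back to the source grid and
renormalized, and the final source-grid labels are obtained by re-running
the weighted argmax there with the continuity weights carried over by
nearest neighbour. Relabeling from interpolated posteriors places the class
boundary with sub-voxel consistency and measurably outperforms
nearest-neighbour label transfer.

## Synthetic phantoms

A phantom scene is lung parenchyma at −900 HU, a ground-glass ellipsoid at
−600 HU, soft-tissue structures at +50 HU (tubular vessels swept along
spline paths with a linearly tapering diameter profile, and an optional
spherical core), partial-volume blur (Gaussian, σ 0.6 mm), and additive
Gaussian noise (σ 20 HU), rasterized on an anisotropic source grid of
1.0 × 0.7 × 0.7 mm — the resolution regime of low-dose screening CT. Truth
labels are assigned on the *pre-blur* geometry (a partial-volume voxel
inherits its geometric class, mirroring how an annotator outlines
structures), with precedence core > vessel > ground-glass. Cohorts cycle
through four strata — non-solid and part-solid, each with and without
crossing vessels — and record every sampled parameter in a manifest.

Default geometry ranges: nodule radii 5.5–8 mm per axis (11–16 mm diameter),
core radius 45–60% of the smallest nodule radius (≈ 5–9.6 mm diameter,
placed eccentrically as part-solid cores typically are), vessels 2.2–3.2 mm
in diameter tapering to 85–100%. Vessel paths are rejection-sampled to keep
clearance from the core sphere and from each other: real crossing vessels
are distinct branches, and a vessel piercing the core — or two tubes forming
an X inside the nodule — makes the classes locally undecidable for any
intensity-and-shape classifier, which would test annotation ambiguity rather
than the method. The ranges are chosen so that every structure is resolvable
at the blur and grid of the phantom (a structure thinner than ~2 mm against
0.6 mm blur and 1 mm slices has no recoverable boundary); they emulate the
appearance of screen-detected subsolid nodules, not any particular cohort.

Sparse annotations emulate an expert marking a few hundred voxels per class:
samples are drawn uniformly per class, stratified over each class's
26-connected components (every vessel and core contributes approximately
equally), so structures of multiple sizes are represented.

What the phantoms do **not** emulate — and hence what passing tests do not
show about real data: irregular and lobulated nodule shapes, bubble-like
lucencies ("complex" nodules are outside the method's scope), airways,
vessel branching inside the nodule, scanner-specific kernel/noise texture,
and annotation disagreement between human readers. Phantom scores are
best-case figures for geometry the model class can represent.

## Evaluation protocol

* **Detection**: a class counts as detected when a 26-connected component of
  ≥ 2 voxels exists. Pairs of raters are compared per class in a 2 × 2
  table: accuracy, sensitivity, specificity, precision, and Cohen's
  κ = (p_o − p_e)/(1 − p_e) with a 95% CI from the asymptotic standard error
  √(p_o(1 − p_o)/(n(1 − p_e)²)) — a closed-form choice, flagged in report
  metadata. Degenerate tables (p_e = 1, empty margins) yield NaN rather
  than a fabricated value.
* **Voxel scores**: per nodule and class, sensitivity |P∩R|/|R|, precision
  |P∩R|/|P|, Dice 2|P∩R|/(|P|+|R|), on the axial slice with the largest
  nodule cross-section (ties: smallest index) or in full 3D. If exactly one
  of prediction/reference lacks the class, all three scores are 0 for that
  nodule; if both lack it, the row is excluded from aggregates and flagged.
* **Consensus standards** intersect two raters' labels; disagreement voxels
  fall back to ground-glass inside the nodule. Summaries report mean and
  sample SD (ddof = 1, stated in the report header) twice: over all
  scoreable nodules and over the presence-agreement stratum, with n per
  cell; empty strata are undefined, not zero.

## Problem sizes

The shipped experiments run at phantom scale: 5 training + 5 held-out
phantoms (~2,000 annotation voxels, k clipped only if the balanced set drops
below k) for parameter recovery, and a 16-phantom balanced cohort for
detection agreement. These sizes exercise every code path — balancing,
grouped cross-validation, the full weight grid at step 0.01, continuity with
attached and unattached components — while a complete acceptance run stays
within a few minutes on one CPU.

## Known limitations

* kNN with k = 150 over a ~2,000-sample training set smooths posteriors over
  7.5% of the data; boundary placement for the thinnest vessels is the first
  casualty. Larger annotation sets would sharpen it.
* Diameter estimates on digitized thin tubes carry ±1 voxel uncertainty;
  w_vc is robust to this because d_in and d_out share the bias, but absolute
  calibres below ~2 voxels are unreliable.
* The default tubularity segmenter is deliberately simple; for real scans an
  external lung-vessel segmentation should be supplied.
* The three-class model cannot represent bubble-like lucencies or other
  "complex" morphology; such nodules are out of scope by design.
* Missed outside vessels cannot be recovered: a true vessel whose entering
  vessel is absent from the outer segmentation is penalized as unattached.
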