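# Methods

## Problem setting

A dense phenotyping pipeline maps a fixed-topology template mesh onto each
subject's bone surface so that template vertices (quasi-landmarks) are in
anatomical correspondence across subjects. Its validity is established by
comparing the landmarks it produces automatically (CALs) with manual expert
indications (MLs) under a repeated-measures design: several observers, several
repetitions, several automatic mapping rounds, two samples (anatomically
unaltered mandibles and surgically altered, "operated" ones). Because real
CBCT-derived surfaces cannot be redistributed, the package ships a synthetic
mandible generator with exact ground truth; all tests and the study replica
run on it.

Coordinates are millimetres throughout; vertex indices are 0-based.

## The mapping chain

`map_mandible` composes three stages.

1. **Similarity initialization** from five crudely indicated positioning
   landmarks (left/right lateral condylar poles, left/right gonion, chin
   protuberance): the closed-form least-squares similarity fit
   (Kabsch–Umeyama) with reflections excluded by construction. Degenerate
   (collinear) configurations raise rather than fall back.
2. **Rigid ICP refinement**: alternating exact closest-point correspondence
   and closed-form rigid updates; scale stays frozen at the stage-1 value.
   Convergence when the RMS correspondence distance improves by less than
   1e-6 mm (cap 100 iterations); the recorded objective trace is
   non-increasing.
3. **Non-rigid registration** (`nonrigid_register`), described next.

### Non-rigid registration

A visco-elastic non-rigid ICP with these elements per iteration:

* **Push channel** — each floating (template) vertex is matched to its exact
  globally closest point on the target surface.
* **Pull channel** (symmetric correspondence) — each target vertex projects
  onto the floating surface and votes its displacement barycentrically to the
  three vertices of the matched floating face.
* **Inlier weighting** — weights combine normal agreement (clamped cosine
  between floating and target normals) with a robust distance term: full
  weight within `inlier_kappa` robust scales, Gaussian taper beyond. The
  robust scale is floored at mean+std of the current distances; a pure
  MAD-type scale collapses once most of the mesh touches the target and then
  misclassifies genuine residual deformation as outliers.
* **Regularized update** — the desired positions (current + weighted
  displacement) are smoothed by confidence-weighted *linear
  moving-least-squares* fits: per vertex, an affine map from the undeformed
  neighborhood to the desired positions, evaluated at the vertex. Linear fits
  propagate stretch and rotation from curvature-rich regions into featureless
  ones; a weighted *mean* smoother cannot, and in our experiments leaves a
  ~2 mm tangential drift that no schedule removes.
* **Annealing in physical units** — the Gaussian bandwidth of the smoother
  anneals geometrically from `elasticity_start` (8 mm) to `elasticity_end`
  (2.5 mm) over the first half of the iterations, then holds. Parameterizing
  the schedule in millimetres (not neighbor counts) makes behaviour
  resolution-independent; the k-nearest stencil (`smoothing_neighbors`, 96)
  only bounds the kernel support.
* **Affine warmup** — 30 iterations of global affine ICP before the local
  stage absorb smooth global stretch/shear cheaply.
* **Divergence guard** — an error (with the objective trace attached) if the
  mean vertex-to-target distance exceeds 1.05× its running best for more than
  10 consecutive iterations; tolerances below 1e-4 mm are ignored as
  numerically meaningless.

Defaults (200 iterations, bandwidths 8→2.5 mm) were fixed against the
synthetic populations described below: on a 2562-vertex template deformed by
a smooth 3 mm (mean) displacement field they give a mean ground-truth
correspondence error of 0.23–0.31 mm across seeds with ~0.01 mm residual
surface distance, at ~40 s per registration on one core. The study replica
uses 100 iterations on 642-vertex meshes (~4 s per mapping, GT error
~0.29 mm), which is ample for its ordering-level questions.

Two alternatives were evaluated and rejected: a curvature-signature
correspondence channel (deformation changes curvature by ~12%, so the
channel's fixed point is biased away from the true correspondence and the
iteration diverges) and a quadratic MLS basis (flexible enough to restore the
tangential drift the linear fit suppresses).

### Generalized Procrustes analysis and template averaging

`generalized_procrustes` iterates similarity fits against an evolving
consensus normalized to unit centroid size; fitted scales are returned so
original sizes stay recoverable. The consensus seed is the centered mean of
the inputs (falling back to the first configuration if that mean is
degenerate), which makes GPA an exact no-op on its own aligned output.
Convergence: consensus movement below 1e-9. `build_template` GPA-aligns
correspondence maps, averages vertex-wise, and rescales the consensus to the
mean input centroid size so templates stay in millimetres.

## Landmark transfer

A manual landmark is embedded as the barycentric address of its closest point
on the mapped (template-topology) surface; the same address names a template
location. Training a template landmark averages the training MLs'
template-space positions arithmetically and projects the average back onto
the template surface by closest point (ties broken toward the lowest face
index). No re-alignment is needed because all addresses live on one fixed
template. The accuracy assessment uses leave-one-out training (the target is
structurally excluded from its own training set, enforced on the record
type); the repeated-measures reliability assessment trains on the full
sample, independently per sample, since it compares mapping rounds rather
than methods.

## Statistics

* **RMS-to-centroid** of repeated indications; reliability tables aggregate
  per-landmark RMS over mandibles and summarize over the 26 landmarks with a
  t-based 95% CI (25 df). The CI method is a package choice; bootstrap would
  be equally defensible.
* **Principal variation axes**: eigen-decomposition of the uncentered second
  moment of deviation vectors, so the variances sum to the mean squared
  deviation norm.
* **ML–CAL accuracy**: per-landmark descriptives of the Euclidean distance,
  with a final row holding the arithmetic mean of the per-landmark columns
  (the per-landmark-average convention, not a pooled recomputation).
* **Variance components**: balanced jaw × observer × method ANOVA by expected
  mean squares; for balanced data these equal restricted-maximum-likelihood
  estimates, which the test suite verifies against a direct numerical REML
  optimizer. Negative estimates are truncated to zero and flagged.
  Unbalanced layouts are rejected — this package supports the balanced
  validation design only.
* **Agreement**: SEM = √σ²_error, RC = 2.77 × SEM (the literal constant, not
  1.96√2), ICC = σ²_jaw/(σ²_jaw + σ²_error). The ICC denominator excludes
  the observer component because that convention reproduces the study's
  worked examples from its printed components; the observer-inclusive variant
  is available via `include_observer=True`.
* **Multivariate ICC**: per-dimension two-way subject × method decomposition;
  the statistic is trace(subject)/trace(subject+method+error) summed over the
  325 interlandmark distances. It reduces exactly to the univariate
  absolute-agreement ICC at dimension 1 (verified against an independent
  implementation) and equals 1 at perfect agreement. This trace construction
  is a documented stand-in for the original multivariate generalization,
  whose formula the validation study does not reproduce; published
  multivariate-ICC values are therefore not comparison targets.

## Synthetic data: what it emulates, and what it does not

The base shape is a radially perturbed subdivided icosahedron (base radius
45 mm) with condylar, coronoid, gonial and chin prominences, exactly
bilaterally symmetric, carrying the canonical 26 anatomical landmarks and the
5 positioning landmarks at labeled feature directions; landmark points lie
exactly on the triangulated surface. Seeded low-amplitude symmetric bumps
give each template seed an individual character.

* **Population variation**: members are the base plus a sum-of-Gaussian
  radial-basis displacement field, rescaled so the mean per-vertex
  displacement norm equals `amplitude` (default 2.5 mm; 3 mm in the
  correspondence-recovery experiments). The length scale defaults to 45 mm —
  half the bone extent — because dominant inter-individual mandibular modes
  (allometry, ramus/body proportions, intercondylar width, gonial angle) are
  half-to-full-structure wavelength. At much shorter length scales a stored
  correspondence becomes partially unidentifiable from geometry alone
  (tangential field components relabel the surface rather than reshape it),
  so correspondence-recovery results are only meaningful in the smooth
  regime. True landmarks ride along as fixed barycentric addresses;
  correspondence is vertex identity by construction.
* **Operated variant**: the anterior tooth-bearing region (anchored at the
  chin landmarks) is rigidly displaced inside a smoothstep band
  (14 → 30 mm), with a short-length-scale seeded perturbation peaking
  mid-band to mimic healed bone cuts.
* **Observers**: indication = truth + per-observer×landmark bias
  (sd 0.7 mm/coordinate) + per-repetition noise (sd 0.8 mm/coordinate),
  re-projected onto the surface. Projection suppresses the normal noise
  component, so the expected intra-observer RMS over r repetitions is
  ≈ σ√(2(r−1)/r) ≈ 0.92 mm at the defaults — inside the 0.75–1.2 mm range
  reported for trained observers, which is the calibration anchor. The noise
  is isotropic; real landmarking error is anisotropic along ridges (condylar,
  gonial and chin landmarks scatter most along the bony edge), so synthetic
  reliability tables match real ones in scale, not in per-landmark anisotropy.
* **Initialization jitter**: positioning landmarks get isotropic 3 mm-scale
  Gaussian jitter (default sd 2 mm) re-projected onto the surface; the three
  automatic mapping rounds of the study replica differ only in this jitter,
  attributing all automatic variation to the initialization phase.

Passing tests on these populations therefore demonstrate correctness of the
algorithms and statistics under smooth, closed, noise-controlled geometry;
they do not certify performance on segmented clinical surfaces with holes,
plates, or segmentation artifacts.

## Study replica and problem sizes

`run_study` defaults mirror the validation design: 30 unaltered + 20 operated
mandibles, 7 observers × 3 repetitions, 3 automatic mapping rounds, 26
landmarks — producing tables with the same row/column structure as the
published ones (9 reliability rows; 26+1 accuracy rows; variance/agreement
block; 7+1 multivariate-ICC rows). The test suite exercises a reduced replica
(6 unaltered / 4 operated mandibles on 642-vertex meshes) — the orderings it
asserts (automatic repeat RMS at least 10× below intra-observer RMS; errors
vanishing in the zero-noise limit) are scale-free, so the smaller sample is a
deliberate problem-size choice. Every statistic in a study report is
recomputable from the run's raw-data manifest; `validate_report` re-derives
all of them and compares at 1e-9.

## Numerical choices and edge cases

* Closest-point queries are exact: a KD-tree over face centroids prunes only
  faces provably farther than the current best (centroid distance minus the
  largest face circumradius); unpruned cases fall back to an exact radius
  search. Face ties break toward the lowest index.
* PLY is written as double-precision ASCII (the common float32 PLY encoding
  loses ~2e-6 mm at anatomical scale); OBJ round-trips below 1e-6 mm; binary
  STL is a float32 triangle soup and is contractually lossy on shared-vertex
  topology.
* Meshes need not be watertight or manifold; only index validity, non-zero
  face area (1e-12 mm² tolerance), and finiteness are enforced.
* Barycentric weights must sum to 1 within 1e-9 and are clipped to [0, 1].
* The degenerate principal-axes case (all-zero deviations) returns zero
  variances with an identity axis set and a flag rather than raising.
* All randomness flows through explicit integer seeds; study runs with equal
  configuration are byte-identical.

## Known limitations

* Tangential correspondence is recovered only through the interplay of
  curvature features and the linear-MLS prior; on surfaces or deformations
  without usable curvature variation the mapped correspondence can slide
  within the surface while the fitted geometry remains excellent.
* The non-rigid defaults are tuned for ~45 mm-radius single-bone surfaces;
  other anatomies will need `elasticity_start/end` rescaled.
* Statistics support the balanced validation design only; general unbalanced
  mixed models and between-sample hypothesis tests are out of scope.
* The template-and-target meshes of the synthetic study share a tessellation
  family; identical very coarse tessellations can lock correspondence
  artificially, so correspondence-recovery numbers are quoted at the
  2562-vertex scale where the effect is small.
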