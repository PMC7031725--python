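# Methods

This note documents the models, numerical choices and assumptions behind
`palsyflow`, and what the synthetic cohort does and does not establish
about real LSCI data.

## Morphable face model

Face shape is a PCA statistical model: `S = v̄ + Σ_i α_i σ_i v_i` with a
mean mesh `v̄` (N vertices), unit-norm deformation modes `v_i` stored
unscaled, and per-mode standard deviations `σ_i` stored separately, so the
coefficients `α` are standardized and the fit regularizer `‖α‖²` is a
unit-normal prior.  The model also carries the two conventions every
downstream stage relies on: the 68 landmark–vertex correspondences (iBUG
ordering assumed; configurable through the correspondence table) and the
region atlas — explicit, pairwise-disjoint vertex-index sets for the 7
premarked regions × 2 sides.  Making region extents explicit index sets
(rather than a pictorial convention) keeps the segmentation testable.

The container is a directory: JSON manifest (counts, atlas, landmark
correspondences) plus flat little-endian float64/int64 arrays, which round
trip bit-exactly; a `mesh.ply` is exported for visualization but never read
back (typical PLY writers downcast to float32, which would break the
exactness contract).

### Synthetic model builder

Licensed clinical face models cannot be redistributed, so the simulator
builds its own: a parametric grid surface over `(u, v)` with dome, nose,
mouth and brow displacement fields; regions assigned from half-open boxes
in parameter space; landmarks placed at 68 parametric targets by greedy
nearest-vertex matching.  The basis consists of seeded random smooth
fields (low-order polynomial/harmonic features per coordinate),
orthonormalized by QR with a deterministic sign convention.

Two numerical choices matter:

* **Affine-gauge removal.** An affine camera absorbs any displacement
  field of the form `A x + t`, making the camera/shape decomposition
  ambiguous.  Each raw mode is therefore made least-squares orthogonal, on
  its 68-landmark restriction, to the 12-dimensional affine fields of the
  mean shape.  Consequence: with noiseless landmarks the camera estimated
  from mean-shape correspondences is already exact (≈1e-13), and a single
  camera→shape pass recovers the generating coefficients.
* **Mode scale.** `σ_i = 0.05 √N · 0.9^i`, i.e. one standard deviation of
  the leading mode displaces the surface by ~5% of the face half-width
  (per-vertex RMS of a unit-norm mode is `1/√N`) — a realistic
  inter-individual magnitude.  Much smaller scales would make all faces
  essentially identical and leave the landmark design matrix too weak for
  meaningful coefficient recovery.

Default dimensionality is M = 10 retained components (exposed as a model
property; any M up to the stored basis width can be fitted).

## Camera estimation and shape fitting

`estimate_affine_camera` is the normalized least-squares procedure: both
point sets are translated to zero centroid and isotropically scaled to RMS
norm √2 (2D) / √3 (3D), the 2×4 affine rows are solved by `lstsq`, and the
result is denormalized; the last row is `(0,0,0,1)` exactly by
construction.  Coplanar 3D configurations (third singular value ≤ 1e-9 of
the first) are rejected as degenerate.

`fit_shape` minimizes
`E(α) = Σ‖y_i(α) − p_i‖²/(2σ_2D²) + ‖α‖²` in closed form:
`(AᵀA + 2σ_2D² I) α = Aᵀb` with `A` the camera's linear part applied to
the σ-scaled basis rows of the 68 correspondence vertices (136 × M) and
`b` the observed-minus-projected-mean residual.  The system is symmetric
positive definite for any σ_2D > 0 and is solved with a Cholesky-backed
solver; its condition number is logged at debug level.  `σ_2D` defaults to
3 px, a typical landmark-detector error; it is the only tunable of the fit
and acts purely as the ridge weight `λ = 2σ_2D²`.

`fit_face` with `iterations=1` (default) is the sequential procedure —
camera from mean-shape correspondences, one shape solve.  Larger values
alternate camera re-estimation against the current fitted mesh with fresh
shape solves; each half-step is an exact block minimizer, so the energy is
non-increasing (tested over 20 seeds).  Whether the original clinical
system re-estimated the camera is unknown; both behaviours are exposed and
neither is asserted as "the" reference behaviour.

## Segmentation and Dice

A triangle belongs to a region when all three vertices do; region
triangles are projected and rasterized with a hand-written
pixel-center-in-triangle test (integer lattice, top-left tie rule), so
coverage is deterministic, orientation-independent, and never double-claims
a shared edge.  Pixels outside the image are clipped; an all-empty mask set
only warns (downstream mean-flow extraction raises).  Overlap between
region projections is resolved first-come in code order by default;
`zbuffer=True` switches to nearest triangle-centroid depth along the view
axis.  The default is off because acquisition is near-frontal (device
fixed ~20 cm above a supine face), where self-occlusion of the 14 regions
is negligible.

Dice: `2|X∩Y|/(|X|+|Y|)`; the empty∩empty case is defined as 1 (a region
absent from both labelings is perfect agreement), empty-vs-nonempty is 0.
The multi-region score pools intersections and sizes over the 14 codes —
it is *not* the mean of per-region values, and always lies between their
minimum and maximum.

## Perfusion features

Regional mean flow is the arithmetic mean of blood-flow pixels under each
code.  Features order the affected side first (`A_B…A_MB`, then
`H_B…H_MB`, region order B, E, N, C, MU, MC, MB) and divide by
`Volume_min`, the minimum over all 14 raw means (read literally as "all
regions" rather than per side).  After normalization the minimum is
exactly 1 (IEEE division of the minimum by itself), all entries are ≥ 1,
and the mapping is invertible given `volume_min`, which is retained for
audit.  Missing regions are a hard error — imputation would corrupt the
classifier input silently.  For healthy (grade I) participants the right
side is treated as "affected", the one stated convention for P_r
reporting.

The sample unit is the patient: per-frame regional means are averaged over
QC-passed frames and normalized once, yielding one vector per participant
(matching the 80-sample dataset structure and avoiding leakage of frames
of one patient across folds).

## Classifiers and cross-validation

* k-NN: Euclidean distance, k = 11; the likelihood is the neighbor vote
  fraction.
* SVM: polynomial kernel, degree 2 (`coef0 = 1`, `gamma='scale'`);
  one-vs-rest decision values pass through a softmax to produce the
  six-grade likelihood (order-preserving; margins are not calibrated
  probabilities and are only used via their ranks plus a smooth squash).
* NN: 14→32→16→6, rectifier activations, softmax/cross-entropy, trained
  full-batch with L-BFGS for up to 500 iterations, fixed seed.  Weight
  decay `α = 0.1`: with ~64 training faces per fold a conventional
  small-sample L2 penalty is essential; the library default (1e-4)
  overfits badly.
* Standardization (zero mean/unit variance) is fitted on the training
  folds only and applied for SVM/NN, not k-NN (configurable).

Likelihoods are mapped onto the six grades with zero mass on grades absent
from training; the predicted grade is the argmax with exact ties broken
toward the lower (clinically less severe) grade, logged.  Cross-validation
shuffles patients with the master seed and partitions them into k folds
(5 or 10); the fold structure is returned with the report, so the
no-leakage property is checkable structurally.

## Cohort simulator

Per patient: standard-normal shape coefficients, a sampled near-frontal
affine camera (scale 0.28–0.33 of the image side, ±2° in-plane rotation,
small tilt and center jitter), an ill side (uniform L/R; grade I → R), and
a per-frame regional flux table

    flux[t, r, side] = base_r · subject · jitter[r, side] · frame_t · ε[t, r, side]

with region-specific baselines `base_r` (B 1.2, E 1.5, N 1.3, C 1.1,
MU 1.0, MC 1.05, MB 0.95 — eyes and nose are better perfused than the
perioral skin) and lognormal factors: subject scale sd 0.2 (cancelled by
normalization), fixed per-patient region-side jitter sd 0.05 (the
discriminative noise floor), global per-frame factor sd 0.1, and per-frame
per-region noise sd 0.03 (averages out over 100 frames).  The affected
side is multiplied by `m(grade) = 1 − δ(grade−1)`, δ = 0.09 by default, so
the expected asymmetry `P_r = 1/m` rises from 1.0 (grade I) to ≈1.82
(grade VI).  The linear form is a design choice: published evidence
establishes only a monotone severity trend, not a functional form, so δ is
an explicit knob, not a clinical estimate.

Determinism: per-patient seeds are derived by stable hashing of
(master seed, patient index) via `SeedSequence`, so adding a patient never
perturbs the others, and the whole cohort is a pure function of its
configuration.

Frames are rendered lazily from the flux table (8,000 512×512 float
rasters would be ~17 GB): per-vertex flux interpolated barycentrically
over projected triangles on a low positive ambient background, Gaussian
smoothing (σ = 1.5 px), seeded multiplicative pixel noise (sd 0.02), an
extra blur on artifact frames.  Regional means measured on rendered
frames agree with the generating flux table to within the rendering blur
(tested at 25%); classifier experiments therefore use the flux-table
feature path, while the rendered path (render → fit → segment → extract)
is exercised end to end on reduced cohorts.

By default the cohort contains no artifact frames — the reference dataset
is described *after* deletion of corrupted frames (exactly 100 per
participant) — and artifacts are injected explicitly where QC is under
test.  QC screens the frame-mean series with a one-sided robust z-score
(median/MAD, threshold 3): head motion elevates whole-frame flux.  A
z > 3 rule carries ~0.1–0.2 expected false positives per 100 clean frames
irrespective of the noise scale; constant series (MAD = 0) warn and flag
nothing.

### Speckle forward model

The full temporal-decorrelation physics is reduced to the standard
spatial-contrast statistic: true contrast `K = (1 + s·flow)^(-1/2)`
(`s` = exposure scale), intensity gamma-distributed with that
sd/mean ratio, `K` measured as local sd/mean over an odd window (default
7) and averaged over 10 independent speckle realizations — the temporal
averaging every LSCI device performs, and necessary for a stable estimate
(a single 49-pixel window estimates K with ~10% sampling error; averaging
brings the map's coefficient of variation under 5%).  Flow is recovered as
`(1/K² − 1)/s`, affine in the true flow, giving rank correlation > 0.95 on
smooth fields.

## What the synthetic cohort does and does not show

The simulator makes the pipeline fully testable: geometry, rasterization,
feature algebra, fold hygiene and the monotone perfusion-asymmetry signal
all have exact or statistical ground truth.  It does **not** establish
clinical performance: real LSCI frames have tissue-optics texture,
pulse-synchronous temporal dynamics, detector-specific landmark errors,
occlusions, and an unknown grade→asymmetry relationship that is certainly
not exactly linear with lognormal noise.  Accuracy figures measured on the
synthetic cohort (e.g. ~0.90 NN 5-fold at the defaults) characterize the
pipeline under the simulator's assumptions, not the clinical system.

## Problem sizes used in checks

Statistical checks run at sizes chosen for tight Monte-Carlo error at
interactive runtimes: 10⁴ patient draws for perfusion statistics, 256²
rasters for segmentation scoring (1 px landmark noise), 256² fields for
speckle recovery, the full 80-patient cohort for cross-validation, and
reduced cohorts (12 patients × 20 frames at 160²) for end-to-end pipeline
tests.

## Known limitations

* Landmark detection on real images is out of scope; any external
  68-point detector can be plugged in through the landmark file formats.
* The affine camera ignores perspective; fine at ~20 cm with a shallow
  face relief, increasingly wrong for close-range wide-angle capture.
* Occlusion handling is triangle-centroid z-buffering at best; profile
  poses are out of scope.
* SVM "likelihoods" are softmaxed margins: correct argmax and ordering,
  but not calibrated posteriors.
* The region atlas is a fixed convention of the synthetic model; clinical
  use requires premarking the same regions on the clinical face model.
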