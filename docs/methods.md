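# Methods

This note records the models, algorithms, parameter choices and known
limitations of `dticlass`, in the order data flows through the pipeline.

## Signal model and tensor estimation

Diffusion-weighted signals follow the monoexponential tensor model
`S = S0 · exp(−b gᵀ D g)` with `b` in s/mm², unit gradient direction
`g`, and a symmetric positive tensor `D` in mm²/s. The default
synthetic acquisition is 25 non-collinear directions (a deterministic
Fibonacci hemisphere, so no two directions are parallel up to sign) at
b = 1000 s/mm² plus one b = 0 volume.

`fit_tensor` solves the log-linearized system
`ln S = ln S0 − b gᵀ D g` per voxel by ordinary least squares over the
7 unknowns `(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`; a weighted variant
(weights equal to the observed signals, the usual correction for the
log transform's heteroscedasticity) is available via `weighted=True`.
OLS is the default because it is the common default of standard DTI
fitting tools and is exact on noiseless data. Voxels with nonpositive
mean b=0 signal are masked invalid; signals are floored at 1e-12 before
the log. A rank-deficient design (collinear gradients) raises
immediately with a message naming the deficiency.

On noiseless phantoms the fit inverts the generator to ~1e-16 per
component. Under Rician noise with sigma = 2% of S0 the median
componentwise error stays below `(sigma/S0)/b` = 2e-5 mm²/s
(established by Monte-Carlo over repeated noise draws; the test suite
re-checks it with 30 draws).

Fractional anisotropy comes from the eigenvalues:
`FA = sqrt(3/2) · sqrt(Σ(λi − λ̄)²) / sqrt(Σλi²)`, defined as 0 for the
zero tensor and clipped to [0, 1]. The principal direction is the
eigenvector of the largest eigenvalue. FA is rotation-invariant and is
cross-checked in tests against an eigen-free closed form from tensor
invariants, `FA² = 3/2 · (‖D‖²_F − 3·mean(λ)²)/‖D‖²_F`.

## Mean-FA skeleton

Subjects are generated pre-aligned on a common grid, so no registration
is performed anywhere in the package; the skeleton-projection search of
full TBSS collapses to a direct voxel lookup. The group skeleton is the
ridge of the voxel-wise mean-FA map: a voxel is kept when its mean FA
is at least the threshold (default 0.2, the de-facto TBSS convention)
and is a strict local maximum of mean FA along the two grid axes
perpendicular to the local fiber orientation. The fiber orientation is
the principal eigenvector of the subject-averaged dyadic tensor (the
sign-free average of per-subject principal directions); its dominant
grid axis is excluded from suppression. Suppressing along both
perpendicular axes (rather than a single one) is what thins a tube to
its one-voxel centerline — a single-axis rule leaves a one-voxel-thick
*sheet*. Plateaus of exactly equal mean FA keep only the voxel with the
lowest C-order linear index, so the skeleton is deterministic. An empty
skeleton at the requested threshold raises with advice to lower it.

Skeleton features are the subject's FA values at the skeleton voxels in
sorted linear-index order (the order is serializable as a sidecar TSV).
Columns that are zero for every subject are dropped and logged before
classification.

## Tractography and connectome

`track_fact` implements FACT-style deterministic propagation: from each
seed (one per voxel with FA at or above the stopping threshold, voxel
centers, linear-index order) a streamline is stepped in fixed
increments along the principal eigenvector of the *current* voxel
(nearest-voxel lookup, the defining FACT behavior), with the
eigenvector sign aligned to the direction of travel; the seed is
propagated in both directions and the half-tracks concatenated.
Stopping rules, applied in this order: turning angle above threshold
(sharp-angle), next point outside the volume (out-of-bounds),
trilinearly interpolated FA below threshold (low-FA), or the length cap
(max-length; each hemisphere gets half the budget so the concatenated
streamline respects it). Defaults: step 0.5 × the smallest voxel edge,
FA stop 0.2, angle 45°, max length 200 mm, 1 seed per voxel — all
configurable; the motivating study names only the algorithm, not its
parameters, so these are the common defaults of deterministic-tracking
software.

Edges are assigned by endpoints: a streamline whose first and last
points fall in two distinct nonzero parcellation labels adds one count
to that undirected pair; endpoints in background, or both in one
region, contribute nothing (counted and reported as unassigned).
Counts form a symmetric matrix with zero diagonal; the feature vector
is the strict upper triangle in row-major order over v < u, which maps
every feature index back to a named region pair (6670 features for 116
regions). The sum of the feature vector equals the number of assigned
streamlines — a conservation identity asserted in tests.

## Synthetic data

The generators define the benchmark conditions:

- **Phantoms**: straight or curved (circular-arc) tubes of prolate
  tensors (axial 1.7e-3, radial 0.3e-3 mm²/s → FA ≈ 0.80) in an
  isotropic background (0.8e-3 mm²/s, FA 0); optional quadratic radial
  anisotropy falloff so FA peaks at the centerline (used by skeleton
  tests, since a constant-FA tube has no ridge to find). Noise is
  Rician on the magnitude, the physically appropriate model for
  magnitude MRI. Tensors with negative requested eigenvalues are
  rejected at construction.
- **Parcellations**: a seeded Voronoi tessellation of the grid —
  compact, space-filling regions, every label nonempty.
- **Feature cohorts**: Gaussian features (baseline mean 0.5, sd 0.1,
  loosely FA-like); patients are shifted *down* by `effect × sd` on the
  informative subset, mirroring reduced FA in injury. Default group
  sizes 30 patients vs 67 controls match the motivating study's largest
  patient group and control group.
- **Connectome cohorts**: negative-binomial edge counts (mean 20,
  dispersion 8 — overdispersed, as streamline counts are); patient
  means on designated edges are reduced by `effect` null-distribution
  standard deviations, clipped at zero with a warning.

What the synthetic data does *not* emulate: anatomy, partial-volume
effects, crossing fibers, scanner artifacts, motion, registration
error, and site effects. Passing benchmarks therefore demonstrate the
correctness and leak-freedom of the *procedure*, not expected accuracy
on clinical data.

## Feature selection and embedding

Per fold, features are ranked by a two-sample t-test (pooled variance
by default — the classic two-sample test; Welch by flag) and the D
smallest p-values are kept. Ties on p break by larger |t|, then lower
feature index, so selection is deterministic. Features where both
groups are constant with equal means get t = 0, p = 1 by convention and
are flagged. An optional p-value cap can discard selected features that
are not nominally significant.

LLE follows the standard construction: k nearest neighbors by Euclidean
distance (stable ordering on ties), per-point reconstruction weights
from the Tikhonov-regularized local Gram system
`(G + reg·tr(G)/k · I) w = 1` normalized to sum 1, and the embedding
from eigenvectors 2..d+1 (ascending eigenvalues) of `(I−W)ᵀ(I−W)`,
solved densely (cohort sizes are ~100, so a dense symmetric
eigensolver is exact and fast). Each component's sign is fixed so its
largest-magnitude entry is positive. Embedding columns are the
eigenvectors themselves: zero-mean, unit-norm. Held-out subjects are
mapped by the weight-based out-of-sample extension (find the k nearest
training points, compute the same constrained weights, combine their
embedding coordinates); a point coinciding exactly with a training
point returns that point's embedding, making the extension consistent
at the training set. Duplicate points are survivable (the
regularization carries the singular local Gram) and warned about.

Defaults D = 20, k = 12, d = 10 for ~100-subject, 200-feature cohorts.
The motivating study reports none of D, k, d, nor how the held-out
subject was embedded; these are free parameters, exposed in the config
and swept in tests, not estimates of the study's settings.

## Classification and inference

The SVM is a soft-margin SVC (scikit-learn) with linear or Gaussian-RBF
kernel; C = 1. The package default pairs the RBF kernel with connectome
features (as in the study's figures) and the linear kernel with
skeleton features. `gamma` defaults to the variance-adaptive "scale"
rule: the kernel operates on the d-dimensional embedding, so a width
tied to D (the pre-reduction feature count) would be numerically
degenerate. No inner hyperparameter tuning loop exists, because the
procedure being implemented describes none. The decision threshold for
labeling is 0; patients are the positive class throughout, which fixes
the SS/SC orientation.

LOOCV runs exactly N folds. Selection and LLE are fitted inside each
fold on the N−1 training subjects; the held-out subject only ever
passes through `lle_transform` and `decision_function`. A
`selection_hook` receives each fold's consumed subject indices, so
leakage is auditable by instrumentation; the test suite additionally
shows that a deliberately leaky variant (selection on all N subjects)
inflates GR on pure-noise cohorts, while the honest nested pipeline
stays at chance.

Two chance-level facts worth knowing when interpreting null results
(both reproduced in the test suite): with the underfitting linear
default on weak/no signal the classifier collapses to majority-class
prediction (GR = Nc/N exactly); with the more flexible RBF default the
nested LOOCV GR on noise sits a couple of points *below* the
majority rate — the well-known anti-learning bias of leave-one-out with
imbalanced classes, where the training set's composition anticorrelates
with the held-out label. Neither is a leak; leakage moves GR in the
opposite direction.

ROC curves sweep the unique decision scores (ties move the curve
diagonally in one step) and AUC is trapezoidal, which makes it exactly
the Mann-Whitney concordant-pair fraction with ties counted 1/2 —
asserted against a brute-force pair-counting oracle. Constant scores
yield the degenerate two-point curve with AUC 0.5 and a warning.

The permutation test shuffles the labels once per permutation and
reruns the *full* nested procedure (selection and LLE refitted per fold
per permutation — the conservative reading). p-values use the add-one
estimator with a ≥ comparison: `p = (1 + #{GR_perm ≥ GR0})/(1 + n_perm)`,
never zero, minimum `1/(n_perm+1)`. Permutations draw child seeds from
the master seed via `numpy.random.SeedSequence.spawn`, so runs are
reproducible and individual permutations independent. A warning fires
when `n_perm` cannot reach a requested alpha.

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen to keep the default suite in the
minutes range on one core: tensor-noise bounds use 30 draws on 6³
grids; recovery and chance-level checks run the full 30-vs-67 cohorts
(10 and 20 seeds); the permutation type-I calibration runs 200
replicate null datasets at n_perm = 99 with cohorts scaled to 6 vs 10
subjects and 40 features (a full-size calibration would need hours;
the type-I property is size-invariant, though smaller cohorts make the
test *conservative* because GR ties deflate rejections — 6 vs 10 is
the smallest size at which the test remains informative).

## Determinism

Every stochastic component takes an explicit integer seed; generators
are bit-reproducible, tracking and skeletonization are deterministic by
construction, and a pipeline run writes its config hash and seed into
the bundle. Report directories are named by config hash + seed (not by
timestamp), so re-running an identical configuration overwrites with
byte-identical output.

## Known limitations

- No registration, motion/eddy correction, or brain extraction: the
  package starts from aligned volumes, which only synthetic data
  provides. Real-data use requires upstream preprocessing.
- Single-tensor model only; no crossing-fiber handling, no multi-shell
  support, FA only (no MD/AD/RD maps).
- Endpoint-based edge assignment (a pass-through variant is a config
  alternative) and no edge-weight thresholding before classification.
- The published accuracies of the motivating study derive from patient
  MRI and unreported hyperparameters, and are not reproducible
  end-to-end; the package reproduces the *metric arithmetic* of the
  published tables and the behavior of the procedure on synthetic
  ground truth.
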