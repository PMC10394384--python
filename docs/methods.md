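# Methods

This note documents the models, parameters, numerical choices and known
limitations of `neurofactor`. The package predicts five standardized
depression-symptom factor scores from T1-weighted structural MRI by
patch-based 3D convolutional regression over a-priori regions of interest,
and ranks ROIs by the median squared error of their estimates.

## Patch sampling

Patches are cubic subvolumes of edge `patch_size` (default 32 voxels,
matching 1 mm isotropic data on a 182 × 218 × 182 grid). A cube at center
`c` spans the half-open range `[c − s//2, c + s − s//2)` per axis, 0-based
voxel units. `patches_per_roi = 5` centers are drawn uniformly from the ROI
mask; a candidate set is accepted only if every pair of (clamped) cubes
shares at most a fraction `cap` of its volume, where

    cap(ROI) = 0.50 + (voxel_count − min_count) / (max_count − min_count) · 0.25

interpolated per atlas between the smallest and largest ROI, clamped to
[0.50, 0.75]. The overlap of two equal cubes is computed in closed form,
`∏ max(0, s − |Δ_axis|) / s³`. Candidate sets are drawn in vectorized
batches; after `max_attempts` failed draws the cap is relaxed by
`relax_step = 0.05` and the budget resets, erroring only when the cap would
exceed 0.95. Small regions (several a-priori ROIs are smaller than a 32³
cube) therefore terminate with heavily overlapping but valid patches.
Centers are clamped so the whole cube stays inside the volume — patches may
cover tissue outside the ROI, which is intended (anatomical variability
tolerance), but never artificial padding; clamps are recorded in the patch
provenance. Intensities are z-scored per volume (volume-wide mean/SD)
before extraction. Patch centers are fixed once per subject (manifest-driven)
rather than re-drawn per epoch.

## The regression network

`3D-ResNet-12`: a ResNet-18-derived layout trimmed to 12 convolutions —
one stem convolution, five residual basic blocks of two 3×3×3 convolutions
(stride-2 entering stages 2–5; channels 16, 16, 32, 64, 128, 256), and one
final 1³ convolution before global average pooling and a linear scalar
head. Every convolution is followed by batch normalization then ReLU (the
second ReLU of a block follows the residual addition). Shortcuts are
parameter-free (strided subsampling with channel zero-padding), so the
convolution count is exactly 12; `NetworkConfig` checks the layout against
its declared depth and allows full overrides.

One network is trained per factor as a single regression task; all patches
of a subject carry that subject's score for the factor. The loss is the
squared 2-norm of the residual vector divided by the batch size, so its
scale is batch-invariant and directly comparable to per-subject squared
errors. Optimization is Adam at initial learning rate 0.001 (batch 1000 by
default), no schedule, optional decoupled weight decay on convolution and
linear weights only (default 0). Batch normalization uses batch statistics
in training and frozen statistics at inference; after the last epoch a
single frozen-weight calibration pass replaces the momentum-averaged
running statistics with exact training-set statistics. This matters when
training is short and the learning rate high: momentum averages lag the
final weights and shift every inference-mode prediction by a
model-specific offset, which pollutes cross-validated estimates.

The engine is written on numpy: convolutions run as an im2col gather (a
numba kernel producing contiguous `(B·P, k³·C)` column buffers in
channels-last layout) followed by one BLAS matrix multiply, with the
mirrored scatter-add for gradients; batch-norm statistics and
normalization are fused numba passes. Gradients of every layer were
verified against central finite differences in float64 (relative error
≤ 1e-8; conv biases directly followed by batch norm have exactly zero
gradient, as expected). All computation is float32 and deterministic given
the seed.

## Cross-validation and aggregation

Folds partition subjects (never patches): 10 folds, sizes within one of
each other (116 subjects → six folds of 12, four of 11). All factors share
one fold assignment so per-factor comparisons are paired. Each fold's
model is trained on the other folds' patches and predicts the held-out
subjects' patches; ROI-level estimates are the arithmetic mean of the
ROI's five patch estimates, subject-level estimates the mean of the M
ROI-level estimates.

By default the experiment runner stratifies folds by the first requested
factor's score: subjects are sorted by score and fold labels drawn within
consecutive blocks, so every fold spans the score range. Rationale: with
small cohorts, unstratified CV produces a systematic negative association
between held-out truths and any estimator that regresses toward its
training mean — the held-out fold's mean score and its training set's mean
are anti-correlated by construction (`cov(pred, y) ≈ −σ²/(n−k)` for fold
size k) — which biases the pooled estimate-vs-truth correlation and
inflates the false-positive rate of its significance test under the null.
Stratification removes the artifact at the root by pinning every fold's
mean near the cohort mean; since the five factors are orthogonal,
stratifying on one factor is neutral for the others in expectation.
Unstratified assignment remains available (`stratify_folds: false`,
and `make_folds` defaults to unstratified).

## Evaluation

ROI-level performance pools (subject, ROI) estimate/truth pairs across all
folds (~N·M pairs); this pooling is what makes the degrees of freedom of
the reported p-values consistent with cohort-scale results. Alongside
Pearson r (t-transform p, n − 2 dof), a robust line is fitted by IRLS:
starting from OLS, weights `w_i² = max(|e_i|, ε)^(p−2)` are recomputed
from the previous residuals and a weighted least-squares problem is solved
until the coefficient change falls below 1e-8 or 50 iterations. Default
norm power p = 1 (absolute-deviation flavor); ε = 1e-6 guards the weight
formula at exact-fit points; p = 2 reproduces OLS to machine precision.
The t statistic is slope / SE with SE from the weighted-least-squares
covariance at the final weights (weighted residual variance, n − 2 dof) —
the weighted choice is recorded in the fit metadata. With p = 1 on data
whose majority of pairs carry no signal, the robust line tracks the dense
null bulk: small slopes with large t values are expected and reflect the
high precision of the bulk fit, not effect size.

The chi-square operation implements the printed formula
`Σ(Oᵢ−Eᵢ)²/Eᵢ` with an upper-tail p at caller-supplied dof and requires
strictly positive expected values. Standardized scores can be negative, so
the per-factor report applies the formula to distributional counts:
observed = histogram of estimates over truth-decile bins, expected =
histogram of truths over the same bins (positive by construction),
dof = bins − 1. The conventional Pearson p is always reported alongside.

Per-ROI informativeness is the median across subjects of
`(ŷ_ROI − y_subject)²`; testing-set values pool member ROIs' records
before taking the median (`mean_of_medians` available as an alternative).
The top-5 ranking sorts ascending by median with lexicographic
tie-breaking on the ROI abbreviation.

## Synthetic cohorts

The generator emulates the statistical shape of a clinical LLD cohort:

* **Atlas** — `n_rois` non-overlapping random ellipsoids (rejection
  placement) labeled 1..n, grouped into `n_groups` contiguous testing sets;
  full preset: 34 ROIs in 10 sets on a 182 × 218 × 182 grid.
* **Scores** — Gaussian draws, column-centered, QR-orthogonalized, unit
  population SD: five factors with mean 0, SD 1 and exactly zero pairwise
  sample correlation, emulating varimax-rotated PCA factor scores
  (orthogonalization needs n ≥ 7; below that, columns are only
  standardized).
* **Volumes** — a smooth radial baseline (amplitude 10 intensity units,
  bright center) so patches contain non-degenerate structure, plus i.i.d.
  Gaussian voxel noise (SD 1), plus per-effect signal: `intensity_shift`
  adds `β · score` inside the ROI; `texture_scale` multiplies the ROI's
  noise by `exp(β · score)`. The default mechanism is the intensity shift:
  it is analytically checkable and detectable by a convolutional
  regressor, whereas true morphometric (shape) deformation is not
  parameterized here — a deliberate simplification. Passing tests
  therefore demonstrate signal recovery and calibration of the pipeline,
  not performance on real morphometric effects, scanner physics, bias
  fields, or registration error, none of which are simulated.

All outputs are deterministic functions of (config, seed); per-subject
volume seeds are spawned from the master seed and recorded in the
manifest.

## Desk-scale profile

CPU-scale presets keep the full pipeline runnable in tens of seconds
without changing its structure: cohorts of 40 subjects, 64³ volumes, 6
ROIs in 6 sets (radii 5–8 voxels), one intensity effect with β/σ = 2;
16³ patches with a 2,000-draw budget per relaxation level (desk ROIs are
smaller than the patch, so infeasible caps should be detected and relaxed
quickly); the same 12-convolution network at quarter width with the stride
budget moved forward (stem stride 2; block strides 2, 2, 2, 1, 1); Adam
with batch 64, lr 0.003, 10 epochs. The small-batch/higher-rate setting is
deliberate: at these cohort sizes, large-batch training at lr 0.001
memorizes training subjects before the generalizable intensity feature
emerges, and held-out predictions carry no signal. Problem sizes for the
test suite (micro cohorts of 12 subjects, 48³ volumes, 3 ROIs) are chosen
so the full suite exercises every stage end to end.

## Known limitations

* The robust-regression t under p = 1 depends on the ε floor and the
  weighted-variance convention; it is comparable across runs of this
  package but not across robust-regression implementations.
* The pooled correlation treats (subject, ROI) pairs as exchangeable;
  within-subject dependence makes its p anti-conservative, which is why
  the null-calibration check (zero-effect cohorts) is part of the test
  suite.
* One network per factor is trained on patches from all ROIs jointly;
  per-testing-set training is available via the module API but is not the
  default, and the two readings are not equivalent.
* Hemispheres are separate ROIs by default (`merge_hemispheres` collapses
  homologues when a bilateral reading is wanted).
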