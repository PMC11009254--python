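# Methods

`tractclass` reimplements, as a tested and reusable pipeline, an analysis
design used to ask whether a retinal disease leaves a detectable signature
in the brain's white matter: classify disease status from tract profiles
of the optic radiations (OR) and compare against non-visual control
bundles (corticospinal tract, CST; uncinate fasciculus, UNC). Because the
cohort data such a study runs on are access-restricted, the package is
driven by a synthetic-cohort generator that emulates the *statistical*
structure of the problem; everything downstream of the generator — the
matching, feature preparation, models and inference — is the analysis
itself and runs unchanged on real subject and profile tables in the same
CSV formats.

## Synthetic cohort

**Subjects.** Cases and controls share every covariate distribution
except age, which is deliberately confounded: case ages are truncated
normal 68 ± 7 years, control ages 62 ± 7, both clipped to [40, 90]. Sex
is Bernoulli(0.46); ethnicity a 3-level categorical (0.91/0.05/0.04); the
Townsend deprivation index normal (−1.3, 3.0). Visual acuity (logMAR) is
measured for 70% of subjects; the eligibility rule keeps subjects whose
acuity is missing or ≤ 0.3.

**Profiles.** Each subject carries 3 bundles × 2 hemispheres × 3 tissue
properties (FA, MD in µm²/ms, MK) × 100 nodes. A profile is a smooth
bundle-specific mean template plus two noise components: a Gaussian
process over nodes with squared-exponential correlation (length 10 nodes)
and a per-profile random intercept (0.75× the node SD). The marginal
per-node SD of the sum is the "control SD" in which all effects are
expressed. Node SDs are FA 0.030, MD 0.040, MK 0.060 — chosen so profiles
look like tract profiles (FA ≈ 0.45–0.55, MD ≈ 0.8, MK ≈ 0.95) with
realistic overlap between groups.

**Disease effect.** The default case-minus-control offset lives in the OR
only: MK lowered by 0.30 SD across the whole bundle; FA lowered up to
0.35 SD posteriorly with a +0.10 SD anterior reversal; MD mirrored. CST
and UNC carry exactly zero offset. Peak magnitudes of 0.2–0.4 SD put the
per-bundle classifiers in the weak-classifier regime (test AUC roughly
0.6–0.8), which is the operating point the design is about. Two further
patterns are available: a mild second-disease ("AMD-like") Gaussian bump
on OR FA/MD, and an *orthogonal* high-frequency sinusoidal pattern whose
inner product with the default curves is numerically zero — used to test
that a disease-trained model carries no information about an unrelated
group difference.

**Aging.** Optionally every bundle drifts with age: −0.18 SD/decade FA,
+0.18 MD, −0.04 MK (relative to age 62). Slopes are concentrated in
FA/MD so the aging direction and the MK-dominated disease signature are
largely distinct profile directions; a 10-year gap then supports an
age-group classifier around AUC 0.6–0.65 while leaving disease-trained
models near chance on age-labeled data. The aging drift is disabled in
the default `EffectConfig` (so control bundles are exactly null even in
age-confounded cohorts) and enabled by the pipeline, which needs the
age-classification arm to be learnable.

**Non-linear effects.** `mixture_offsets` adds the configured curve to
each case with a random ±1 sign (one sign per subject). Group means stay
exactly equal, so a linear classifier is blind to the effect, but the
case distribution is a two-component mixture a non-linear model can
detect — the cleanest way to separate what the CNN can learn from what
the logistic baseline can.

**Missingness.** Whole (subject, bundle, hemisphere) blocks are knocked
out jointly for all three tissue properties, independently of the label,
at rates mirroring how often bundle recognition fails: OR 4.2% (left) /
5.1% (right), CST 0.2%, UNC 0%.

**What the generator does not emulate.** Spatial structure (no image
volumes, no registration error), covariance between tissue properties
within a voxel, non-Gaussian heavy tails, site/scanner effects, and any
dependence of missingness on disease or image quality. Passing tests
therefore certify the *pipeline logic and its statistical calibration*,
not classifier performance on real data; absolute AUC values on synthetic
cohorts are calibration targets set by the chosen effect sizes, not
predictions.

## Matching

Cases are paired to controls by solving the rectangular linear assignment
problem (exact Jonker–Volgenant-class solver) on the matrix of
Mahalanobis distances between confounder vectors (age, sex, ethnicity
one-hot, TDI). The metric uses the covariance of the pooled
case+control confounder matrix with n−1 normalization, ridge-regularized
(escalating from 1e−8× the mean diagonal) so the one-hot block's rank
deficiency never matters — one-hot difference vectors are orthogonal to
the null directions, so the regularization does not distort pair
distances. Pairs with distance > 0.3 are pruned *after* the globally
optimal assignment. With an age shift of s years, each case's age is
reduced by s before both the pooled covariance and the difference vectors
are formed, which matches cases to controls s years younger. Matched
pairs are shuffled (seeded) and assigned to splits in tandem: test gets
round(0.20·n) pairs, validation round(0.16·n), the remainder train.

## Bundle recognition and profiling

Streamline acceptance uses four conditions with a 3 mm tolerance: no
midline crossing (sign change of x against the sagittal plane), at least
one point within tolerance of each inclusion ROI, no point within
tolerance of the exclusion ROI, and termini within tolerance of the two
endpoint ROIs (better of the two terminus↔ROI assignments, since which
terminus maps to which ROI is not fixed a priori). ROIs are spheres in
the synthetic setting and distances are signed point-to-surface values
(negative inside). Cleaning iteratively (≤ 5 passes) removes streamlines
whose length z-score exceeds 4 or whose mean distance from the bundle
core (node-wise mean after resampling to 100 nodes) has z-score above 3;
bundles under 3 streamlines are left untouched, and zero-variance
statistics are guarded. Profiles resample each streamline to 100
equidistant arc-length nodes, orient streamlines by flipping whichever
direction is closer to the first streamline, and average the scalar field
at each node with Gaussian weights exp(−d²/2) on the Mahalanobis distance
of each point from the node's point cloud (covariance ridge-regularized),
so stray trajectories contribute little. The first and last 10 nodes are
trimmed before modeling because the bundle ends are the most contaminated
in real data.

## Models

**Input.** Per bundle: subjects × 80 nodes × 6 channels in the fixed
order FA-L, FA-R, MD-L, MD-R, MK-L, MK-R. Missing channel blocks are
imputed with the mean profile of the non-missing subjects *of the same
split*; z-scoring statistics (per node × channel) are fitted on the
training split only and applied to all splits. Neither operation ever
crosses split boundaries. (Whether the original normalization was global
or train-only is ambiguous; train-only is the leakage-safe reading and is
the default.) Zero-variance cells floor the SD at a machine-epsilon-scaled
constant so constant channels map to zeros.

**CNN.** Three residual blocks (kernel sizes 8/5/3 per block; 64, 128,
128 filters) of conv–batchnorm–ReLU with an additive shortcut (identity,
or a kernel-1 conv + batchnorm when channel counts change), then global
average pooling and one sigmoid unit — 506,753 parameters. Implemented
directly in numpy: convolutions are im2col + GEMM forward, shifted GEMMs
backward; batch normalization keeps running statistics (momentum 0.9,
eps 1e−5); everything is float32. A finite-difference oracle in the test
suite checks every parameter family's gradient. The final dense layer is
zero-initialized, so an untrained network outputs exactly 0.5. Training
minimizes binary cross-entropy with Adam (default lr 1e−3, batch 128),
early-stops on validation loss (default patience 5 within 30 epochs) and
restores the best-validation weights including batch-norm statistics.
Optimizer, loss, learning rate and schedule are this implementation's own
choices and are exposed in `TrainConfig`, not treated as fixed
architecture constants.

**Logistic baseline.** L2-penalized logistic regression (liblinear) on
every other node from the 20th to the 78th (1-based ordinals → 30 nodes)
for each of the six channels — 180 features. The inverse regularization
strength is scanned over 10^(−4…2) in half-decade steps and chosen by
validation AUC, then the model is refit on the training split alone.

**A note on CNN vs logistic on synthetic data.** The default generator's
disease effect is a pure mean shift, i.e. exactly linear. In that regime
the 180-feature ridge is close to Bayes-optimal and more sample-efficient
than the 507k-parameter CNN: at ~840 pairs the logistic reaches test AUC
≈ 0.76 while the CNN plateaus at ≈ 0.61–0.65 across learning rates and
budgets. With a mixture (sign-flip) effect the ordering reverses sharply
(CNN ≈ 0.72, logistic ≈ 0.53). Real cohorts, where the CNN has been
observed to lead, presumably sit between these extremes; the synthetic
defaults were chosen for calibration clarity, not to reproduce that
ordering.

## Inference

AUC is the Mann–Whitney statistic with ties counted one half, computed
via midranks; the ROC curve itself comes from scikit-learn and its
trapezoidal area equals the Mann–Whitney value exactly. The AUC variance
is the DeLong structural-components estimator var(V10)/n_pos +
var(V01)/n_neg on placement values; two models scored on the same
subjects are compared with the paired DeLong z-test using the placement-
value covariances (two-sided). Families of per-bundle AUCs are screened
against 0.5 with normal-approximation confidence intervals at the
Bonferroni-corrected per-test level 1 − α/3 (untransformed; the
conservative correction is used because it applies to intervals rather
than p-values), and families of pairwise comparisons are corrected with
Benjamini–Hochberg (the step-up FDR variant). Confusion matrices use a
0.5 threshold with score ≥ threshold counting as positive. Calibration is
tested rather than assumed: the suite checks the DeLong variance against
a 10,000-replicate bootstrap (within 15% at n = 200) and the paired
test's type-I error against [0.035, 0.065] at nominal 0.05 over 2,000
null replicates.

## Pipeline and problem sizes

`run_experiment` mirrors the full dataset roster: the matched primary
dataset (905 cases vs 5,292 controls → ~840 pairs at threshold 0.3), a
second-disease test set matched from controls unused by the primary
matching, a 70-vs-60-year age-gap test set (age shift 10), an
age-classification training arm (70–79-year-old controls matched to
10-year-younger controls), and that arm's two generalization sets. It
trains 3 CNNs + 3 logistic models on the primary dataset and 3 CNNs on
the age arm, asserts train/test disjointness for every (train, test)
pair, and writes config, subject tables, matched sets, scores, histories,
and a sorted `metrics.json` (reruns with the same config are
byte-identical). The acceptance script runs this at the default scale,
about 3½ minutes on one CPU. The heavy pattern-recovery tests use 3
cohort seeds with a condensed training budget (15 epochs, patience 3) —
enough for the OR-specificity pattern, chosen to keep the whole suite
comfortably runnable; a 10-seed release-scale check is a one-line change
of the seed tuple.

## Known limitations

- The probabilistic-atlas component of real control-bundle recognition
  has no synthetic counterpart and is out of scope.
- Synthetic noise is Gaussian and stationary along nodes; real tract
  profiles have node-dependent variance and inter-property correlation.
- The CNN's training-budget defaults favour determinism and speed over
  squeezing out the last AUC point; on linear synthetic effects it trails
  the linear baseline (see above).
- `cross_apply` reuses the training dataset's z-scoring statistics, which
  is the right frozen-model behaviour but means cross-task AUCs depend on
  the training cohort's scale.
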