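# Methods

This note documents the models, conventions and design choices behind
the package, what the synthetic-data generators do and do not emulate,
and the numerical details a user re-running or extending the analysis
should know.

## Coordinate conventions

All geometry is handled in world millimetres, RAS orientation. TCK
files already store RAS mm; TRK files store voxel-scaled coordinates
which are pushed through the header affine on load, so both dialects
arrive in one frame. Voxel indices are 0-based; a scalar volume's
affine maps voxel index to world mm, and sampling positions map back
through its inverse. This single-convention rule exists because mixed
trk/tck voxel conventions are the classic source of silent
half-brain-offset bugs.

## Bundle cleaning

A bundle is first oriented (each streamline flipped so its node 0 is
nearest the designated start-ROI centroid; exact ties keep stored
order) and resampled to `n_nodes` (default 100) equidistant arc-length
positions by linear interpolation along the polyline. The core tract is
the per-node mean and 3×3 covariance across streamlines (unbiased
normalisation), with two safeguards: an isotropic floor of 1e-6 mm² on
every covariance, and shrinkage toward the diagonal when the condition
number still exceeds 1e10 (small bundles yield rank-deficient
covariances).

Each fascicle's distance score is the **mean over nodes** of its
node-wise Mahalanobis distance from the core, in SD units. The
aggregation rule is configurable (`distance_stat="max"` is available)
because the rejection rule in the tract-profile literature is stated
per-fascicle without an explicit aggregation; the mean is the
convention of that lineage and is robust to single-node noise. Cleaning
iterates: recompute the core from survivors, remove (as one union) all
fascicles with score > `dist_sd` (default 2.6) or polyline length >
mean + `len_sd` (default 2.8) × length-SD, stop when a pass removes
nothing, cap at 20 iterations with a convergence warning. The length
criterion is one-sided — only too-*long* fascicles are suspect, since
spuriously long paths indicate wandering trajectories while short
paths are legitimate. Lengths are always measured on the original
polyline, not the 100-node resampling, which would alias
high-curvature detours. A bundle retaining fewer than `min_fascicles`
(default 10) streamlines is flagged as a tracking failure — a reported
state, never an exception, because failure to track is itself a
finding.

Cleaning is idempotent by construction (the final pass removes
nothing), monotone in `dist_sd`, and invariant to streamline order; the
test suite checks all three plus equivalence with a brute-force
reference on small bundles.

## Tensor model

The diffusion tensor is fitted per voxel by log-linear least squares:
log(S/S₀) = −b gᵀDg with S₀ the mean of the b=0 channels. An iterative
weighted fit would add little at the package's scale and costs
determinism. Non-positive signals are clamped to the smallest positive
signal in that voxel before the log; negative eigenvalues are clamped
to zero before FA/MD. FA is clipped to [0, 1]; an all-zero tensor
yields FA 0 with a warning. The white-matter mask is the single strict
threshold FA > 0.15 — the manual mask editing used in practice on real
data is deliberately not reproduced, since manual steps are not
reproducible.

## Tract profiles and laterality

Scalars are sampled at node world positions by trilinear interpolation
(nearest-neighbour available by config). Trilinear is the default
because it reproduces linear fields exactly and avoids staircase
artefacts; the literal "voxels touched by the tract" reading would be
nearest-neighbour. Each node's profile value is the weighted mean over
streamlines with Gaussian weights w ∝ exp(−d²/2) of the node-wise core
Mahalanobis distance, normalised to sum to one per node (uniform
weights available for sensitivity checks). A constant field therefore
always yields a constant profile, whatever the weights.

Whole-tract summaries average nodes 15–85 inclusive (both ends), 
dropping the proximal and distal 15 nodes vulnerable to grey-matter
partial volume. Distal summaries average nodes 60–85 of the **full**
profile — not the clipped one — because the range is anchored at "% of
total tract length" from the LGN end; they require an
orientation-tagged bundle. Laterality is 100·|contra − ipsi| / ipsi
(controls: left−right over right). It is scale-invariant and
non-negative; the ipsilesional mean must be positive.

For group-level laterality both conventions are available: computed
from group-mean hemisphere values (matching published worked values)
or per participant then averaged; the pipeline emits per-participant
rows so either aggregation can be formed from the tables.

## Behaviour: scoring and classification

Trials with fixation deviation strictly greater than 1° are excluded
(a trial at exactly 1° is retained — "exceeded"). Excluded trials
reduce the denominator of the binomial test. Percent correct is
reported per contrast and pooled; a contrast level with no valid trials
is flagged missing, never imputed.

The blindsight criterion is one-sided ("above chance" is directional):
P(X ≥ k) under Binomial(n, 0.5), applied to the pooled count over all
valid trials *or* the 100%-contrast cell, positive if either tail
probability is below α = 0.01. "Average score significantly above
chance" is read as the pooled binomial over all valid trials (100
nominal) rather than the mean of per-contrast percentages — a
cumulative binomial needs a trial count, and pooling is the only
self-consistent reading. At 20 trials the 100%-contrast threshold is
16/20 (p = 0.0059; 15/20 gives 0.0207).

k-NN validation is leave-one-out with Euclidean distance over the
all-contrast performance vector; neighbour labels come from the
binomial criterion, and ties break toward "negative" (conservative
labelling). The Gaussian-mixture check fits two full-covariance
components blind (EM, 10 seeded restarts, best likelihood kept — the
restart count buys determinism plus robustness); the
higher-mean-performance centroid is called "positive", and an
all-identical cohort is reported as a degenerate-fit error rather than
silently output. Both classifiers are sklearn estimators under the
hood.

A structural limit worth knowing: concordance between the curve-shape
classifiers and the binomial criterion is bounded by the criterion's
own error rate. A true chance-level performer passes the OR-criterion
with probability ≈ 0.011 (exact tail arithmetic at 20 + 80 trials), so
in a cohort with five such participants roughly 5% of simulated
cohorts contain one lucky "positive" whose flat performance curve the
classifiers — correctly — place in the negative cluster. Perfect
17/17 agreement in ≥ 99% of replicates is therefore not attainable at
these trial counts; the acceptance suite measures ~93/100.

## Group statistics

The two-way ANOVA (status × side) uses Type-II sums of squares by
default — the conventional choice for an unbalanced design (12 vs 5)
absent interaction-driven hypotheses — with Type I/III selectable.
Hemisphere is treated as a crossed fixed factor, matching the stated
model; a paired/repeated-measures alternative would also be defensible
but is not the default. Saturated designs (no residual degrees of
freedom) are rejected with a design error. t-tests use pooled variance
by default (Welch by flag). Partial correlation is computed on
residuals after regressing out the covariate (algebraically identical
to the standard formula; p from the t transform with n−3 df). No
multiple-testing correction is applied; reports state the number of
tests run. Lesion summaries require masks on a shared grid — resampling
between grids is out of scope by design.

## Synthetic data: what it emulates, and what it does not

`gen_bundle` produces fascicles as a shared core curve plus a smooth
stationary perturbation: randomized-phase sine/cosine pairs over 20
harmonics, giving per-coordinate displacement SD exactly `jitter_sd`
(default 1 mm) at every point. Smooth (band-limited) perturbations are
essential: per-point white noise would destroy the arc-length
correspondence the node-wise statistics assume. Each fascicle's
derivative-weighted coefficient energy is normalised to the ensemble
mean, which removes the skewed chi-square component of arc-length
variation and leaves inlier lengths Gaussian — this is what makes
planted length outliers separable from inlier scatter at the 2.8-SD
threshold. Fascicle endpoints scatter around the ROI centroids, as
real fascicles terminate across an ROI volume.

Positional outliers add an `outlier_offset` (default 10 × jitter)
displacement along a plateau covering the tract midsection in a random
direction; length outliers add a small-amplitude high-frequency wiggle
sized by bisection to extend arc length by 8 inlier length-SDs
(configurable) while staying positionally near the core, so they trip
the length criterion and not the distance criterion. Ground-truth
indices are recorded. Measured recovery at the default settings:
pooled precision 0.975, recall 1.000 over 50 seeded replicates.

One resampling artefact is worth knowing: node covariance in the
*transverse* plane matches jitter_sd² closely, but the *tangential*
(along-tract) variance is inflated ~2.5× because length scatter slides
equal-arc-fraction nodes along the curve. This is a property of
arc-length correspondence itself, not of the generator.

`gen_scalar_volumes` builds FA/MD fields that are constant except for a
spherical lesion (reduced FA, elevated MD) with a one-voxel linear
transition band. `gen_dwi` simulates S = S₀·exp(−b gᵀDg) from an
axially symmetric tensor whose analytic FA/MD equal the requested
targets exactly (λ₁ = m+2d, λ₂,₃ = m−d with d = m√3·FA/√(9−6FA²)),
plus Rician noise in the magnitude convention (σ = S₀/SNR); note the
Rician mean exceeds the noiseless signal by ≈ σ²/2S, so validation
compares against the analytic Rice mean. `gen_behavior` draws 2AFC
trials with P(correct) = ½ + (½ − lapse)·logistic(slope·(log c − log
c₅₀)) over the five standard contrasts {1, 5, 10, 50, 100}%, 20 trials
each; fixation deviations are half-normal with scale set so the
exceedance probability over 1° equals the requested break rate.

What the generators do **not** emulate: realistic brain geometry,
crossing or kissing bundles, partial-volume mixtures at tissue
boundaries, spatially varying noise, susceptibility distortion, or
behavioural lapses correlated across trials. Passing tests demonstrate
that the analysis machinery is correct and well-calibrated under its
own assumptions — not that those assumptions hold in any particular
scan.

## Problem sizes and determinism

All stochastic stages draw from a single seed; identical inputs,
config and seed give byte-identical output tables. Test and validation
problem sizes were chosen at desk scale: 100-fascicle bundles at 100
nodes (50 replicates for cleaning recovery), 10³ voxels per SNR level
for tensor noise calibration, 17-participant cohorts (100 replicates)
for classifier concordance, and 1000 replicates for null-calibration
KS checks. These sizes give stable statistics while keeping the full
suite in the low minutes on one core.

## Known limitations

* Tracking itself (CSD/fODF estimation, probabilistic propagation) is
  out of scope; the pipeline consumes streamlines from files or the
  simulator.
* Whether FA/MD should be derived from a combined blip-up/blip-down
  acquisition or a single set is an upstream preprocessing question the
  package does not address; synthetic inputs make it moot, users of
  real data should decide before the tensor stage.
* The profile node SD is reported across streamlines; the
  across-participant SD can be formed from the emitted per-participant
  tables, and which of the two belongs on a plot is left to the user.
* Atlas- or manually-delineated ROIs are not reproduced; ROI centroids
  enter only as bundle orientation anchors and simulator endpoints.
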