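# Methods

This note documents the models, conventions and numerical choices behind
`voxelsvm`, the assumptions of its synthetic data generator, and the
limitations a user should keep in mind.

## Data model and conventions

The central container is the subjects × voxels matrix (`SubjectMatrix`):
rows are subjects, columns are mask-interior voxels in a fixed x-fastest
scan order (x varies fastest, then y, then z). The orientation follows the
samples × features convention of modern estimators; column order is
deterministic given the mask, so column indices are comparable across runs
and machines. Voxel coordinates are 0-based lattice indices; world (mm)
coordinates are derived through the NIfTI affine only for reporting.

Two normalizations are used and deliberately kept distinct:

* **Whole-brain normalization** divides each subject's row by its own
  within-mask *mean* (not sum), making rows unit-mean and the operation
  scale-free with respect to mask size and idempotent. It removes global
  tracer-dose / count differences between scans while preserving relative
  regional effects.
* **Min-max scaling to [−1, 1]** is the SVM input convention. It is fit on
  training rows only and applied unchanged to held-out rows (values may
  leave [−1, 1]; no clipping), which avoids test-set leakage at the
  scaling step. Columns constant on the training rows map to 0.

## Information-gain voxel filter

IG(v) = H(class) − Σ_b (n_b/N) H(class | b), bins from recursive binary
splits of the sorted voxel values. A split is accepted only if its gain
exceeds the Fayyad–Irani MDL cost,

    gain > [log2(N−1) + log2(3^k − 2) − (k·H(S) − k1·H(S1) − k2·H(S2))] / N,

with k the number of classes present in the segment and k1, k2 in the two
halves. If no split is accepted, IG(v) = 0; voxel selection keeps exactly
the voxels with IG(v) > 0. The MDL stop is the mechanism that makes the
filter sparse — on pure noise at 20 + 20 subjects only a few percent of
voxels receive any accepted split — which matches the intended "blind
dimension reduction" role of this stage.

Numerical conventions: logarithms base 2, 0·log 0 := 0, cut points fall
only between distinct values (tied subjects always share a bin), ties in
gain resolved toward the leftmost cut. IG therefore depends only on the
ordering of values and is invariant under strictly monotone transforms;
both properties are asserted by tests, and the implementation is checked
against an independent exhaustive-cut-point oracle on small inputs. The
per-column computation is vectorized across all voxels for the first
split; only columns whose first split is accepted enter the recursion.

The Lilliefors screen (per voxel, within each class; a voxel is "normal"
iff not rejected in both classes; zero-variance voxels count as rejected)
uses the asymptotic p-value approximation from statsmodels. It is
descriptive only and never gates the pipeline.

## Spatial clustering

The clustering primitive is a single-pass DBSCAN specialised to the voxel
lattice with ε = √2 and MinPts = 2 (the neighborhood count includes the
point itself, so "core" means "has at least one face- or edge-adjacent
neighbor"). ε = √2 is interpreted as Euclidean distance ≤ √2, i.e. the
18-neighborhood: 6 face neighbors at distance 1 and 12 edge neighbors at
distance √2; corner-adjacent voxels (distance √3) do not connect. Under
these defaults the labeling provably equals connected components of the
≤ √2-adjacency graph (every non-isolated voxel is core), which the test
suite verifies against a brute-force breadth-first oracle on hundreds of
random universes.

Cluster ids are renumbered canonically — descending size, ties by the
lexicographically smallest member coordinate — so labelings are invariant
to input order and byte-stable across runs. The retention filter drops
noise voxels and clusters below `min_cluster_size` (default 20).

### Monte-Carlo cluster-extent threshold

`estimate_cluster_threshold` answers "how large must a spatially connected
cluster be before it is unlikely to arise from smooth noise?". Per
iteration: white Gaussian noise on the grid → Gaussian smoothing to the
target FWHM → standardization within the mask → two-sided thresholding at
the voxel-level p (|z| ≥ z₁₋ₚ/₂) → the largest connected suprathreshold
cluster under the same ≤ √2 adjacency the pipeline uses. The returned k is
the smallest extent whose family-wise exceedance fraction is ≤ α.

Choices worth noting: the simulation controls the family-wise rate (the
probability of *any* suprathreshold cluster of size ≥ k in the mask), the
usual convention of extent-threshold simulators; thresholding is two-sided
on a single noise field per iteration; connectivity matches the pipeline's
own adjacency for internal consistency. For 10 mm FWHM noise on a
brain-scale ellipsoid mask of 4 mm voxels (40×48×35 grid) with voxel
p = 0.002 and α = 0.01, the simulation yields k ≈ 25–27 at 1000
iterations. Published thresholds for comparable configurations are of the
same order (≈ 20); residual differences of a few voxels are expected
across simulators, which differ in connectivity, sidedness, edge handling
and mask geometry. The resolution convention matters enormously: the same
10 mm smoothness expressed on a 2 mm grid (5-voxel FWHM, 79×95×69)
yields k ≈ 186, because extent thresholds scale with the per-voxel resel
volume — thresholds are only meaningful together with their grid.

## SVM stage

SVMs are libsvm-backed (scikit-learn `SVC`/`NuSVC`). The polynomial kernel
is (γ·⟨x, x′⟩ + coef0)^degree. The parameter grid enumerates, per
(kernel, SVM-type) pair, only the axes that matter: linear → C or ν;
RBF → γ × (C or ν); sigmoid → γ × coef0 × (C or ν); polynomial → degree ×
γ × coef0 × (C or ν), over degree ∈ {3..7}, C ∈ {2,4,10,12,15,20},
γ ∈ {0.001,…,0.1}, coef0 ∈ {0.01,…,20}, ν ∈ {0.2,0.29,0.4,0.5} — 2,590
points in total, in a fixed deterministic order.

Feature ranking for elimination always uses a *linear* C-SVM (default
C = 1, configurable), regardless of the kernel that wins the accuracy
grid: |w_j| of the linear decision function is the feature's contribution
score. Each elimination step removes exactly R (default 100) smallest-|w|
columns; ties in |w| drop the earlier column index first, so the loop is
fully deterministic. The loop interleaves re-clustering with elimination
and stops after the final evaluation once ≤ R voxels remain (or earlier if
clustering empties the active set); the active voxel count strictly
decreases, giving the ⌈n/R⌉ + 1 iteration bound.

Model selection: cross-validated F-measure, ties by recall. Among
iterations tied on both, the earliest iteration (largest voxel set) is
reported, consistent with the first-encountered rule used for tied
parameter points.

## Evaluation

Stratified k-fold assignment is constructed directly (not via
scikit-learn): fold target sizes are fixed first (N mod k remainder to the
lowest fold ids), then each class deals its floor share to every fold and
its remainder to the folds with the most remaining capacity. This
guarantees *simultaneously* that fold sizes differ by ≤ 1 and per-fold
class counts differ by ≤ 1 from an even split — e.g. a 93 + 69 cohort at
k = 10 gives exactly eight held-out folds of 16 and two of 17.
Off-the-shelf stratified splitters guarantee only the per-class property
(they produce fold sizes 15–17 in this configuration).

Cross-validated metrics pool the held-out predictions of all folds into
one confusion table (default) rather than averaging per-fold metrics;
per-fold F is unstable at fold sizes near 16 and pooling coincides with
averaging for accuracy-type counts. The fold-averaged mode is available
(`pooled=False`). Leave-one-out is k-fold with k = N, pooled. Zero
denominators in precision/recall/specificity/F are defined as 0. The
positive class is the disease class, so recall = sensitivity.

Two protocols exist and are reported as such:

* **default** — feature selection on the full cohort (matching the
  framework this package reimplements), then CV/LOO of the classification
  step. This estimate is optimistically biased: under pure noise the
  selected voxels can reach cross-validated F ≈ 0.8–1.0, because the
  selection has already seen every subject's label.
* **nested** — IG filtering, clustering, grid search and elimination
  repeated inside every training fold; held-out subjects never influence
  selection. This is the leakage-free generalization estimate, and the
  one that is chance-calibrated: on null cohorts its pooled F is
  statistically indistinguishable from the margin-implied chance level
  (verified over 20 seeds in the test suite).

## Synthetic cohorts

The generator emulates whole-brain-normalized perfusion maps: per subject,
volume = baseline·(1 + s·effect·1_cluster) + N(0, σ_noise), then Gaussian
smoothing to the target FWHM, then masking and flattening; s is the
planted cluster sign (+ with probability `effect_sign_mix`) for
positive-class subjects and 0 for controls. Smoothing is applied after
effect and noise, mimicking acquisition-side smoothing acting on signal
and noise alike. Effects are multiplicative on a positive baseline, as
appropriate for count-normalized perfusion data.

Defaults (chosen once as the package's study conditions): 40×48×35 grid
with an inscribed ellipsoid mask (≈ 30,000 voxels — a brain at roughly
4 mm resolution, and small enough that the full pipeline runs in seconds),
20 subjects per group, three ball-shaped clusters of radius 3 voxels
(123 voxels each, comfortably above the 20-voxel retention threshold),
effect size 15 %, smoothing FWHM 5 voxels, baseline 100,
noise σ = 100 before smoothing. Smoothing a white field with FWHM 5
attenuates its standard deviation ≈ 20×, so the *effective* voxel-level
inter-subject variability is ≈ 5 % of baseline, a realistic order for
normalized perfusion data. Ball centres are redrawn until pairwise
non-adjacent (centre distance > 2r + 2) and fully inside the mask, with a
bounded retry budget; everything is reproducible bit-for-bit from the
config seed.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: spatially structured (smooth) biological
variability between subjects (noise is white before smoothing, so
post-smoothing SNR is higher than in real cohorts at matched nominal
noise), vascular texture, scanner noise spectra, motion, partial-volume
effects, registration error, and site/cohort heterogeneity. Two practical
consequences observed in the integration tests: (1) with a large planted
effect, cross-validated F saturates at 1.0 from the first iteration, so
best-iteration selection falls to the tie-break rather than to a genuine
accuracy peak; (2) smoothing spreads the planted effect beyond the ball,
and the selected voxel set includes this halo, so its Jaccard overlap with
the pre-smoothing ground truth fluctuates around ≈ 0.3 (truth *coverage*
is ≥ 0.96) — the integration test asserts the median over its fixed seeds.

## Problem sizes used by the automated checks

The test suite and the acceptance script run entirely on synthetic data at
the reduced 40×48×35 scale (20 + 20 subjects; reduced SVM grids for the
loop-heavy checks), with 1000-iteration noise simulations for the
cluster-extent threshold; these sizes were chosen so a complete run takes
a few minutes on one CPU while leaving every stage's behavior measurable.
The full 79×95×69 reference grid is supported throughout and is exercised
where cheap (grid arithmetic, mask enumeration).

## Known limitations

* The default protocol's leakage (selection on all subjects) is inherent
  to the design it reimplements; use the nested mode for honest
  generalization estimates.
* The MDL-stopped discretization is one defensible choice of IG
  discretizer; other discretizers (equal-frequency, fixed-bin) give
  different survivor sets.
* The cluster-extent simulation assumes stationary Gaussian smoothness
  and controls the family-wise error of cluster extent; it is not a
  voxel-wise FDR procedure.
* `NuSVC` fits can be infeasible for some ν/data combinations; such
  solver failures are surfaced with the parameter point attached rather
  than silently skipped.
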