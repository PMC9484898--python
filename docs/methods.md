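# Methods

## The model

One case is a 3-D image volume plus a binary tumor mask on the same grid.
The analysis treats the masked voxel intensities x₁…x_N as an unordered
1-D sample: habitats are *intensity-defined* subregions, obtained by
K-means with K = 3 on the (by default z-scored) intensities, not a
spatially regularized segmentation.  The working hypothesis is the one the
clinical workflow encodes: high-grade tumors contain organized intensity
compartments (in particular a high-signal zone at the tumor edge), so
their voxel distribution clusters more cleanly than the near-homogeneous
distribution of low-grade tumors, and cluster-validity indices of the
K = 3 partition therefore carry grade information.

Five indices summarise each partition (Euclidean geometry throughout,
consistent with the K-means objective): inertia (WCSS), the
Calinski-Harabasz variance ratio, the mean silhouette coefficient,
separation, and the Davies-Bouldin index.  "Separation" has no single
standard definition; this package defines it as the between-cluster sum of
squares BCSS = Σ n_k‖μ_k − μ̄‖², the exact complement of inertia in the
total sum of squares (the minimum inter-centroid distance variant is
available via `separation_method="min_centroid_dist"`).  Because
inertia + separation = total sum of squares is an identity, those two
indices are strongly coupled; the dimensionless indices are invariant to
affine intensity rescaling while inertia and separation scale
quadratically — one reason per-case z-scoring is the default.

Downstream, cases are split 7:3 (stratified by grade, seeded), each
feature is screened by a two-sided Welch t-test when both groups pass
Shapiro-Wilk at α = 0.05 and a Mann-Whitney U-test otherwise, together
with a single-feature empirical ROC: AUC (equal to the normalized
Mann-Whitney statistic), DeLong 95% CI, and the Youden-optimal operating
point with ties broken toward higher specificity.  The classifier is a
Gaussian-process classifier with a constant × RBF kernel (single length
scale, initialized at 1, bounds 10⁻⁵–10⁵), marginal-likelihood
optimization with 3 seeded restarts and the Laplace approximation to the
Bernoulli likelihood, fitted on z-scored training features only.  Its
default feature set is the four indices the published model used
(inertia, Calinski-Harabasz, silhouette, Davies-Bouldin); data-adaptive
selection chains (univariate screen, L1-logistic with seeded CV, a
|r| > 0.9 Pearson filter that keeps the higher-AUC member, PCA at 95%
variance) are available instead.  `predict` thresholds P(high grade) at
the Youden-optimal training cutoff (0.5 via `threshold_policy="fixed"`).

Evaluation reports the ROC with DeLong CI, a quantile-binned (10 bins,
equal-count) reliability curve, and decision-curve analysis on the
threshold grid 0.01…0.99 (step 0.01) with net benefit
NB(p_t) = TP/n − (FP/n)·p_t/(1 − p_t), against treat-all and treat-none;
a case is called positive when its probability is ≥ p_t.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 3 | habitat count; matches the low/intermediate/high-signal compartment model |
| `standardize` | True | z-score intensities within each ROI before clustering so indices are comparable across scanners; raw intensities via flag |
| `n_restarts` | 10 | Lloyd restarts; alternating plain and greedy k-means++ seeding (see below) |
| `tol` | 1e-6 | relative inertia-change stop; runs also stop when the assignment is stationary |
| `silhouette_subsample` | 10,000 | cap for the O(N²) pairwise path on multi-dimensional input; 1-D input is computed exactly at any size by a sorted prefix-sum algorithm |
| `split_ratio` | 0.7 | the 7:3 training/test convention; |train| = round(0.7 n), stratified |
| `threshold_policy` | "youden" | operating cutoff on training ROC |
| phantom `grid_size` | 48 | voxels per axis |
| phantom `tumor_radii` | (10, 12, 14) | ellipsoid semi-axes, jittered ±20% per case (≈ 7,000 ROI voxels) |
| phantom `base_intensity`, `noise_sd` | 100, 10 | arbitrary MR-like units; Δ is expressed in noise-sd units |
| phantom `habitat_contrast` Δ | 3 | compartment separation of the high-grade arm; Δ = 0 collapses onto the null |
| phantom `rim_fraction` | 0.25 | outer shell thickness as a fraction of normalized radius |

## Numerical choices

- **K-means** is implemented in-package so its contracts are exact: a
  per-iteration inertia trace (non-increasing by construction), lowest-id
  tie-breaking on assignment, farthest-point repair of empty clusters (the
  returned solution never contains one), and bit-determinism given a seed.
  Restarts alternate plain k-means++ seeding with the greedy variant
  (2 + ⌊log K⌋ candidates, keep the potential-minimizing one): greedy
  starts are high-quality but highly correlated, plain starts are diverse,
  and the portfolio reaches the exhaustive dynamic-programming optimum on
  small 1-D instances far more reliably than either alone.  1-D data uses
  an O(k log n)-per-iteration sorted prefix-sum formulation whose
  semantics (ties, repair, trace) match the generic path.  Habitat ids are
  relabelled in ascending-centroid order purely for presentation; every
  index is label-permutation invariant.
- **Silhouette** uses an exact O(N log N) sorted prefix-sum computation
  for scalar points, so no subsampling bias enters the default pipeline;
  the seeded 10,000-point subsample applies only to multi-dimensional
  input.  Singleton clusters contribute s = 0.
- **Degenerate inputs**: a pure partition (WCSS = 0) yields an infinite
  Calinski-Harabasz value, reported as `inf` rather than dropped; a
  constant-intensity ROI cannot be standardized or split into 3 clusters
  and the case is excluded with a logged count, mirroring the exclusion of
  unanalyzable images from a real cohort.
- **Z-scoring** uses the sample-sd (n − 1) convention, so {1, 2, 3} maps
  exactly to {−1, 0, 1}; zero-variance features are dropped with a warning.
- **DeLong** variance uses the midrank structural-component formulation;
  the implementation matches R's `pROC::ci.auc(method="delong")` to
  10 decimals on a frozen fixture.  Zero variance (perfect separation)
  collapses the CI onto the point estimate.
- **Calibration** bins are equal-count quantile bins (robust to the skewed
  probability distributions GP classifiers produce); equal-width bins via
  `strategy="uniform"`.  Duplicate quantile edges collapse, so fewer than
  `n_bins` bins can return.
- The model artifact is a single versioned JSON file (scaler, selected
  features, optimized kernel hyperparameters, standardized training data);
  loading rebuilds the GP with the stored kernel fixed, which reproduces
  the saved model's probabilities deterministically.

## What the phantoms emulate — and what they do not

`synthetic_data` generates ellipsoidal phantoms: grade 0 is homogeneous
Gaussian signal N(μ₀, σ²); grade 1 has three concentric compartments —
core (normalized radius ρ < (1 − rim)/2) at μ₀ − Δσ/2, middle shell at
μ₀, and rim (ρ ≥ 1 − rim) at μ₀ + Δσ — plus N(0, σ²) noise, placing the
high-signal habitat at the tumor edge as observed clinically.  The
compartment count matches K = 3 by design (and is configurable to probe
misspecification); no partial-volume blur is applied by default so the
compartment-cluster correspondence stays exact in tests (an optional
Gaussian blur of 0.5 voxel stresses robustness).

The phantoms deliberately omit Rician noise, bias fields, scanner and
protocol variation, irregular tumor shapes, and any distinction between
WHO II and III.  Passing the end-to-end tests therefore demonstrates that
the pipeline recovers the *designed* heterogeneity signal at realistic
cohort sizes and is well-calibrated under the null — not that the
published clinical accuracies transfer; those depend on a patient cohort
that is not publicly available, and reproducing their numeric AUCs is
explicitly out of scope.

Note that K-means centroids are Voronoi-cell means of the intensity
mixture, not compartment means: compartments closer than ≈ 4σ (e.g. the
core, at Δσ/2 from the middle shell) yield centroids biased toward the
cell interior.  The generator tests compare sample centroids against the
population-level K-means fixed point of the exact mixture, and only the
well-separated rim centroid against its compartment mean.

## Problem sizes used in the shipped analyses

The end-to-end power analysis runs the full default pipeline on 30 + 30
case cohorts at 48³ grids, 20 seeded runs at Δ = 3 (expecting test
AUC ≥ 0.85 in at least 80%) and 20 at Δ = 0 (expecting the mean test AUC
in [0.42, 0.58]); the screening type-I-error study uses 1,000 seeded
label permutations of a 120-case null table; oracle-equivalence sweeps
use 200 random instances with N ≤ 20 and 100 exhaustive small instances
with N ≤ 12.  These sizes were chosen as the smallest designs at which
each property is statistically decisive.

## Known limitations

- Habitats are intensity-only; spatially coherent subregions
  (e.g. Gaussian-mixture or graph-regularized segmentation) are a
  different method and out of scope, as are automatic selection of K,
  DICOM ingestion, registration, bias-field correction and resampling.
- The screening report applies no multiple-testing correction by default,
  matching the workflow it reproduces; Benjamini-Hochberg is available.
- A single-draw calibration check at n = 5,000 has ≈ 20% probability of a
  bin deviation above 0.05 under perfect calibration (bin sd ≈ 0.022);
  the shipped checks average the max deviation over 10 seeded replicates.
- GP classifiers interpolate their training labels, so training-set AUC is
  near 1 even under the null; only held-out metrics are meaningful, and
  all pipeline claims are stated on the test partition.
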