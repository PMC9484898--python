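# tumorhabitat

Unsupervised *multihabitat* analysis of tumor MRI for predicting meningioma
grade.  The package segments each tumor's contrast-enhanced T1 voxels into
K = 3 intensity habitats with K-means, summarises the partition with five
cluster-validity indices used as heterogeneity features, and feeds those
features to a Gaussian-process classifier that separates high-grade
(WHO II–III) from low-grade (WHO I) meningioma, with the clinical
evaluation suite (ROC, calibration, decision-curve analysis) attached.
It is aimed at researchers in quantitative neuro-oncology imaging who want
a reproducible, testable implementation of the habitat-heterogeneity
workflow — including a phantom generator, so the whole pipeline runs and
is validated without patient data.

## Method

For one tumor, let x₁…x_N be the voxel intensities inside the mask
(z-scored within the ROI by default).  K-means with K = 3 partitions them
into habitats C₁…C_K with centroids μ_k, and the heterogeneity feature
vector is

- **inertia** (WCSS): Σ_k Σ_{x∈C_k} ‖x − μ_k‖²
- **Calinski-Harabasz index**: [BCSS/(K−1)] / [WCSS/(N−K)]
- **silhouette coefficient**: mean of (b − a)/max(a, b) over voxels
- **separation** (BCSS): Σ_k n_k ‖μ_k − μ̄‖²
- **Davies-Bouldin index**: (1/K) Σ_i max_{j≠i} (s_i + s_j)/‖μ_i − μ_j‖

A cohort of labeled cases is split 7:3 (stratified), each feature is
screened with a t- or U-test plus a single-feature ROC (AUC with DeLong
95% CI, Youden-optimal cutoff, J = sensitivity + specificity − 1), and a
Gaussian-process classifier (RBF kernel, Laplace approximation) over the
z-scored features yields P(high grade), evaluated by ROC, reliability
bins and net benefit NB(p_t) = TP/n − (FP/n)·p_t/(1 − p_t).

## Worked example

Simulate a 20 + 20 phantom cohort (low-grade tumors are homogeneous;
high-grade tumors carry a bright rim, an intermediate shell and a faint
core, at habitat contrast Δ = 3 noise-sd units) and run the full pipeline:

```bash
tumorhabitat simulate --out demo/data --seed 42 --n-low 20 --n-high 20
tumorhabitat run --input-dir demo/data --seed 42 --out demo/out
```

which prints

```
wrote 40 cases to demo/data
train AUC 1.000, test AUC 1.000 (0 case(s) excluded; config 2afaa06aa25b)
```

and writes `features.csv`, `screening.csv`, `model.json`, train/test
evaluation JSON and ROC/calibration/DCA plots under `demo/out/`.  The
screening report for this cohort:

```
          feature   auc  specificity  sensitivity  youden_index  p_value
          inertia 0.857        0.643        0.929         0.571    0.001
calinski_harabasz 0.796        0.571        1.000         0.571    0.003
       silhouette 1.000        1.000        1.000         1.000    0.000
       separation 0.505        0.286        0.929         0.214    0.872
   davies_bouldin 0.908        0.857        0.929         0.786    0.000
```

At this contrast the silhouette coefficient separates the arms perfectly
(the three phantom compartments make high-grade clusterings much cleaner),
most other indices carry signal, and the between-cluster dispersion alone
does not — a pattern consistent with silhouette being the strongest
single discriminator in the clinical study this workflow models.  The
train/test AUC of 1.0 reflects the strong effect size, small phantom
cohort, and absence of real-scanner confounds; see `docs/methods.md` for
what the phantoms do and do not emulate.

The same steps are available as library calls (`generate_cohort`,
`HeterogeneityExtractor`, `split_cohort`, `GradeClassifier`,
`evaluate_model`) — every estimator follows the scikit-learn
fit/transform/predict convention and composes with sklearn tooling.

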