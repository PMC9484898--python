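"""Cluster-validity indices used as per-tumor heterogeneity features.

Five indices summarise how cleanly a tumor's voxel intensities split into
K habitats, and together form the feature vector of one case:

* **inertia** — within-cluster sum of squares (WCSS), the K-means objective;
* **Calinski-Harabasz index** — [BCSS/(K−1)] / [WCSS/(N−K)];
* **silhouette coefficient** — mean over voxels of (b−a)/max(a,b), where a
  is the mean intra-cluster distance and b the mean distance to the nearest
  other cluster;
* **separation** — between-cluster sum of squares, BCSS = Σ_k n_k‖μ_k−μ̄‖²
  (the complement of inertia in the total sum of squares; the literature
  uses "separation" loosely, and a minimum inter-centroid-distance variant
  is available via ``separation_method``);
* **Davies-Bouldin index** — mean over clusters of the worst
  (s_i + s_j)/‖μ_i − μ_j‖ ratio, with s_i the mean distance of cluster-i
  points to their centroid.

All use Euclidean distance, consistent with the K-means objective.  A
degenerate WCSS = 0 labeling yields an infinite Calinski-Harabasz value,
reported as ``inf`` (never silently dropped).  For silhouette on large
multi-dimensional inputs a seeded subsample bounds the O(N²) cost; 1-D
inputs use an exact O(N log N) sorted-prefix-sum computation instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import IndexUndefinedError, InvalidLabelingError
from .habitat import HabitatLabeling, segment_habitats
from .io import TumorROI

__all__ = [
    "HeterogeneityFeatures",
    "FEATURE_NAMES",
    "compute_inertia",
    "compute_calinski_harabasz",
    "compute_silhouette",
    "compute_separation",
    "compute_davies_bouldin",
    "compute_all_metrics",
    "HeterogeneityExtractor",
]

FEATURE_NAMES = (
    "inertia",
    "calinski_harabasz",
    "silhouette",
    "separation",
    "davies_bouldin",
)


@dataclass(frozen=True)
class HeterogeneityFeatures:
    """The five validity indices of one case's habitat labeling."""

    inertia: float
    calinski_harabasz: float
    silhouette: float
    separation: float
    davies_bouldin: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def _validate(points, labels, centroids=None, min_k: int = 2):
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise InvalidLabelingError(
            f"{labels.shape[0]} labels for {x.shape[0]} points"
        )
    ids = np.unique(labels)
    k = ids.size
    if centroids is not None:
        centroids = np.asarray(centroids, dtype=float)
        if centroids.ndim == 1:
            centroids = centroids[:, None]
        if centroids.shape[0] < ids.max() + 1:
            raise InvalidLabelingError("fewer centroids than label ids")
        if k < centroids.shape[0]:
            raise InvalidLabelingError(
                "empty cluster: a centroid has no assigned points"
            )
    if k < min_k:
        raise IndexUndefinedError(f"index undefined for K={k} cluster(s)")
    return x, labels, centroids, ids


def compute_inertia(points, labels, centroids) -> float:
    """Within-cluster sum of squared Euclidean distances to centroids."""
    x, labels, cents, _ = _validate(points, labels, centroids)
    return float(((x - cents[labels]) ** 2).sum())


def _bcss(x: np.ndarray, labels: np.ndarray, cents: np.ndarray, ids: np.ndarray) -> float:
    gmean = x.mean(axis=0)
    counts = np.array([(labels == i).sum() for i in ids])
    return float((counts * ((cents[ids] - gmean) ** 2).sum(axis=1)).sum())


def compute_separation(points, labels, centroids) -> float:
    """Between-cluster sum of squares Σ_k n_k ‖μ_k − μ̄‖²."""
    x, labels, cents, ids = _validate(points, labels, centroids)
    return _bcss(x, labels, cents, ids)


def compute_calinski_harabasz(points, labels, centroids) -> float:
    """Variance-ratio criterion; ``inf`` when WCSS = 0 (pure clusters)."""
    x, labels, cents, ids = _validate(points, labels, centroids)
    k, n = ids.size, x.shape[0]
    wcss = float(((x - cents[labels]) ** 2).sum())
    bcss = _bcss(x, labels, cents, ids)
    if wcss == 0.0:
        return float("inf")
    return (bcss / (k - 1)) / (wcss / (n - k))


def _silhouette_1d(x: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> float:
    """Exact mean silhouette for scalar points via sorted prefix sums.

    Mean |x−y| over a sorted cluster is evaluated per query point with a
    binary search, giving O((N + Σm log m)) total instead of O(N²).
    """
    sorted_vals = {}
    prefix = {}
    counts = {}
    for i in ids:
        v = np.sort(x[labels == i])
        sorted_vals[i] = v
        prefix[i] = np.concatenate(([0.0], np.cumsum(v)))
        counts[i] = v.size

    def sum_absdiff(q: np.ndarray, cid) -> np.ndarray:
        v, p, m = sorted_vals[cid], prefix[cid], counts[cid]
        pos = np.searchsorted(v, q, side="right")
        left = q * pos - p[pos]
        right = (p[m] - p[pos]) - q * (m - pos)
        return left + right

    s = np.zeros(x.shape[0])
    for i in ids:
        sel = labels == i
        q = x[sel]
        m = counts[i]
        if m == 1:
            s[sel] = 0.0  # singleton convention
            continue
        a = sum_absdiff(q, i) / (m - 1)  # self contributes |q−q| = 0
        b = np.full(q.shape, np.inf)
        for j in ids:
            if j == i:
                continue
            b = np.minimum(b, sum_absdiff(q, j) / counts[j])
        denom = np.maximum(a, b)
        si = np.zeros_like(q)
        nz = denom > 0
        si[nz] = (b[nz] - a[nz]) / denom[nz]
        s[sel] = si
    return float(s.mean())


def _silhouette_pairwise(x: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> float:
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    n = x.shape[0]
    s = np.zeros(n)
    counts = {i: (labels == i).sum() for i in ids}
    for idx in range(n):
        own = labels[idx]
        if counts[own] == 1:
            s[idx] = 0.0
            continue
        a = d[idx, labels == own].sum() / (counts[own] - 1)
        b = min(
            d[idx, labels == j].mean() for j in ids if j != own
        )
        denom = max(a, b)
        s[idx] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def compute_silhouette(
    points,
    labels,
    subsample: int | None = 10_000,
    seed: int = 0,
) -> float:
    """Mean silhouette coefficient (Euclidean).

    1-D inputs are computed exactly at any size.  Multi-dimensional inputs
    larger than ``subsample`` points are evaluated on a seeded random
    subsample (stratification-free; the estimator's spread is bounded in
    the test suite).
    """
    x, labels, _, ids = _validate(points, labels, None)
    if x.shape[1] == 1:
        return _silhouette_1d(x[:, 0], labels, ids)
    if subsample is not None and x.shape[0] > subsample:
        rng = np.random.default_rng(seed)
        keep = rng.choice(x.shape[0], size=subsample, replace=False)
        x, labels = x[keep], labels[keep]
        ids = np.unique(labels)
        if ids.size < 2:
            raise IndexUndefinedError("subsample left a single cluster")
    return _silhouette_pairwise(x, labels, ids)


def compute_davies_bouldin(points, labels, centroids) -> float:
    """Mean worst-pair (s_i + s_j)/d_ij over clusters; 0 for pure clusters."""
    x, labels, cents, ids = _validate(points, labels, centroids)
    scatter = {}
    for i in ids:
        sel = labels == i
        scatter[i] = float(
            np.sqrt(((x[sel] - cents[i]) ** 2).sum(axis=1)).mean()
        )
    k = ids.size
    total = 0.0
    for i in ids:
        worst = 0.0
        for j in ids:
            if j == i:
                continue
            dij = float(np.sqrt(((cents[i] - cents[j]) ** 2).sum()))
            ratio = np.inf if dij == 0 else (scatter[i] + scatter[j]) / dij
            worst = max(worst, ratio)
        total += worst
    return total / k


def compute_all_metrics(
    labeling: HabitatLabeling,
    roi: TumorROI | None = None,
    separation_method: str = "bcss",
    silhouette_subsample: int | None = 10_000,
) -> HeterogeneityFeatures:
    """The five indices of one labeling, computed in its clustering feature space."""
    if labeling.points is not None:
        pts = labeling.points
    elif roi is not None:
        pts = np.asarray(roi.intensities, dtype=float)
    else:
        raise InvalidLabelingError("labeling carries no points and no roi given")
    labels, cents = labeling.labels, labeling.centroids
    if separation_method == "bcss":
        sep = compute_separation(pts, labels, cents)
    elif separation_method == "min_centroid_dist":
        c = np.atleast_2d(np.asarray(cents, dtype=float).T).T
        dists = [
            float(np.sqrt(((c[i] - c[j]) ** 2).sum()))
            for i in range(len(c))
            for j in range(i + 1, len(c))
        ]
        sep = min(dists)
    else:
        raise ValueError(f"unknown separation_method {separation_method!r}")
    return HeterogeneityFeatures(
        inertia=compute_inertia(pts, labels, cents),
        calinski_harabasz=compute_calinski_harabasz(pts, labels, cents),
        silhouette=compute_silhouette(
            pts, labels, subsample=silhouette_subsample, seed=labeling.seed
        ),
        separation=sep,
        davies_bouldin=compute_davies_bouldin(pts, labels, cents),
    )


class HeterogeneityExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping tumor ROIs to the five-index feature vector.

    Stateless (``fit`` is a no-op); ``transform`` accepts a sequence of
    :class:`~tumorhabitat.io.TumorROI` and returns an (n_cases, 5) feature
    matrix in :data:`FEATURE_NAMES` order.  Each case is clustered into
    ``k`` habitats (z-scored within the ROI when ``standardize``) before
    the indices are evaluated.
    """

    def __init__(
        self,
        k: int = 3,
        standardize: bool = True,
        n_restarts: int = 10,
        separation_method: str = "bcss",
        silhouette_subsample: int | None = 10_000,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.standardize = standardize
        self.n_restarts = n_restarts
        self.separation_method = separation_method
        self.silhouette_subsample = silhouette_subsample
        self.random_state = random_state

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for roi in X:
            labeling = segment_habitats(
                roi,
                k=self.k,
                seed=self.random_state,
                n_restarts=self.n_restarts,
                standardize=self.standardize,
            )
            rows.append(
                compute_all_metrics(
                    labeling,
                    roi,
                    separation_method=self.separation_method,
                    silhouette_subsample=self.silhouette_subsample,
                ).as_array()
            )
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
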