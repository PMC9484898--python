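import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from tumorhabitat.errors import IndexUndefinedError, InvalidLabelingError
from tumorhabitat.habitat import segment_habitats
from tumorhabitat.metrics import (
    FEATURE_NAMES,
    HeterogeneityExtractor,
    compute_all_metrics,
    compute_calinski_harabasz,
    compute_davies_bouldin,
    compute_inertia,
    compute_separation,
    compute_silhouette,
)

# mean silhouette of {0,1,10,11} | {A,A,B,B}: outer points s = 9.5/10.5,
# inner points s = 8.5/9.5 (their nearest-other-cluster mean distance is 9.5)
WORKED_SILHOUETTE = (2 * (9.5 / 10.5) + 2 * (8.5 / 9.5)) / 4  # = 0.8997494...


def _random_instance(rng, n_max=20, k_max=4, d=1):
    n = int(rng.integers(k_max + 2, n_max + 1))
    k = int(rng.integers(2, k_max + 1))
    x = rng.normal(size=(n, d))
    labels = rng.integers(0, k, size=n)
    # ensure every cluster non-empty
    labels[:k] = np.arange(k)
    cents = np.vstack([x[labels == i].mean(axis=0) for i in range(k)])
    return x, labels, cents


class TestWorkedValues:
    def test_inertia(self, worked_points):
        assert compute_inertia(*worked_points) == pytest.approx(1.0)

    def test_calinski_harabasz(self, worked_points):
        assert compute_calinski_harabasz(*worked_points) == pytest.approx(200.0)

    def test_silhouette(self, worked_points):
        points, labels, _ = worked_points
        assert compute_silhouette(points, labels) == pytest.approx(
            WORKED_SILHOUETTE, abs=1e-12
        )
        # independent oracle on the same fixture
        assert compute_silhouette(points, labels) == pytest.approx(
            silhouette_score(points[:, None], labels), abs=1e-12
        )

    def test_separation(self, worked_points):
        assert compute_separation(*worked_points) == pytest.approx(100.0)

    def test_davies_bouldin(self, worked_points):
        assert compute_davies_bouldin(*worked_points) == pytest.approx(0.1)


class TestDegenerateCases:
    def test_pure_clusters_inertia_zero_ch_infinite(self):
        pts = np.array([0.0, 0.0, 10.0, 10.0])
        labels = np.array([0, 0, 1, 1])
        cents = np.array([0.0, 10.0])
        assert compute_inertia(pts, labels, cents) == 0.0
        assert compute_calinski_harabasz(pts, labels, cents) == np.inf
        assert compute_silhouette(pts, labels) == pytest.approx(1.0)
        assert compute_davies_bouldin(pts, labels, cents) == 0.0

    def test_single_cluster_is_undefined(self):
        with pytest.raises(IndexUndefinedError):
            compute_silhouette(np.arange(4.0), np.zeros(4, dtype=int))
        with pytest.raises(IndexUndefinedError):
            compute_inertia(np.arange(4.0), np.zeros(4, dtype=int), np.array([1.5]))

    def test_empty_cluster_is_invalid(self):
        pts = np.arange(4.0)
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(InvalidLabelingError):
            compute_inertia(pts, labels, np.array([0.5, 2.5, 9.0]))

    def test_centroids_equal_global_mean_give_zero_separation(self):
        pts = np.array([-1.0, 1.0, -1.0, 1.0])
        labels = np.array([0, 0, 1, 1])
        cents = np.array([0.0, 0.0])
        assert compute_separation(pts, labels, cents) == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_indices_match_independent_oracles(self, seed):
        """sklearn implements the same textbook formulas independently."""
        rng = np.random.default_rng(seed)
        x, labels, cents = _random_instance(rng, d=int(rng.integers(1, 3)))
        assert compute_silhouette(x, labels) == pytest.approx(
            silhouette_score(x, labels), abs=1e-9
        )
        assert compute_calinski_harabasz(x, labels, cents) == pytest.approx(
            calinski_harabasz_score(x, labels), abs=1e-9, rel=1e-9
        )
        assert compute_davies_bouldin(x, labels, cents) == pytest.approx(
            davies_bouldin_score(x, labels), abs=1e-9, rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_silhouette_1d_fast_path_equals_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        x, labels, _ = _random_instance(rng, n_max=60)
        fast = compute_silhouette(x, labels)  # 1-D → prefix-sum path
        slow = compute_silhouette(np.column_stack([x[:, 0], np.zeros(len(x))]), labels)
        assert fast == pytest.approx(slow, abs=1e-9)


class TestInvariances:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_bcss_wcss_decomposition(self, seed):
        """BCSS + WCSS = total sum of squares on every instance."""
        rng = np.random.default_rng(seed)
        x, labels, cents = _random_instance(rng)
        tss = float(((x - x.mean(axis=0)) ** 2).sum())
        got = compute_separation(x, labels, cents) + compute_inertia(x, labels, cents)
        assert got == pytest.approx(tss, abs=1e-9, rel=1e-9)

    def test_permutation_and_reorder_invariance(self):
        rng = np.random.default_rng(1)
        x, labels, cents = _random_instance(rng, n_max=15, k_max=3)
        perm = np.array([2, 0, 1])[labels]  # relabel clusters
        cents_p = np.vstack([x[perm == i].mean(axis=0) for i in range(3)])
        shuf = rng.permutation(len(x))  # reorder points
        for fn in (compute_inertia, compute_calinski_harabasz,
                   compute_separation, compute_davies_bouldin):
            base = fn(x, labels, cents)
            assert fn(x, perm, cents_p) == pytest.approx(base, rel=1e-12)
            c_s = np.vstack([x[shuf][labels[shuf] == i].mean(axis=0) for i in range(3)])
            assert fn(x[shuf], labels[shuf], c_s) == pytest.approx(base, rel=1e-12)
        assert compute_silhouette(x, perm) == pytest.approx(
            compute_silhouette(x, labels), rel=1e-12
        )

    def test_affine_rescaling_behaviour(self):
        """x → ax+b: inertia and separation scale by a²; the dimensionless
        indices are unchanged."""
        rng = np.random.default_rng(2)
        x, labels, cents = _random_instance(rng)
        a, b = 3.0, 7.0
        x2 = a * x + b
        cents2 = a * cents + b
        assert compute_inertia(x2, labels, cents2) == pytest.approx(
            a**2 * compute_inertia(x, labels, cents), rel=1e-9
        )
        assert compute_separation(x2, labels, cents2) == pytest.approx(
            a**2 * compute_separation(x, labels, cents), rel=1e-9
        )
        for fn in (compute_calinski_harabasz, compute_davies_bouldin):
            assert fn(x2, labels, cents2) == pytest.approx(
                fn(x, labels, cents), rel=1e-9
            )
        assert compute_silhouette(x2, labels) == pytest.approx(
            compute_silhouette(x, labels), rel=1e-9
        )

    def test_subsampled_silhouette_is_tight(self):
        """Seeded subsampling at 5,000 points: sd of 10 draws < 0.02
        around the full computation."""
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 2500), rng.normal(4, 1, 2500)])
        labels = (x > 2).astype(int)
        full = compute_silhouette(x, labels)  # exact 1-D path
        x2 = np.column_stack([x, np.zeros_like(x)])  # force pairwise+subsample path
        draws = [
            compute_silhouette(x2, labels, subsample=1000, seed=s) for s in range(10)
        ]
        assert np.std(draws) < 0.02
        assert np.mean(draws) == pytest.approx(full, abs=0.03)


class TestComputeAll:
    def test_matches_component_operations(self, make_roi):
        roi = make_roi(np.array([0.0, 1.0, 10.0, 11.0]))
        lab = segment_habitats(roi, k=2, seed=0, standardize=False)
        f = compute_all_metrics(lab)
        assert f.inertia == pytest.approx(1.0)
        assert f.calinski_harabasz == pytest.approx(200.0)
        assert f.silhouette == pytest.approx(WORKED_SILHOUETTE)
        assert f.separation == pytest.approx(100.0)
        assert f.davies_bouldin == pytest.approx(0.1)
        np.testing.assert_array_equal(
            f.as_array(),
            [getattr(f, n) for n in FEATURE_NAMES],
        )

    def test_min_centroid_distance_separation_variant(self, make_roi):
        roi = make_roi(np.array([0.0, 1.0, 10.0, 11.0]))
        lab = segment_habitats(roi, k=2, seed=0, standardize=False)
        f = compute_all_metrics(lab, separation_method="min_centroid_dist")
        assert f.separation == pytest.approx(10.0)

    def test_extractor_transform_shape_and_determinism(self, make_roi):
        rng = np.random.default_rng(0)
        rois = [make_roi(rng.normal(size=50)) for _ in range(3)]
        ex = HeterogeneityExtractor(k=3, random_state=1)
        out1 = ex.fit_transform(rois)
        out2 = HeterogeneityExtractor(k=3, random_state=1).transform(rois)
        assert out1.shape == (3, 5)
        np.testing.assert_array_equal(out1, out2)
        assert list(ex.get_feature_names_out()) == list(FEATURE_NAMES)
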