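import numpy as np
import pytest

from tumorhabitat.io import TumorROI


@pytest.fixture
def worked_points():
    """The 1-D worked instance: two pairs {0,1} and {10,11}."""
    points = np.array([0.0, 1.0, 10.0, 11.0])
    labels = np.array([0, 0, 1, 1])
    centroids = np.array([0.5, 10.5])
    return points, labels, centroids


@pytest.fixture
def make_roi():
    def _make(intensities):
        intensities = np.asarray(intensities, dtype=float)
        coords = np.zeros((intensities.size, 3), dtype=int)
        coords[:, 0] = np.arange(intensities.size)
        return TumorROI(intensities=intensities, voxel_coords=coords, case_id="synthetic")

    return _make


def optimal_1d_kmeans_cost(x, k):
    """Exact optimal K-means WCSS in 1-D by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the DP over
    segment boundaries is exhaustive.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    ps = np.concatenate(([0.0], np.cumsum(xs)))
    ps2 = np.concatenate(([0.0], np.cumsum(xs**2)))

    def seg_cost(i, j):
        c = j - i
        s = ps[j] - ps[i]
        return (ps2[j] - ps2[i]) - s * s / c

    D = np.full((k + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            D[kk, j] = min(D[kk - 1, i] + seg_cost(i, j) for i in range(kk - 1, j))
    return float(D[k, n])
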