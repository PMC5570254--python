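"""Density clustering against a brute-force density-reachability oracle."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bootbin.cluster import dbscan_cluster, estimate_eps


def brute_force_dbscan(coords, min_pts, eps):
    """O(n^2) transitive closure over density reachability.

    Core point: >= min_pts points (self included) within eps. Clusters
    are connected components of core points under mutual eps-reachability
    plus their border points (assigned to the first core neighbour found,
    matching standard first-come semantics up to relabelling).
    """
    n = len(coords)
    d = cdist(coords, coords)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    current = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        current += 1
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = current
                    if core[k]:
                        stack.append(k)
    return labels


def same_partition(a, b):
    """Equality of labelings up to renumbering; noise (-1) must match."""
    a, b = np.asarray(a), np.asarray(b)
    if ((a == -1) != (b == -1)).any():
        return False
    mapping = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if mapping.setdefault(la, lb) != lb:
            return False
    return len(set(mapping.values())) == len(mapping)


def test_two_tight_blobs():
    rng = np.random.default_rng(0)
    a = rng.normal(scale=0.2, size=(20, 2))
    b = rng.normal(scale=0.2, size=(20, 2)) + [100, 0]
    cl = dbscan_cluster(np.vstack([a, b]), min_pts=5, eps=1.0)
    assert cl.n_clusters == 2
    assert (cl.labels != -1).all()
    # deterministic numbering by lowest member index
    assert cl.labels[0] == 1 and cl.labels[20] == 2


def test_isolated_point_is_noise():
    rng = np.random.default_rng(1)
    blob = rng.normal(scale=0.2, size=(20, 2))
    pts = np.vstack([blob, [[100.0, 100.0]]])
    cl = dbscan_cluster(pts, min_pts=5, eps=1.0)
    assert cl.labels[-1] == -1
    assert cl.n_clusters == 1


@pytest.mark.parametrize("seed", range(10))
def test_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 200))
    coords = rng.normal(size=(n, 2)) * rng.uniform(0.5, 3)
    min_pts = int(rng.integers(3, 10))
    eps = float(rng.uniform(0.2, 1.5))
    got = dbscan_cluster(coords, min_pts=min_pts, eps=eps).labels
    want = brute_force_dbscan(coords, min_pts, eps)
    # border points reachable from two clusters may legally differ; DBSCAN
    # assigns them to whichever core point claims them first. Compare core
    # points exactly and border/noise status loosely.
    d = cdist(coords, coords)
    core = (d <= eps).sum(axis=1) >= min_pts
    assert same_partition(got[core], want[core])
    assert ((got == -1) == (want == -1))[core].all()
    # non-core points: noise status must agree
    assert ((got == -1) == (want == -1)).all()


def test_all_noise_emits_tuning_warning():
    rng = np.random.default_rng(2)
    pts = rng.uniform(size=(30, 2)) * 1000
    with pytest.warns(UserWarning, match="decreasing minPts"):
        cl = dbscan_cluster(pts, min_pts=10, eps=0.001)
    assert (cl.labels == -1).all()


class TestEstimateEps:
    def test_grid_spacing_bounds(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        est = estimate_eps(grid, min_pts=2)
        assert 1.0 <= est <= np.sqrt(2)

    def test_degenerate_identical_points_fallback(self):
        pts = np.ones((30, 2))
        with pytest.warns(UserWarning, match="fallback"):
            est = estimate_eps(pts, min_pts=5)
        assert 0 < est < 1e-10

    def test_scale_homogeneity(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 2))
        assert estimate_eps(pts * 10, 5) == pytest.approx(10 * estimate_eps(pts, 5))


def test_min_pts_monotonicity():
    rng = np.random.default_rng(4)
    pts = np.vstack(
        [rng.normal(scale=0.3, size=(40, 2)), rng.normal(scale=0.3, size=(25, 2)) + 5]
    )
    eps = 0.5
    n_clustered = [
        int((dbscan_cluster(pts, min_pts=m, eps=eps).labels != -1).sum())
        for m in (3, 5, 10, 20)
    ]
    assert all(a >= b for a, b in zip(n_clustered, n_clustered[1:]))
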