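"""Density-based clustering of cluster-point 2D coordinates.

Only cluster points (length >= t_c) are clustered; border points are
embedded alongside to push clusters apart but never receive a de novo
label. Standard DBSCAN semantics: a core point has at least minPts points
(itself included) within eps, clusters are maximal density-connected
sets, and everything else is noise. eps defaults to an automatic
k-distance heuristic since users should only have to reason about minPts
(decrease it to allow small clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

DEFAULT_MIN_PTS = 20

# Quantile of the k-distance distribution used by the automatic eps rule.
_EPS_QUANTILE = 95.0


@dataclass
class ClusterLabels:
    """De novo labels (1..K, -1 = noise) for the clustered points."""

    ids: list[str]
    labels: np.ndarray  # int, -1 for noise
    eps: float
    min_pts: int

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels > 0])))

    def as_dict(self) -> dict[str, int]:
        return {i: int(l) for i, l in zip(self.ids, self.labels)}


def estimate_eps(coords: np.ndarray, min_pts: int = DEFAULT_MIN_PTS) -> float:
    """k-distance heuristic: 95th percentile of each point's distance to
    its (minPts - 1)-th nearest neighbour.

    Falls back to a machine-epsilon-scaled value (with a warning) when
    all coordinates coincide.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < min_pts + 1:
        raise ValueError(f"need at least minPts+1={min_pts + 1} points, got {n}")
    nn = NearestNeighbors(n_neighbors=min_pts).fit(coords)
    dist, _ = nn.kneighbors(coords)
    kdist = dist[:, -1]  # distance to the (minPts-1)-th neighbour (self is 0th)
    est = float(np.percentile(kdist, _EPS_QUANTILE))
    if est <= 0.0:
        scale = max(1.0, float(np.abs(coords).max()))
        est = float(np.finfo(float).eps) * scale
        warnings.warn(
            "all pairwise k-distances are zero; using machine-epsilon fallback eps",
            stacklevel=2,
        )
    return est


def dbscan_cluster(
    coords: np.ndarray,
    ids: list[str] | None = None,
    min_pts: int = DEFAULT_MIN_PTS,
    eps: float | str = "auto",
) -> ClusterLabels:
    """Cluster 2D coordinates with DBSCAN.

    Cluster numbering is deterministic: clusters are ordered by the
    lowest row index of their members and labelled 1..K; noise is -1.
    Emits a warning suggesting a smaller minPts when everything is noise.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if min_pts < 2:
        raise ValueError("minPts must be >= 2")
    if n < min_pts:
        raise ValueError(f"need at least minPts={min_pts} points, got {n}")
    if ids is None:
        ids = [str(i) for i in range(n)]

    eps_val = estimate_eps(coords, min_pts) if eps == "auto" else float(eps)
    if eps_val <= 0:
        raise ValueError("eps must be positive")

    raw = DBSCAN(eps=eps_val, min_samples=min_pts).fit_predict(coords)

    # Renumber deterministically by lowest member index.
    labels = np.full(n, -1, dtype=int)
    next_label = 1
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = next_label
            next_label += 1
        labels[i] = mapping[lab]

    if (labels == -1).all():
        warnings.warn(
            "no clusters found; consider decreasing minPts", stacklevel=2
        )
    return ClusterLabels(ids=list(ids), labels=labels, eps=eps_val, min_pts=min_pts)


def write_clusters_tsv(cl: ClusterLabels, path: str) -> None:
    with open(path, "w") as out:
        out.write("sequence_id\tcluster\n")
        for rid, lab in zip(cl.ids, cl.labels):
            out.write(f"{rid}\t{int(lab)}\n")
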