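"""Reversible point-set compression before embedding and clustering.

To speed up the embedding and the density clustering, points are randomly
sampled as *representatives*; each representative absorbs its c nearest
unassigned neighbours (its *associates*) in signature feature space. Only
representatives are embedded and clustered; decompression propagates each
representative's de novo cluster label to its associates, enlarging the
classifier training set beyond the sampled points alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CompressionMap:
    """Representatives, associates, and the associate -> representative map."""

    factor: int
    representatives: list[str]
    assoc: dict[str, str]  # associate id -> representative id
    seed: int | None = None

    @property
    def n_points(self) -> int:
        return len(self.representatives) + len(self.assoc)

    def associates_of(self, rep_id: str) -> list[str]:
        return [a for a, r in self.assoc.items() if r == rep_id]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            out.write("associate_id\trepresentative_id\n")
            for a in sorted(self.assoc):
                out.write(f"{a}\t{self.assoc[a]}\n")


def compress(
    features: np.ndarray, ids: list[str], c: int, seed: int = 0
) -> CompressionMap:
    """Greedy random compression of a point set by factor ``c``.

    Repeatedly draws an unassigned point uniformly at random as a
    representative and assigns its c nearest unassigned neighbours
    (Euclidean distance in feature space, ties broken by lower row index)
    as associates, until every point is assigned. ``c=0`` disables
    compression: every point becomes a representative.
    """
    if c < 0:
        raise ValueError("compression factor must be >= 0")
    n = features.shape[0]
    if n != len(ids):
        raise ValueError("features and ids length mismatch")
    if n == 0:
        raise ValueError("cannot compress an empty point set")
    if c == 0:
        return CompressionMap(factor=0, representatives=list(ids), assoc={}, seed=seed)

    rng = np.random.default_rng(seed)
    unassigned = list(range(n))
    reps: list[str] = []
    assoc: dict[str, str] = {}
    while unassigned:
        pick = int(rng.integers(len(unassigned)))
        rep_idx = unassigned.pop(pick)
        reps.append(ids[rep_idx])
        if unassigned and c > 0:
            cand = np.asarray(unassigned)
            d = np.linalg.norm(features[cand] - features[rep_idx], axis=1)
            order = np.lexsort((cand, d))  # distance, then lower row index
            taken = cand[order[:c]]
            for idx in taken:
                assoc[ids[int(idx)]] = ids[rep_idx]
            taken_set = set(int(t) for t in taken)
            unassigned = [i for i in unassigned if i not in taken_set]
    return CompressionMap(factor=c, representatives=reps, assoc=assoc, seed=seed)


def decompress(
    cmap: CompressionMap, rep_labels: dict[str, object]
) -> dict[str, object]:
    """Propagate representative labels to associates.

    Every representative must be labelled (noise is a label); each
    associate inherits its representative's label. The result covers
    exactly the compressed point set.
    """
    missing = [r for r in cmap.representatives if r not in rep_labels]
    if missing:
        raise ValueError(f"unlabelled representative(s): {missing[:5]}")
    out: dict[str, object] = {r: rep_labels[r] for r in cmap.representatives}
    for a, r in cmap.assoc.items():
        out[a] = rep_labels[r]
    return out
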