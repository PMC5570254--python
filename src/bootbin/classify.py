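"""The bootstrapped supervised step: random-forest label propagation.

The de novo cluster labels (decompressed to associates) become the
training response over signature features, and the fitted forest assigns
every retained sequence — cluster, border, remaining and noise points
alike — a final bin. Bins are therefore a subset of the cluster labels:
the classifier cannot invent classes, it can only extend cluster
membership to sequences that were too short to embed or too sparse to
cluster. Features are the transformed signatures, not 2D coordinates,
because remaining points are never embedded yet must be classified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .compress import CompressionMap, decompress
from .partition import ChunkMap

DEFAULT_N_TREES = 500
NOISE = -1


@dataclass
class BinningResult:
    """Final per-sequence assignment of the pipeline."""

    ids: list[str]
    roles: dict[str, str]
    cluster: dict[str, int]  # clustered ids only; -1 = noise
    bins: dict[str, int]  # every retained id
    n_bins: int
    training_size: int
    seed: int | None = None
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def bin_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for rid, b in self.bins.items():
            out.setdefault(b, []).append(rid)
        return out


def build_training_set(
    cluster_labels: dict[str, int],
    cmap: CompressionMap | None,
    feature_ids: list[str],
    features: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble the classifier training set from de novo labels.

    Training rows are the non-noise cluster points plus their
    decompressed associates with inherited labels; noise points and
    border points never enter.

    Raises
    ------
    ValueError
        If no non-noise training point exists ("no clusters to learn from").
    """
    if cmap is not None and cmap.assoc:
        labels = decompress(cmap, cluster_labels)
    else:
        labels = dict(cluster_labels)
    keep = {rid: lab for rid, lab in labels.items() if lab != NOISE}
    if not keep:
        raise ValueError("no clusters to learn from (all points are noise)")
    index = {rid: i for i, rid in enumerate(feature_ids)}
    missing = [rid for rid in keep if rid not in index]
    if missing:
        raise ValueError(f"training IDs missing from feature matrix: {missing[:5]}")
    train_ids = sorted(keep, key=lambda r: index[r])
    X = features[[index[r] for r in train_ids]]
    y = np.asarray([keep[r] for r in train_ids], dtype=int)
    return X, y, train_ids


def train_and_assign(
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_ids: list[str],
    features: np.ndarray,
    roles: dict[str, str],
    cluster_labels: dict[str, int],
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    min_vote: float = 0.0,
) -> BinningResult:
    """Fit the forest and predict a bin for every retained sequence.

    ``feature_ids``/``features`` must cover exactly the retained
    sequences (length >= min_len). With a single training class every
    sequence is trivially assigned to it, with a warning. Training
    sequences are re-predicted, so a sequence's bin may differ from its
    de novo cluster. ``min_vote`` optionally leaves sequences whose
    majority vote share falls below the threshold unbinned (off by
    default).
    """
    classes = np.unique(y_train)
    if classes.size == 0:
        raise ValueError("empty training set")
    if features.shape[0] != len(feature_ids):
        raise ValueError("feature matrix / id length mismatch")

    forest = None
    if classes.size == 1:
        warnings.warn(
            "only one cluster found; assigning every retained sequence to it",
            stacklevel=2,
        )
        pred = np.full(len(feature_ids), int(classes[0]), dtype=int)
        vote = np.ones(len(feature_ids))
    else:
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        forest.fit(X_train, y_train)
        proba = forest.predict_proba(features)
        best = np.argmax(proba, axis=1)
        pred = forest.classes_[best].astype(int)
        vote = proba[np.arange(len(pred)), best]

    bins: dict[str, int] = {}
    for rid, p, v in zip(feature_ids, pred, vote):
        if v >= min_vote:
            bins[rid] = int(p)
    result = BinningResult(
        ids=list(feature_ids),
        roles=dict(roles),
        cluster=dict(cluster_labels),
        bins=bins,
        n_bins=len(set(bins.values())),
        training_size=int(len(y_train)),
        seed=seed,
    )
    result.classifier_ = forest  # type: ignore[attr-defined]
    return result


def aggregate_chunk_bins(
    chunk_bins: dict[str, int],
    chunk_map: ChunkMap,
    chunk_lengths: dict[str, int],
) -> tuple[dict[str, int], dict[str, float]]:
    """Aggregate chunk-level bins to parent contigs by bp-weighted majority.

    The parent's bin is the bin receiving the largest total chunk length;
    ties break to the smaller bin label. Parents with no retained chunk
    are left out (unbinned). Returns (parent bin map, per-parent
    agreement fraction = winning bp / total retained bp).
    """
    weights: dict[str, dict[int, int]] = {}
    for cid, b in chunk_bins.items():
        pid = chunk_map.parent[cid]
        weights.setdefault(pid, {}).setdefault(b, 0)
        weights[pid][b] += chunk_lengths[cid]
    parent_bins: dict[str, int] = {}
    agreement: dict[str, float] = {}
    for pid, per_bin in weights.items():
        total = sum(per_bin.values())
        best = min(per_bin, key=lambda b: (-per_bin[b], b))
        parent_bins[pid] = best
        agreement[pid] = per_bin[best] / total
    return parent_bins, agreement
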