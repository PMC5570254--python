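"""End-to-end bootstrapped supervised binning as a scikit-learn estimator.

:class:`BootstrappedBinner` wires the stages together: size selection
into point roles, optional chunking, signature computation, optional
compression, 2D embedding of border + cluster representatives, density
clustering of the cluster points only, decompression of the de novo
labels, and random-forest assignment of a final bin to every retained
sequence. One master ``random_state`` derives per-stage seeds at fixed
offsets so each stage is independently reproducible.
"""

from __future__ import annotations

import time
from contextlib import contextmanager

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import classify as _classify
from . import cluster as _cluster
from . import embed as _embed
from . import partition as _partition
from . import signatures as _signatures
from .compress import compress as _compress_points
from .compress import decompress as _decompress
from .fasta_io import SequenceRecord

UNBINNED = -2  # label for sequences that received no bin (discarded, or
# parents without retained chunks in chunked mode)

_SEED_MOD = 2**31


class BootstrappedBinner(BaseEstimator):
    """Reference-independent binner for contigs and long reads.

    Parameters
    ----------
    k : int, default 5
        Oligonucleotide length of the genomic signature.
    transform : {"clr", "none"}, default "clr"
        Feature transform applied to the raw frequency vectors.
    t_b, t_c : int, default 1000
        Border-point and cluster-point length thresholds (bp); sequences
        with length >= t_c are clustered, [t_b, t_c) are embedded only,
        [min_len, t_b) are classified only. For narrow length
        distributions set t_b = t_c (e.g. both 500 for raw long reads).
    min_len : int, default 500
        Sequences below this length are discarded.
    chunk_length : int, default 0
        When > 0, split sequences into chunks of this many bp before
        binning (density normalization); parent bins are recovered by
        bp-weighted majority over chunks.
    compression : int, default 0
        Compression factor c: each randomly sampled representative absorbs
        up to c nearest neighbours. 0 disables compression.
    perplexity : float, default 30.0
        t-SNE perplexity (clamped to (n-1)/3).
    min_pts : int, default 20
        DBSCAN minPts; decrease to allow the detection of small clusters.
    eps : float or "auto", default "auto"
        DBSCAN radius; "auto" uses a k-distance percentile heuristic.
    n_trees : int, default 500
        Random-forest size.
    min_vote : float, default 0.0
        Optional minimum forest vote share; sequences below it stay
        unbinned (off by default).
    theta, n_iter
        Barnes-Hut angle and iteration count of the embedding.
    random_state : int, default 0
        Master seed; stage seeds are derived at fixed offsets.

    Attributes
    ----------
    labels_ : ndarray of int
        Bin label per input record (UNBINNED = -2 where none).
    assignments_ : DataFrame
        Per working-sequence table (sequence_id, length, role, cluster, bin).
    roles_ : dict
        Sequence ID -> role.
    cluster_labels_ : dict
        De novo cluster label per cluster point (reps and decompressed
        associates; -1 = noise).
    embedding_ : Embedding2D
        Coordinates of the embedded representatives.
    n_bins_ : int
        Number of distinct final bins.
    """

    def __init__(
        self,
        k: int = 5,
        transform: str = "clr",
        t_b: int = _partition.DEFAULT_TB,
        t_c: int = _partition.DEFAULT_TC,
        min_len: int = _partition.DEFAULT_MIN_LEN,
        chunk_length: int = 0,
        compression: int = 0,
        perplexity: float = 30.0,
        min_pts: int = _cluster.DEFAULT_MIN_PTS,
        eps: float | str = "auto",
        n_trees: int = _classify.DEFAULT_N_TREES,
        min_vote: float = 0.0,
        theta: float = 0.5,
        n_iter: int = 1000,
        random_state: int = 0,
    ):
        self.k = k
        self.transform = transform
        self.t_b = t_b
        self.t_c = t_c
        self.min_len = min_len
        self.chunk_length = chunk_length
        self.compression = compression
        self.perplexity = perplexity
        self.min_pts = min_pts
        self.eps = eps
        self.n_trees = n_trees
        self.min_vote = min_vote
        self.theta = theta
        self.n_iter = n_iter
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _stage_seed(self, offset: int) -> int:
        return (int(self.random_state) + offset) % _SEED_MOD

    @contextmanager
    def _stage(self, name: str, n_in: int):
        t0 = time.perf_counter()
        holder = {"n_out": n_in}
        try:
            yield holder
        except Exception as exc:
            raise type(exc)(f"stage '{name}': {exc}") from exc
        self.stage_log_.append(
            {
                "stage": name,
                "n_in": n_in,
                "n_out": holder["n_out"],
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )

    @staticmethod
    def _as_records(X) -> list[SequenceRecord]:
        records = []
        for item in X:
            if isinstance(item, SequenceRecord):
                records.append(item)
            elif isinstance(item, (tuple, list)) and len(item) == 2:
                records.append(SequenceRecord(id=str(item[0]), seq=str(item[1])))
            else:
                raise TypeError(
                    "records must be SequenceRecord or (id, seq) pairs"
                )
        return records

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y=None) -> "BootstrappedBinner":
        """Run the full binning pipeline on a list of sequences."""
        records = self._as_records(X)
        if not records:
            raise ValueError("no input sequences")
        _partition.validate_thresholds(self.t_b, self.t_c, self.min_len)
        self.stage_log_: list[dict] = []

        # Optional chunking: downstream stages operate on chunks.
        self.chunk_map_ = None
        working = records
        if self.chunk_length and self.chunk_length > 0:
            with self._stage("chunk", len(records)) as st:
                self.chunk_map_ = _partition.chunk_sequences(
                    records, self.chunk_length, self.min_len
                )
                working = self.chunk_map_.records
                st["n_out"] = len(working)

        lengths = {r.id: r.length for r in working}

        with self._stage("roles", len(working)) as st:
            point_roles = _partition.assign_roles(
                working, self.t_b, self.t_c, self.min_len
            )
            self.roles_ = point_roles.roles
            retained = [
                r for r in working
                if self.roles_[r.id] != _partition.ROLE_DISCARDED
            ]
            st["n_out"] = len(retained)
        if not retained:
            raise ValueError(
                f"no sequences retained (all shorter than min_len={self.min_len})"
            )

        with self._stage("signatures", len(retained)) as st:
            sig = _signatures.signature_matrix(
                [r.id for r in retained], [r.seq for r in retained], k=self.k
            )
            features = _signatures.transform(sig, mode=self.transform)
            self.signature_ids_ = sig.ids
            st["n_out"] = features.shape[0]
        feat_index = {rid: i for i, rid in enumerate(sig.ids)}

        cluster_ids = [
            r.id for r in retained if self.roles_[r.id] == _partition.ROLE_CLUSTER
        ]
        border_ids = [
            r.id for r in retained if self.roles_[r.id] == _partition.ROLE_BORDER
        ]
        if not cluster_ids:
            raise ValueError(
                "no cluster points: every sequence is shorter than "
                f"t_c={self.t_c}"
            )

        # Compression runs per role so that only cluster-point labels are
        # ever decompressed; border points are never clustered.
        with self._stage("compress", len(cluster_ids) + len(border_ids)) as st:
            self.compression_map_ = _compress_points(
                features[[feat_index[i] for i in cluster_ids]],
                cluster_ids,
                self.compression,
                seed=self._stage_seed(1),
            )
            self.border_compression_map_ = (
                _compress_points(
                    features[[feat_index[i] for i in border_ids]],
                    border_ids,
                    self.compression,
                    seed=self._stage_seed(2),
                )
                if border_ids
                else None
            )
            rep_ids = list(self.compression_map_.representatives)
            border_reps = (
                list(self.border_compression_map_.representatives)
                if self.border_compression_map_
                else []
            )
            st["n_out"] = len(rep_ids) + len(border_reps)

        with self._stage("embed", len(rep_ids) + len(border_reps)) as st:
            emb_ids = rep_ids + border_reps
            self.embedding_ = _embed.embed_2d(
                features[[feat_index[i] for i in emb_ids]],
                ids=emb_ids,
                perplexity=self.perplexity,
                seed=self._stage_seed(3),
                theta=self.theta,
                n_iter=self.n_iter,
            )
            st["n_out"] = len(emb_ids)

        with self._stage("cluster", len(rep_ids)) as st:
            coords = self.embedding_.coords[: len(rep_ids)]
            cl = _cluster.dbscan_cluster(
                coords, ids=rep_ids, min_pts=self.min_pts, eps=self.eps
            )
            self.eps_ = cl.eps
            rep_labels = cl.as_dict()
            st["n_out"] = cl.n_clusters

        with self._stage("decompress", len(rep_labels)) as st:
            self.cluster_labels_ = _decompress(
                self.compression_map_, rep_labels
            )
            st["n_out"] = len(self.cluster_labels_)

        with self._stage("train_assign", len(retained)) as st:
            X_train, y_train, train_ids = _classify.build_training_set(
                rep_labels, self.compression_map_, sig.ids, features
            )
            result = _classify.train_and_assign(
                X_train,
                y_train,
                sig.ids,
                features,
                self.roles_,
                self.cluster_labels_,
                seed=self._stage_seed(4),
                n_trees=self.n_trees,
                min_vote=self.min_vote,
            )
            self.result_ = result
            self.classifier_ = getattr(result, "classifier_", None)
            self.training_size_ = result.training_size
            self.n_bins_ = result.n_bins
            st["n_out"] = result.n_bins

        # Per working-sequence assignment table (chunks when chunked).
        rows = []
        for r in working:
            rows.append(
                {
                    "sequence_id": r.id,
                    "length": lengths[r.id],
                    "role": self.roles_[r.id],
                    "cluster": self.cluster_labels_.get(r.id),
                    "bin": result.bins.get(r.id),
                }
            )
        self.assignments_ = pd.DataFrame(rows)

        if self.chunk_map_ is not None:
            with self._stage("aggregate", len(result.bins)) as st:
                self.parent_bins_, self.agreement_ = _classify.aggregate_chunk_bins(
                    result.bins, self.chunk_map_, lengths
                )
                st["n_out"] = len(self.parent_bins_)
            bin_of = self.parent_bins_
        else:
            self.parent_bins_, self.agreement_ = None, None
            bin_of = result.bins

        self.input_ids_ = [r.id for r in records]
        self.bins_ = dict(bin_of)
        self.labels_ = np.asarray(
            [bin_of.get(r.id, UNBINNED) for r in records], dtype=int
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit the pipeline and return the bin label per input sequence."""
        return self.fit(X).labels_

    # -- conveniences ----------------------------------------------------

    def coordinates(self, place_associates: bool = True) -> dict[str, tuple[float, float]]:
        """2D coordinates for plotting.

        Representatives carry their embedded coordinates; with
        ``place_associates`` associates are placed at their
        representative's position (cosmetic only — associates were never
        embedded).
        """
        coords = self.embedding_.as_dict()
        if place_associates:
            for cmap in (self.compression_map_, self.border_compression_map_):
                if cmap is None:
                    continue
                for a, rep in cmap.assoc.items():
                    if rep in coords:
                        coords[a] = coords[rep]
        return coords
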