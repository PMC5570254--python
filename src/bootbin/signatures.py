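"""Genomic signatures: canonical k-mer frequency vectors.

Each sequence is represented by the frequencies of its oligonucleotides
(pentamers by default), pooled over both strands: a k-mer and its reverse
complement count as the same feature, since contig orientation carries no
information. Windows containing N or other ambiguity codes are skipped.
The resulting compositional vectors are optionally mapped to centered
log-ratio (CLR) coordinates before any distance-based step.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_ALPHABET = "ACGT"

# CLR pseudo-frequency is 1/(2W) for a row with W valid windows, floored
# so that very long sequences cannot drive the log argument to zero.
_PSEUDO_FLOOR = 1e-6


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def canonical_kmer(kmer: str) -> str:
    """Return the lexicographic minimum of a k-mer and its reverse complement.

    Raises
    ------
    ValueError
        If the k-mer contains a character outside {A,C,G,T}; callers
        counting windows should skip such windows instead.
    """
    if any(b not in _COMP for b in kmer):
        raise ValueError(f"ambiguous k-mer {kmer!r}: skip this window")
    return min(kmer, reverse_complement(kmer))


@functools.lru_cache(maxsize=8)
def canonical_kmers(k: int) -> tuple[str, ...]:
    """All canonical k-mers of length k, sorted. For odd k there are 4^k/2."""
    seen = set()
    for code in range(4**k):
        kmer = _decode(code, k)
        seen.add(min(kmer, reverse_complement(kmer)))
    return tuple(sorted(seen))


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(out))


@functools.lru_cache(maxsize=8)
def _canonical_index_table(k: int) -> np.ndarray:
    """Lookup table: dense k-mer code -> canonical feature index."""
    kmers = canonical_kmers(k)
    index = {km: i for i, km in enumerate(kmers)}
    table = np.empty(4**k, dtype=np.int64)
    for code in range(4**k):
        kmer = _decode(code, k)
        table[code] = index[min(kmer, reverse_complement(kmer))]
    return table


def n_canonical_kmers(k: int) -> int:
    return len(canonical_kmers(k))


def _window_codes(seq: str, k: int) -> tuple[np.ndarray, int]:
    """Dense codes of all valid (ACGT-only) k-windows and their count."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    base = np.full(codes.shape, -1, dtype=np.int64)
    for ch, val in _BASE_CODE.items():
        base[codes == ord(ch)] = val
    n_win = len(seq) - k + 1
    window = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        col = base[j : j + n_win]
        valid &= col >= 0
        window = (window << 2) | np.where(col >= 0, col, 0)
    return window[valid], int(valid.sum())


def signature(seq: str, k: int = 5) -> np.ndarray:
    """Canonical k-mer frequency vector of one sequence.

    Counts every sliding window of length k consisting only of A/C/G/T,
    maps each window to its canonical form, and normalizes by the number
    of counted windows. Returns an all-zero vector when the sequence has
    no valid window.

    Raises
    ------
    ValueError
        If ``len(seq) < k``.
    """
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k ({len(seq)} < {k})")
    D = n_canonical_kmers(k)
    codes, n_valid = _window_codes(seq.upper(), k)
    if n_valid == 0:
        return np.zeros(D)
    table = _canonical_index_table(k)
    counts = np.bincount(table[codes], minlength=D).astype(float)
    return counts / n_valid


def window_count(seq: str, k: int = 5) -> int:
    """Number of valid (ACGT-only) k-windows in ``seq``."""
    if len(seq) < k:
        return 0
    _, n_valid = _window_codes(seq.upper(), k)
    return n_valid


@dataclass
class SignatureMatrix:
    """Per-sequence raw frequency vectors with their valid window counts."""

    ids: list[str]
    k: int
    matrix: np.ndarray  # n x D raw frequencies
    window_counts: np.ndarray  # n, valid windows per row

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def signature_matrix(ids: list[str], seqs: list[str], k: int = 5) -> SignatureMatrix:
    """Stack per-sequence signatures into a :class:`SignatureMatrix`."""
    D = n_canonical_kmers(k)
    mat = np.zeros((len(seqs), D))
    wins = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        mat[i] = signature(s, k)
        wins[i] = window_count(s, k)
    return SignatureMatrix(ids=list(ids), k=k, matrix=mat, window_counts=wins)


def clr_transform(
    matrix: np.ndarray, window_counts: np.ndarray, mode: str = "clr"
) -> np.ndarray:
    """Centered log-ratio transform of a raw frequency matrix.

    Each row gets an additive pseudo-frequency of max(1/(2W), 1e-6) per
    component, where W is the row's valid-window count, then is mapped to
    log(x) minus its row mean; CLR rows sum to zero. Rows with zero valid
    windows are left as zeros (untransformable). ``mode="none"`` returns
    the input unchanged.
    """
    if mode == "none":
        return matrix.copy()
    if mode != "clr":
        raise ValueError(f"unknown transform mode {mode!r}")
    out = np.zeros_like(matrix, dtype=float)
    ok = window_counts > 0
    if ok.any():
        pseudo = np.maximum(1.0 / (2.0 * window_counts[ok]), _PSEUDO_FLOOR)
        x = matrix[ok] + pseudo[:, None]
        logx = np.log(x)
        out[ok] = logx - logx.mean(axis=1, keepdims=True)
    return out


def transform(sig: SignatureMatrix, mode: str = "clr") -> np.ndarray:
    """CLR-transform (or pass through) a :class:`SignatureMatrix`."""
    return clr_transform(sig.matrix, sig.window_counts, mode=mode)


class KmerSignature(BaseEstimator, TransformerMixin):
    """Transformer from raw DNA strings to (CLR-transformed) signatures.

    Parameters
    ----------
    k : int, default 5
        Oligonucleotide length; one of {3, 4, 5, 6}.
    norm : {"clr", "none"}, default "clr"
        Whether to apply the centered log-ratio transform.
    """

    def __init__(self, k: int = 5, norm: str = "clr"):
        self.k = k
        self.norm = norm

    def fit(self, X, y=None):
        if self.k not in (3, 4, 5, 6):
            raise ValueError(f"k must be in {{3,4,5,6}}, got {self.k}")
        self.feature_names_ = list(canonical_kmers(self.k))
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        """X is an iterable of DNA strings (or objects with a ``seq`` attr)."""
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        seqs = [getattr(x, "seq", x) for x in X]
        sig = signature_matrix([str(i) for i in range(len(seqs))], seqs, k=self.k)
        return transform(sig, mode=self.norm)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


def export_signatures_tsv(sig: SignatureMatrix, path: str) -> None:
    header = "sequence_id\t" + "\t".join(canonical_kmers(sig.k))
    with open(path, "w") as out:
        out.write(header + "\n")
        for rid, row in zip(sig.ids, sig.matrix):
            out.write(rid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
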