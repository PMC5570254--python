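"""Canonical k-mer counting and the CLR transform."""

import numpy as np
import pytest
from sklearn.base import clone

from bootbin.signatures import (
    KmerSignature,
    canonical_kmer,
    canonical_kmers,
    clr_transform,
    n_canonical_kmers,
    reverse_complement,
    signature,
    signature_matrix,
    transform,
    window_count,
)

BASES = "ACGT"


def brute_force_signature(seq, k):
    """Independent oracle: dictionary count over all sliding windows."""
    kmers = canonical_kmers(k)
    index = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros(len(kmers))
    n = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(b not in BASES for b in w):
            continue
        counts[index[min(w, reverse_complement(w))]] += 1
        n += 1
    return counts / n if n else counts


def random_dna(rng, length, with_ambiguity=False):
    alphabet = "ACGTN" if with_ambiguity else BASES
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_ambiguity else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))


def test_canonical_kmer_examples():
    assert canonical_kmer("AAAAA") == "AAAAA"
    assert canonical_kmer("TTTTT") == "AAAAA"
    with pytest.raises(ValueError, match="skip"):
        canonical_kmer("AANAA")


def test_canonical_idempotent_over_all_pentamers():
    for code in range(4**5):
        km = ""
        c = code
        for _ in range(5):
            km += BASES[c & 3]
            c >>= 2
        once = canonical_kmer(km)
        assert canonical_kmer(once) == once


@pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
def test_feature_dimension_formula(k):
    # odd k: 4^k/2; even k gains the reverse-complement palindromes
    expected = 4**k // 2 + (4 ** (k // 2) // 2 if k % 2 == 0 else 0)
    assert n_canonical_kmers(k) == expected


def test_signature_single_window_one_hot():
    vec = signature("AAAAA", k=5)
    idx = canonical_kmers(5).index("AAAAA")
    assert vec[idx] == 1.0
    assert vec.sum() == 1.0
    # two windows, same canonical k-mer
    assert np.array_equal(signature("AAAAAA", k=5), vec)


def test_signature_too_short_raises():
    with pytest.raises(ValueError, match="shorter than k"):
        signature("ACG", k=5)


@pytest.mark.parametrize("k", [4, 5])
def test_signature_matches_bruteforce_oracle(k):
    rng = np.random.default_rng(11)
    lengths = rng.integers(5, 5001, size=100)
    for i, length in enumerate(lengths):
        seq = random_dna(rng, int(length), with_ambiguity=(i % 3 == 0))
        if length < k:
            continue
        got = signature(seq, k=k)
        want = brute_force_signature(seq, k)
        np.testing.assert_array_equal(got, want)


def test_reverse_complement_invariance():
    rng = np.random.default_rng(5)
    for _ in range(20):
        seq = random_dna(rng, int(rng.integers(50, 3000)))
        np.testing.assert_array_equal(
            signature(seq, 5), signature(reverse_complement(seq), 5)
        )


def test_rows_sum_to_one_and_ambiguity_skipped():
    sig = signature("ACGTNACGTT", k=3)
    assert sig.sum() == pytest.approx(1.0, abs=1e-9)
    # all-N sequence has no valid window -> zero vector
    assert signature("NNNNNNNN", k=5).sum() == 0.0
    assert window_count("NNNNNNNN", 5) == 0


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        D = n_canonical_kmers(5)
        row = np.full((1, D), 1.0 / D)
        out = clr_transform(row, np.array([10_000]))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        sig = signature_matrix(
            ["a", "b"], ["".join(rng.choice(list(BASES), 800)) for _ in range(2)], k=4
        )
        out = transform(sig, mode="clr")
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-8)

    def test_none_mode_is_identity(self):
        mat = np.random.default_rng(1).random((3, 8))
        out = clr_transform(mat, np.array([5, 5, 5]), mode="none")
        np.testing.assert_array_equal(out, mat)

    def test_zero_window_row_left_as_zeros(self):
        mat = np.zeros((1, 8))
        out = clr_transform(mat, np.array([0]))
        np.testing.assert_array_equal(out, 0.0)


def test_transformer_sklearn_contract():
    est = KmerSignature(k=5)
    est2 = clone(est)
    assert est2.get_params() == est.get_params()
    X = est.fit_transform(["ACGTACGTACGT", "TTTTTTTTTTTT"])
    assert X.shape == (2, 512)
    with pytest.raises(ValueError, match="k must be"):
        KmerSignature(k=7).fit(["ACGTACGT"])
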