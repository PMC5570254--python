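"""The synthetic community generator that underpins every pipeline test."""

import edlib
import numpy as np
import pytest

from bootbin.signatures import signature_matrix, transform
from bootbin.synthetic import (
    CommunitySpec,
    fragment_and_corrupt,
    generate_community,
    generate_genome,
)


def test_same_seed_same_genome():
    a = generate_genome(5000, markov_order=2, seed=4)
    b = generate_genome(5000, markov_order=2, seed=4)
    assert a == b
    assert generate_genome(5000, markov_order=2, seed=5) != a


def test_order0_symmetric_base_frequencies():
    # symmetric Dirichlet, order 0, concentration high enough that the
    # sampled composition is near uniform; each base within 3 sigma of
    # the binomial expectation under the *sampled* transition probs is
    # hard to compute, so use a high concentration to pin probs ~0.25
    n = 100_000
    g = generate_genome(n, markov_order=0, seed=1, concentration=5000.0)
    for base in "ACGT":
        freq = g.count(base) / n
        sigma = np.sqrt(0.25 * 0.75 / n)
        assert abs(freq - 0.25) < 3 * sigma + 0.01


def test_genomes_more_distant_than_windows_of_one_genome():
    """The separability premise: inter-genome CLR signature distance
    exceeds the distance between two halves of the same genome."""
    g1 = generate_genome(100_000, seed=10)
    g2 = generate_genome(100_000, seed=11)
    sig = signature_matrix(
        ["g1a", "g1b", "g2"], [g1[:50_000], g1[50_000:], g2], k=5
    )
    X = transform(sig)
    intra = np.linalg.norm(X[0] - X[1])
    inter = np.linalg.norm(X[0] - X[2])
    assert inter > intra


def test_zero_error_fragments_are_exact_substrings():
    spec = CommunitySpec(fragments_per_genome=20, seed=0)
    genome = generate_genome(200_000, seed=0)
    rng = np.random.default_rng(1)
    records, truth = fragment_and_corrupt(genome, spec, "g1", rng)
    assert len(records) == 20 and len(truth) == 20
    for rec in records:
        assert rec.seq in genome


def test_error_process_matches_binomial_edit_budget():
    genome = generate_genome(200_000, seed=2)
    rng = np.random.default_rng(3)
    start, flen = 1000, 10_000
    from bootbin.synthetic import _corrupt

    frag = _corrupt(genome[start : start + flen], 0.1, rng)
    d = edlib.align(frag, genome[start : start + flen])["editDistance"]
    mean = 0.1 * flen
    sigma = np.sqrt(flen * 0.1 * 0.9)
    assert abs(d - mean) < 3 * sigma


def test_fragment_and_truth_counts():
    spec = CommunitySpec(n_genomes=5, fragments_per_genome=100, seed=0)
    records, truth = generate_community(spec)
    assert len(records) == 500
    assert len(truth) == 500
    assert {truth[r.id] for r in records} == {f"g{i}" for i in range(1, 6)}


def test_byte_identical_across_runs():
    spec = CommunitySpec(n_genomes=2, fragments_per_genome=10, seed=9)
    a, _ = generate_community(spec)
    b, _ = generate_community(spec)
    assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]


def test_lower_concentration_more_distinct_signatures():
    """Mean pairwise inter-genome signature distance grows as the
    Dirichlet concentration shrinks (monotone trend over seeds)."""

    def mean_dist(conc, seed):
        genomes = [
            generate_genome(50_000, seed=np.random.default_rng([seed, i]),
                            concentration=conc)
            for i in range(4)
        ]
        X = transform(signature_matrix([str(i) for i in range(4)], genomes, k=5))
        d = [
            np.linalg.norm(X[i] - X[j])
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        return np.mean(d)

    wins = sum(mean_dist(0.5, s) > mean_dist(50.0, s) for s in range(3))
    assert wins == 3


def test_default_fixture_is_linearly_separable(clean_community):
    """Held-out nearest-centroid accuracy > 95% guarantees the pipeline
    acceptance checks are well-posed."""
    records, truth = clean_community
    X = transform(
        signature_matrix([r.id for r in records], [r.seq for r in records], k=5)
    )
    y = np.array([truth[r.id] for r in records])
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(y))
    half = len(y) // 2
    train, test = idx[:half], idx[half:]
    centroids = {g: X[train][y[train] == g].mean(axis=0) for g in np.unique(y)}
    names = list(centroids)
    C = np.vstack([centroids[g] for g in names])
    pred = [
        names[int(np.argmin(np.linalg.norm(C - x, axis=1)))] for x in X[test]
    ]
    acc = np.mean(np.array(pred) == y[test])
    assert acc > 0.95
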