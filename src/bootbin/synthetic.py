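"""Synthetic metagenomic communities with known ground truth.

Genomes are sampled from order-m Markov chains whose per-context
transition probabilities are drawn from a symmetric Dirichlet; different
genomes therefore carry distinct oligonucleotide signatures, the premise
composition-based binning rests on. Fragments emulate either assembled
contigs or raw long reads: log-normal lengths truncated to a plausible
range, and an optional i.i.d. per-base substitution/indel process
standing in for nanopore-style sequencing noise. Every fragment carries a
ground-truth genome label, so each pipeline stage is testable without
external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .fasta_io import SequenceRecord

_BASES = "ACGT"


@dataclass
class CommunitySpec:
    """Parameters of a simulated community.

    ``fragments_per_genome`` may be a single int or one int per genome
    (to emulate uneven representation). ``dirichlet_concentration``
    controls how distinct the genome signatures are: lower values give
    more idiosyncratic transition matrices, hence larger inter-genome
    signature distances.
    """

    n_genomes: int = 5
    genome_length: int = 200_000
    markov_order: int = 2
    dirichlet_concentration: float = 1.0
    mu_frag: float = math.log(8000.0)
    sigma_frag: float = 0.8
    min_frag: int = 500
    max_frag: int = 50_000
    fragments_per_genome: int | list[int] = 150
    error_rate: float = 0.0
    seed: int = 0

    def per_genome_counts(self) -> list[int]:
        if isinstance(self.fragments_per_genome, int):
            return [self.fragments_per_genome] * self.n_genomes
        counts = list(self.fragments_per_genome)
        if len(counts) != self.n_genomes:
            raise ValueError("fragments_per_genome list must match n_genomes")
        return counts

    @classmethod
    def contigs(cls, **kw) -> "CommunitySpec":
        """Assembly-like preset: log-normal(ln 8000, 0.8) lengths, no error."""
        return cls(**kw)

    @classmethod
    def nanopore(cls, **kw) -> "CommunitySpec":
        """Raw long-read preset: log-normal(ln 6000, 1.0), 10% per-base error."""
        kw.setdefault("mu_frag", math.log(6000.0))
        kw.setdefault("sigma_frag", 1.0)
        kw.setdefault("error_rate", 0.1)
        return cls(**kw)


def generate_genome(
    length: int,
    markov_order: int = 2,
    seed: int | np.random.Generator = 0,
    concentration: float = 1.0,
) -> str:
    """Sample a genome from a random order-m Markov chain.

    A transition matrix is drawn per context (symmetric Dirichlet with the
    given concentration over the four bases), then a sequence of the
    requested length is sampled from the chain. Deterministic per seed.
    """
    if length < 4 ** (markov_order + 1):
        raise ValueError(
            f"length {length} too short for order {markov_order} "
            f"(need >= {4 ** (markov_order + 1)})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ctx = 4**markov_order if markov_order > 0 else 1
    trans = rng.dirichlet(np.full(4, concentration), size=n_ctx)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)

    out = np.empty(length, dtype=np.int64)
    ctx = 0
    mask = n_ctx - 1
    for i in range(length):
        if i < markov_order:
            b = int(np.searchsorted(np.cumsum(np.full(4, 0.25)), u[i], side="right"))
            b = min(b, 3)
        else:
            row = cum[ctx]
            b = int(np.searchsorted(row, u[i], side="right"))
            b = min(b, 3)
        out[i] = b
        ctx = ((ctx << 2) | b) & mask if markov_order > 0 else 0
    return "".join(_BASES[b] for b in out)


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: int, hi: int
) -> int:
    for _ in range(1000):
        x = int(round(rng.lognormal(mu, sigma)))
        if lo <= x <= hi:
            return x
    return int(np.clip(round(rng.lognormal(mu, sigma)), lo, hi))


def _corrupt(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions and single-base indels.

    At each position an error occurs with probability ``error_rate``;
    errors are substitutions, insertions and deletions in 2:1:1 ratio.
    """
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hit = rng.random(len(arr)) < error_rate
    kinds = rng.random(len(arr))  # <0.5 sub, <0.75 ins, else del
    subs = rng.integers(0, 4, size=len(arr))
    out: list[str] = []
    for i, ch in enumerate(seq):
        if not hit[i]:
            out.append(ch)
            continue
        if kinds[i] < 0.5:  # substitution with a different base
            b = _BASES[int(subs[i])]
            if b == ch:
                b = _BASES[(int(subs[i]) + 1) % 4]
            out.append(b)
        elif kinds[i] < 0.75:  # insertion before the base
            out.append(_BASES[int(subs[i])])
            out.append(ch)
        # else deletion: drop the base
    return "".join(out) if out else seq[:1]


def fragment_and_corrupt(
    genome: str,
    spec: CommunitySpec,
    genome_id: str,
    rng: np.random.Generator,
    n_fragments: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Draw fragments from one genome and apply the error process.

    Start positions are uniform, lengths log-normal truncated to
    [min_frag, max_frag]. IDs encode the genome and fragment index; the
    returned dict maps fragment ID -> genome label.
    """
    if spec.max_frag > len(genome):
        raise ValueError("max_frag exceeds genome length")
    n = spec.per_genome_counts()[0] if n_fragments is None else n_fragments
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for i in range(n):
        flen = _truncated_lognormal(
            rng, spec.mu_frag, spec.sigma_frag, spec.min_frag, spec.max_frag
        )
        flen = min(flen, len(genome))
        start = int(rng.integers(0, len(genome) - flen + 1))
        frag = _corrupt(genome[start : start + flen], spec.error_rate, rng)
        rid = f"{genome_id}_frag{i:04d}"
        records.append(SequenceRecord(id=rid, seq=frag))
        truth[rid] = genome_id
    return records, truth


def generate_community(
    spec: CommunitySpec,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Simulate a full community: genomes, fragments, ground truth.

    Deterministic per ``spec.seed``: genome i uses a child seed derived
    from the master seed, and fragmentation consumes an independent
    stream, so changing fragment counts does not change the genomes.
    """
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    counts = spec.per_genome_counts()
    for i in range(spec.n_genomes):
        gid = f"g{i + 1}"
        genome = generate_genome(
            spec.genome_length,
            spec.markov_order,
            seed=np.random.default_rng([spec.seed, i]),
            concentration=spec.dirichlet_concentration,
        )
        frag_rng = np.random.default_rng([spec.seed, 10_000 + i])
        recs, tr = fragment_and_corrupt(genome, spec, gid, frag_rng, counts[i])
        records.extend(recs)
        truth.update(tr)
    return records, truth


def with_fragments(spec: CommunitySpec, counts: list[int]) -> CommunitySpec:
    """Copy of ``spec`` with per-genome fragment counts replaced."""
    return replace(spec, fragments_per_genome=counts)


def write_ground_truth(truth: dict[str, str], path: str) -> None:
    with open(path, "w") as out:
        out.write("sequence_id\tgenome\n")
        for rid in truth:
            out.write(f"{rid}\t{truth[rid]}\n")
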