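"""Ground-truth-based scoring of a binning.

For each source genome g the best bin is the bin holding the largest
(bp-weighted, by default) share of g; sensitivity(g) is that share of g's
binned weight, precision(b) is the weight share of b's majority genome,
and F1(g) is the harmonic mean of sensitivity(g) and the precision of
g's best bin. Aggregates are means and medians over genomes, reported as
percentages. Weighting by bp is the default because binning quality is
about the fraction of a genome recovered; count-weighting suits
chunk-level scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class EvaluationTable:
    """Per-genome metrics (percent) and their aggregates."""

    per_genome: pd.DataFrame  # genome, best_bin, sensitivity, precision, f1
    n_bins: int
    weight: str

    @property
    def aggregates(self) -> dict[str, float]:
        out = {}
        for col in ("sensitivity", "precision", "f1"):
            out[f"mean_{col}"] = float(self.per_genome[col].mean())
            out[f"median_{col}"] = float(self.per_genome[col].median())
        return out

    def to_json_dict(self) -> dict:
        return {
            "per_genome": self.per_genome.to_dict(orient="records"),
            "aggregates": self.aggregates,
            "n_bins": self.n_bins,
            "weight": self.weight,
        }


def _harmonic(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2 * a * b / (a + b)


def score(
    bins: dict[str, int],
    truth: dict[str, str],
    lengths: dict[str, int] | None = None,
    weight: str = "bp",
    strict: bool = False,
    all_ids: list[str] | None = None,
) -> EvaluationTable:
    """Score a bin assignment against a ground-truth genome mapping.

    Parameters
    ----------
    bins
        Sequence ID -> bin label (binned sequences only).
    truth
        Sequence ID -> source genome label.
    lengths
        Sequence ID -> length in bp; required for ``weight="bp"``.
    weight
        "bp" (default) weights every sequence by its length, "count"
        weights them equally.
    strict
        When True, unbinned sequences present in ``truth`` (noise,
        discarded) count against sensitivity; by default the binner is
        scored only on what it claims to bin.
    all_ids
        With ``strict=True``, the universe of sequences the binner saw;
        defaults to the keys of ``truth``.

    Raises
    ------
    ValueError
        If no binned sequence has a ground-truth label.
    """
    if weight not in ("bp", "count"):
        raise ValueError(f"weight must be 'bp' or 'count', got {weight!r}")
    if weight == "bp" and lengths is None:
        raise ValueError("bp weighting requires sequence lengths")

    scored = {rid: b for rid, b in bins.items() if rid in truth}
    if not scored:
        raise ValueError("truth and binning share no sequence IDs")

    def w(rid: str) -> float:
        return float(lengths[rid]) if weight == "bp" else 1.0

    # weight of genome g inside bin b
    gb: dict[tuple[str, int], float] = {}
    bin_tot: dict[int, float] = {}
    genome_binned: dict[str, float] = {}
    for rid, b in scored.items():
        g = truth[rid]
        gb[(g, b)] = gb.get((g, b), 0.0) + w(rid)
        bin_tot[b] = bin_tot.get(b, 0.0) + w(rid)
        genome_binned[g] = genome_binned.get(g, 0.0) + w(rid)

    # denominator per genome: binned weight, or total weight in strict mode
    genome_tot = dict(genome_binned)
    if strict:
        universe = all_ids if all_ids is not None else list(truth)
        genome_tot = {}
        for rid in universe:
            if rid in truth:
                g = truth[rid]
                genome_tot[g] = genome_tot.get(g, 0.0) + w(rid)

    precision_of_bin = {
        b: 100.0
        * max(v for (g, bb), v in gb.items() if bb == b)
        / bin_tot[b]
        for b in bin_tot
    }

    rows = []
    for g in sorted(genome_binned):
        shares = {b: v for (gg, b), v in gb.items() if gg == g}
        best_bin = min(shares, key=lambda b: (-shares[b], b))
        sens = 100.0 * shares[best_bin] / genome_tot[g]
        prec = precision_of_bin[best_bin]
        rows.append(
            {
                "genome": g,
                "best_bin": best_bin,
                "sensitivity": sens,
                "precision": prec,
                "f1": _harmonic(sens, prec),
            }
        )
    # genomes with truth but nothing binned score zero in strict mode
    if strict:
        for g in sorted(set(genome_tot) - set(genome_binned)):
            rows.append(
                {"genome": g, "best_bin": None, "sensitivity": 0.0,
                 "precision": 0.0, "f1": 0.0}
            )
    table = pd.DataFrame(rows)
    return EvaluationTable(per_genome=table, n_bins=len(bin_tot), weight=weight)


def write_evaluation(ev: EvaluationTable, tsv_path: str, json_path: str | None = None) -> None:
    ev.per_genome.to_csv(tsv_path, sep="\t", index=False, float_format="%.4f")
    if json_path:
        import json

        with open(json_path, "w") as out:
            json.dump(ev.to_json_dict(), out, indent=2, sort_keys=True)
            out.write("\n")


def read_ground_truth(path: str) -> dict[str, str]:
    """Read a two-column 'sequence_id<TAB>genome' table (header optional)."""
    truth: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0] in ("sequence_id", "id"):
                continue
            truth[parts[0]] = parts[1]
    return truth
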