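"""Reading and writing the flat-file formats the binner touches.

Input is a single FASTA file of nucleotide sequences (contigs or long
reads); outputs are per-bin FASTA files plus tab-separated assignment and
annotation tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio.SeqIO.FastaIO import SimpleFastaParser

# Nucleotide alphabet including IUPAC ambiguity codes. U is folded to T at
# read time; anything outside this set counts as a non-nucleotide residue.
_IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

_LINE_WIDTH = 70


@dataclass(frozen=True)
class SequenceRecord:
    """A single input sequence: unique ID and uppercase DNA residues."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AnnotationTable:
    """Per-sequence free-text annotations plus IDs that matched nothing."""

    entries: dict[str, str] = field(default_factory=dict)
    unknown_ids: list[str] = field(default_factory=list)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The record ID is the header token up to the first whitespace;
    residues are uppercased and U is mapped to T.

    Raises
    ------
    ValueError
        If the file contains no sequences, a duplicate ID, or a record
        whose residues are mostly non-nucleotide (likely a protein file).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rid = title.split(None, 1)[0] if title.strip() else ""
            if not rid:
                raise ValueError("FASTA record with empty header")
            if rid in seen:
                raise ValueError(f"duplicate sequence ID: {rid!r}")
            seen.add(rid)
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise ValueError(f"sequence {rid!r} is empty")
            bad = sum(1 for ch in seq if ch not in _IUPAC_DNA)
            if bad / len(seq) > 0.5:
                raise ValueError(
                    f"sequence {rid!r}: more than 50% non-nucleotide residues; "
                    "is this a protein FASTA file?"
                )
            records.append(SequenceRecord(id=rid, seq=seq))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + _LINE_WIDTH] for i in range(0, len(seq), _LINE_WIDTH))


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records to ``path`` in FASTA format (70-column wrapped)."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n{_wrap(rec.seq)}\n")


def write_bin_fastas(
    records: list[SequenceRecord],
    bins: dict[str, int],
    out_dir: str | os.PathLike,
    clusters: dict[str, int] | None = None,
) -> list[str]:
    """Write one FASTA file per bin plus a summary TSV.

    Parameters
    ----------
    records
        All input sequences.
    bins
        Mapping sequence ID -> final bin label. IDs absent from the
        mapping (discarded or unbinned sequences) go to ``unbinned.fasta``
        if any exist.
    out_dir
        Output directory (created if missing).
    clusters
        Optional mapping sequence ID -> intermediate cluster label,
        included in the summary TSV (-1 denotes noise; blank if the
        sequence was never clustered).

    Returns
    -------
    list of str
        Paths of the FASTA files written.
    """
    os.makedirs(out_dir, exist_ok=True)
    by_id = {r.id: r for r in records}
    missing = [rid for rid in bins if rid not in by_id]
    if missing:
        raise ValueError(f"binned IDs not among records: {missing[:5]}")

    members: dict[int, list[SequenceRecord]] = {}
    for rid, label in bins.items():
        members.setdefault(label, []).append(by_id[rid])

    paths: list[str] = []
    for label in sorted(members):
        path = os.path.join(out_dir, f"bin_{label:03d}.fasta")
        write_fasta(members[label], path)
        paths.append(path)

    unbinned = [r for r in records if r.id not in bins]
    if unbinned:
        path = os.path.join(out_dir, "unbinned.fasta")
        write_fasta(unbinned, path)
        paths.append(path)

    clusters = clusters or {}
    summary = os.path.join(out_dir, "bin_summary.tsv")
    with open(summary, "w") as out:
        out.write("sequence_id\tcluster\tbin\n")
        for rec in records:
            c = clusters.get(rec.id, "")
            b = bins.get(rec.id, "")
            out.write(f"{rec.id}\t{c}\t{b}\n")
    return paths


def read_annotations(path: str | os.PathLike, known_ids: set[str]) -> AnnotationTable:
    """Read a two-column tab-separated annotation file.

    First column is the sequence ID, second the annotation label. IDs not
    in ``known_ids`` are collected as warnings, not errors.
    """
    table = AnnotationTable()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=2 tab-separated columns"
                )
            rid, label = parts[0], parts[1]
            if rid in known_ids:
                table.entries[rid] = label
            else:
                table.unknown_ids.append(rid)
    return table


def write_assignments(df, path: str | os.PathLike) -> None:
    """Write the per-sequence assignment table.

    Expects a DataFrame with columns sequence_id, length, role, cluster,
    bin; cluster/bin are blank for sequences that have none.
    """
    import pandas as pd

    cols = ["sequence_id", "length", "role", "cluster", "bin"]
    out = df[cols].copy()
    for col in ("cluster", "bin"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)
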