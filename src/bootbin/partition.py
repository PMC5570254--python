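"""Size selection of sequences into point roles, and optional chunking.

Long sequences ("cluster points", length >= t_c) are the only ones
density-clustered; mid-length "border points" (t_b <= length < t_c) are
embedded to pad the space between clusters but never clustered; short
"remaining points" (min_len <= length < t_b) are neither embedded nor
clustered and get their bin only from the trained classifier; anything
below min_len is discarded. Chunking splits long sequences into
fixed-length fragments so that cluster-point density reflects genome
length rather than contig count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fasta_io import SequenceRecord

ROLE_CLUSTER = "cluster"
ROLE_BORDER = "border"
ROLE_REMAINING = "remaining"
ROLE_DISCARDED = "discarded"

DEFAULT_TB = 1000
DEFAULT_TC = 1000
DEFAULT_MIN_LEN = 500
DEFAULT_CHUNK_LENGTH = 3000


@dataclass
class PointRoles:
    """Role per sequence plus the thresholds that produced the partition."""

    roles: dict[str, str]
    t_b: int
    t_c: int
    min_len: int

    def ids_with_role(self, role: str) -> list[str]:
        return [rid for rid, r in self.roles.items() if r == role]

    def counts(self) -> dict[str, int]:
        out = {ROLE_CLUSTER: 0, ROLE_BORDER: 0, ROLE_REMAINING: 0, ROLE_DISCARDED: 0}
        for r in self.roles.values():
            out[r] += 1
        return out


def validate_thresholds(t_b: int, t_c: int, min_len: int) -> None:
    if not (min_len <= t_b <= t_c):
        raise ValueError(
            f"thresholds must satisfy min_len <= t_b <= t_c "
            f"(got min_len={min_len}, t_b={t_b}, t_c={t_c}); "
            "consider decreasing t_c to the value of t_b"
        )


def role_for_length(length: int, t_b: int, t_c: int, min_len: int) -> str:
    """Role of a sequence of the given length; lower edges are inclusive."""
    if length >= t_c:
        return ROLE_CLUSTER
    if length >= t_b:
        return ROLE_BORDER
    if length >= min_len:
        return ROLE_REMAINING
    return ROLE_DISCARDED


def assign_roles(
    records: list[SequenceRecord],
    t_b: int = DEFAULT_TB,
    t_c: int = DEFAULT_TC,
    min_len: int = DEFAULT_MIN_LEN,
) -> PointRoles:
    """Partition sequences into cluster/border/remaining/discarded roles."""
    validate_thresholds(t_b, t_c, min_len)
    roles = {r.id: role_for_length(r.length, t_b, t_c, min_len) for r in records}
    return PointRoles(roles=roles, t_b=t_b, t_c=t_c, min_len=min_len)


@dataclass
class ChunkMap:
    """Chunked records plus the chunk -> parent bookkeeping."""

    records: list[SequenceRecord]
    parent: dict[str, str]  # chunk id -> parent id
    offset: dict[str, int] = field(default_factory=dict)  # chunk id -> 0-based start
    chunk_length: int = DEFAULT_CHUNK_LENGTH

    def chunks_of(self, parent_id: str) -> list[SequenceRecord]:
        chunks = [r for r in self.records if self.parent[r.id] == parent_id]
        return sorted(chunks, key=lambda r: self.offset[r.id])


def chunk_sequences(
    records: list[SequenceRecord],
    chunk_length: int = DEFAULT_CHUNK_LENGTH,
    min_len: int = DEFAULT_MIN_LEN,
) -> ChunkMap:
    """Split each sequence into consecutive non-overlapping chunks.

    A trailing remainder shorter than ``min_len`` is merged into the
    preceding chunk (so a 6200 bp sequence at chunk_length 3000 yields
    chunks of 3000 and 3200 bp); sequences shorter than ``chunk_length``
    become a single chunk.
    """
    if chunk_length < min_len:
        raise ValueError(
            f"chunk_length ({chunk_length}) must be >= min_len ({min_len})"
        )
    out_records: list[SequenceRecord] = []
    parent: dict[str, str] = {}
    offset: dict[str, int] = {}
    for rec in records:
        starts = list(range(0, rec.length, chunk_length))
        # Merge an undersized final chunk into its predecessor.
        if len(starts) > 1 and rec.length - starts[-1] < min_len:
            starts.pop()
        for i, start in enumerate(starts):
            end = start + chunk_length if i < len(starts) - 1 else rec.length
            cid = f"{rec.id}|chunk{i}"
            out_records.append(SequenceRecord(id=cid, seq=rec.seq[start:end]))
            parent[cid] = rec.id
            offset[cid] = start
    return ChunkMap(
        records=out_records, parent=parent, offset=offset, chunk_length=chunk_length
    )
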