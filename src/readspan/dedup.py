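"""Duplicate-read detection.

High-coverage sequencing emits many exact duplicate reads, on the original
strand or as reverse complements.  Before any graph is built, the read set
is collapsed to its distinct reads; each distinct read keeps a count of its
normal-strand and reverse-complement copies (the node multiplicity label).

Candidate duplicates are grouped into blocks keyed by their canonical
31-minimizer and its position, then verified by full string comparison, so
hash collisions can never merge unequal reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kmers
from .fastq_io import ReadSet

__all__ = ["DupRecord", "DedupResult", "reverse_complement", "find_duplicates"]

DEDUP_K = 31  # k-mer size used for duplicate blocking

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass
class DupRecord:
    """Copies of one distinct read in the original file.

    ``representative_index`` indexes the distinct-read list; member index
    lists hold original-file indices.  The representative (first occurrence)
    is not counted among the members.
    """

    representative_index: int
    rep_original_index: int
    normal_members: list[int] = field(default_factory=list)
    rc_members: list[int] = field(default_factory=list)

    @property
    def normal_count(self) -> int:
        return len(self.normal_members)

    @property
    def rc_count(self) -> int:
        return len(self.rc_members)

    @property
    def member_indices(self) -> list[int]:
        return [self.rep_original_index] + self.normal_members + self.rc_members


@dataclass
class DedupResult:
    distinct: ReadSet
    records: list[DupRecord]
    orig_to_distinct: np.ndarray  # original index -> distinct index
    orig_is_rc: np.ndarray  # original read equals rc(representative)

    @property
    def n_distinct(self) -> int:
        return len(self.distinct.sequences)


def _canonical(seq: str) -> tuple[str, bool]:
    """Lexicographically smaller of a read and its reverse complement."""
    rc = reverse_complement(seq)
    return (seq, False) if seq <= rc else (rc, True)


def _block_keys(seqs: list[str]):
    """Strand-symmetric block key per read.

    The key is computed from the canonical orientation of the read, so a
    read and its reverse complement always land in the same block.  Reads
    too short for a 31-mer, or with no N-free window, fall back to the
    canonical string itself as the key (still strand symmetric, still a
    valid blocking key for exact duplicates).
    """
    canon = [_canonical(s)[0] for s in seqs]
    keys: list[tuple] = [None] * len(seqs)  # type: ignore[list-item]
    by_len: dict[int, list[int]] = {}
    for i, c in enumerate(canon):
        by_len.setdefault(len(c), []).append(i)
    for L, idxs in by_len.items():
        if L < DEDUP_K:
            for i in idxs:
                keys[i] = ("raw", canon[i])
            continue
        mat = _kmers.encode_matrix([canon[i] for i in idxs])
        codes, pos, strand, valid = _kmers.extreme_kmers(
            mat, DEDUP_K, both_strands=True
        )
        for j, i in enumerate(idxs):
            if valid[j]:
                keys[i] = (L, int(codes[j]), int(pos[j]), bool(strand[j]))
            else:
                keys[i] = ("raw", canon[i])
    return keys, canon


def find_duplicates(reads: ReadSet) -> DedupResult:
    """Collapse exact duplicates (same strand or reverse complement).

    Distinct reads keep first-occurrence order and orientation; a later read
    equal to the reverse complement of an earlier one is recorded as an RC
    duplicate of it.  A read equal to its own reverse complement counts its
    extra copies as normal duplicates.
    """
    seqs = reads.sequences
    m = len(seqs)
    keys, _canon = _block_keys(seqs)

    blocks: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        blocks.setdefault(key, []).append(i)

    records: list[DupRecord] = []
    distinct_seqs: list[str] = []
    orig_to_distinct = np.empty(m, dtype=np.int64)
    orig_is_rc = np.zeros(m, dtype=bool)
    rep_by_seq: dict[tuple, dict[str, int]] = {}

    order = sorted(blocks, key=lambda k: blocks[k][0])
    for key in order:
        members = blocks[key]
        seen: dict[str, int] = {}
        rep_by_seq[key] = seen
        for i in members:
            s = seqs[i]
            d = seen.get(s)
            if d is not None:  # normal-strand duplicate (full-string verified)
                records[d].normal_members.append(i)
                orig_to_distinct[i] = d
                continue
            rc = reverse_complement(s)
            d = seen.get(rc)
            if d is not None and rc != s:  # reverse-complement duplicate
                records[d].rc_members.append(i)
                orig_to_distinct[i] = d
                orig_is_rc[i] = True
                continue
            d = len(distinct_seqs)
            distinct_seqs.append(s)
            records.append(DupRecord(representative_index=d, rep_original_index=i))
            seen[s] = d
            orig_to_distinct[i] = d

    # restore first-occurrence order of distinct reads
    perm = sorted(range(len(records)), key=lambda d: records[d].rep_original_index)
    remap = np.empty(len(records), dtype=np.int64)
    for new, old in enumerate(perm):
        remap[old] = new
    distinct_seqs = [distinct_seqs[d] for d in perm]
    records = [records[d] for d in perm]
    for new, rec in enumerate(records):
        rec.representative_index = new
    orig_to_distinct = remap[orig_to_distinct]

    distinct = ReadSet(
        sequences=distinct_seqs,
        read_length=reads.read_length,
        read_length2=reads.read_length2,
        n1=len(distinct_seqs),
    )
    return DedupResult(
        distinct=distinct,
        records=records,
        orig_to_distinct=orig_to_distinct,
        orig_is_rc=orig_is_rc,
    )
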