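"""Stream encoding/decoding of a read forest.

Every non-root read is written as a tiny reference code against its parent:
a *shifting substring* (the bases the parent does not cover, as many as the
shifting offset) followed by *mismatch items* (delta-encoded 0-based child
position + replacement base).  A read "ATGCAT" whose parent is "GCATCC" at
shift 2 becomes "AT2G".  The decoder infers the offset from the length of
the leading base run, so no side information per read is needed.

Order-free mode serializes trees in DFS preorder with backtracking step
numbers; order-preserving mode writes one line per original read plus a
parent-ID stream.  Paired-end pairing is stored as visiting-order distances
maintained with a Fenwick tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dedup import DedupResult, DupRecord, reverse_complement
from .fastq_io import ReadSet
from .msf import Forest, ROOT

__all__ = [
    "EncodingError",
    "StreamBundle",
    "encode_child",
    "decode_child",
    "dfs_encode",
    "order_preserving_encode",
    "pair_distance_stream",
    "renumber_read_ids",
    "Fenwick",
]

_DIGITS = set("0123456789")
TREE_SEPARATOR = "-"


class EncodingError(ValueError):
    """Internal encoding inconsistency or malformed encoded text."""


# ---------------------------------------------------------------------------
# child <-> parent reference codes
# ---------------------------------------------------------------------------


def _format_items(positions: list[int], bases: list[str]) -> str:
    parts = []
    prev = 0
    for i, (p, b) in enumerate(zip(positions, bases)):
        parts.append(f"{p if i == 0 else p - prev}{b}")
        prev = p
    return "".join(parts)


def encode_child(
    child: str,
    parent: str,
    delta_cp: int,
    rc: bool,
    *,
    check: bool = True,
) -> tuple[str, int]:
    """Encode ``child`` against ``parent``.

    ``delta_cp`` is (child start - parent start) in the parent's forward
    frame; when ``rc`` is set the child is taken as its reverse complement.
    Returns ``(text, direction_bit)`` with direction 1 = right shift (child
    starts after the parent; the shifting substring is the child's tail)
    and 0 = left shift (substring is the child's head).  Mismatch positions
    are 0-based child coordinates, delta encoded.
    """
    cc = reverse_complement(child) if rc else child
    Lc, Lp = len(cc), len(parent)
    if delta_cp >= 0:
        ob, direction = delta_cp, 1
        if ob > Lc or Lc > Lp:
            raise EncodingError("layout not encodable as a single shifting substring")
        ref = parent[ob:Lc]
        positions = [i for i in range(Lc - ob) if cc[i] != ref[i]]
        substring = cc[Lc - ob :]
    else:
        ob, direction = -delta_cp, 0
        if ob > Lc or Lc - ob > Lp:
            raise EncodingError("layout not encodable as a single shifting substring")
        ref = parent[: Lc - ob]
        positions = [ob + i for i in range(Lc - ob) if cc[ob + i] != ref[i]]
        substring = cc[:ob]
    text = substring + _format_items(positions, [cc[p] for p in positions])
    if not text:
        raise EncodingError(
            "child identical to parent at offset 0 (duplicates must be collapsed)"
        )
    if check and decode_child(parent, text, direction, rc, Lc) != child:
        raise EncodingError("encode/decode self-check failed")
    return text, direction


def parse_encoded_text(text: str) -> tuple[str, list[tuple[int, str]]]:
    """Split an encoded string into (shifting substring, mismatch items).

    Item positions are returned absolute (delta decoding applied).
    """
    i = 0
    while i < len(text) and text[i] not in _DIGITS:
        i += 1
    substring = text[:i]
    items: list[tuple[int, str]] = []
    prev = 0
    while i < len(text):
        j = i
        while j < len(text) and text[j] in _DIGITS:
            j += 1
        if j == i or j == len(text):
            raise EncodingError(f"malformed encoded string {text!r}")
        pos = int(text[i:j]) + (prev if items else 0)
        items.append((pos, text[j]))
        prev = pos
        i = j + 1
    return substring, items


def decode_child(
    parent: str, text: str, direction_bit: int, rc_bit: int | bool, L_child: int
) -> str:
    """Exact inverse of :func:`encode_child`."""
    substring, items = parse_encoded_text(text)
    ob = len(substring)
    if ob > L_child:
        raise EncodingError("shifting substring longer than the read")
    copy_len = L_child - ob
    if direction_bit:
        if L_child > len(parent):
            raise EncodingError("parent too short for right-shift decode")
        cc = list(parent[ob:L_child]) + list(substring)
    else:
        if copy_len > len(parent):
            raise EncodingError("parent too short for left-shift decode")
        cc = list(substring) + list(parent[:copy_len])
    for pos, base in items:
        if not 0 <= pos < L_child:
            raise EncodingError(f"mismatch position {pos} outside the read")
        cc[pos] = base
    out = "".join(cc)
    return reverse_complement(out) if rc_bit else out


def is_backtrack_line(line: str) -> bool:
    """Stream-1 line classification: backtracking numbers are all digits,
    encoded strings always contain at least one letter."""
    return bool(line) and set(line) <= _DIGITS


# ---------------------------------------------------------------------------
# stream bundle
# ---------------------------------------------------------------------------


@dataclass
class StreamBundle:
    """The raw encoding streams of one archive, before backend compression.

    Streams 1-5 follow the MSF encoding layout: encoded strings and
    backtracking numbers; shifting-direction bits; RC-strand bits;
    has-duplicates bits; (normal, RC) duplicate count pairs.  Mode-specific
    streams (parent IDs, singleton flags, pair distances/order) are present
    only where the mode requires them.
    """

    s1_lines: list[str] = field(default_factory=list)
    s2_dir_bits: list[int] = field(default_factory=list)
    s3_rc_bits: list[int] = field(default_factory=list)
    s4_dup_bits: list[int] = field(default_factory=list)
    s5_dup_counts: list[tuple[int, int]] = field(default_factory=list)
    parent_ids: list[int] = field(default_factory=list)
    singleton_bits: list[int] = field(default_factory=list)
    pair_distances: list[int] = field(default_factory=list)
    pair_order_bits: list[int] = field(default_factory=list)
    pair_original_order: list[int] = field(default_factory=list)


def _edge_layout(forest: Forest, seqs: list[str], child: int) -> tuple[int, bool]:
    edge = forest.edge_of[child]
    assert edge is not None
    return edge.child_layout(child, len(seqs[edge.u]), len(seqs[edge.v]))


# ---------------------------------------------------------------------------
# order-free (DFS) encoding
# ---------------------------------------------------------------------------


def dfs_encode(
    forest: Forest,
    distinct: ReadSet | list[str],
    dedup: DedupResult,
    *,
    check: bool = True,
) -> tuple[StreamBundle, np.ndarray]:
    """Serialize the forest in DFS preorder (order-free mode).

    Stream 1 holds each tree's root read followed by the children's encoded
    strings in preorder; after finishing a subtree, a line with the count of
    consecutive upward steps precedes the next descent (trailing pops at a
    tree's end are omitted; a "-" line separates trees).

    Also assigns every original read (including duplicates) its visiting
    rank -- representative first, then normal copies, then RC copies -- and
    returns the original-index -> rank array used by the pairing streams.
    """
    seqs = distinct.sequences if isinstance(distinct, ReadSet) else distinct
    bundle = StreamBundle()
    n_orig = len(dedup.orig_to_distinct)
    rank_of = np.full(n_orig, -1, dtype=np.int64)
    next_rank = 0

    def emit(node: int) -> None:
        nonlocal next_rank
        rec = dedup.records[node]
        has_dups = rec.normal_count + rec.rc_count > 0
        bundle.s4_dup_bits.append(int(has_dups))
        if has_dups:
            bundle.s5_dup_counts.append((rec.normal_count, rec.rc_count))
        for orig in rec.member_indices:
            rank_of[orig] = next_rank
            next_rank += 1

    for root in forest.roots:
        if bundle.s1_lines:
            bundle.s1_lines.append(TREE_SEPARATOR)
        bundle.s1_lines.append(seqs[root])
        emit(root)
        stack: list[list[int]] = [[root, 0]]
        pending_pops = 0
        while stack:
            node, ci = stack[-1]
            kids = forest.children[node]
            if ci < len(kids):
                stack[-1][1] += 1
                child = kids[ci]
                if pending_pops:
                    bundle.s1_lines.append(str(pending_pops))
                    pending_pops = 0
                delta_cp, rc = _edge_layout(forest, seqs, child)
                text, direction = encode_child(
                    seqs[child], seqs[node], delta_cp, rc, check=check
                )
                bundle.s1_lines.append(text)
                bundle.s2_dir_bits.append(direction)
                bundle.s3_rc_bits.append(int(rc))
                emit(child)
                stack.append([child, 0])
            else:
                stack.pop()
                pending_pops += 1
    return bundle, rank_of


def decode_order_free_structure(lines: list[str]) -> list[tuple[str, int]]:
    """Rebuild tree structure from stream-1 lines without decoding bases.

    Returns, per encoded node in emission order, ``(text, parent_emission
    index)`` with -1 for roots.
    """
    nodes: list[tuple[str, int]] = []
    stack: list[int] = []
    for line in lines:
        if line == TREE_SEPARATOR:
            stack.clear()
        elif is_backtrack_line(line):
            pops = int(line)
            if pops <= 0 or pops > len(stack):
                raise EncodingError(f"invalid backtracking step number {line!r}")
            del stack[-pops:]
        else:
            parent = stack[-1] if stack else -1
            nodes.append((line, parent))
            stack.append(len(nodes) - 1)
    return nodes


# ---------------------------------------------------------------------------
# order-preserving encoding
# ---------------------------------------------------------------------------


def renumber_read_ids(
    n_reads: int,
    duplicate_indices: set[int],
    singleton_indices: set[int],
) -> dict[int, int]:
    """Parent-reference numbering of the order-preserving mode.

    Duplicating reads and singleton reads can never be parents, so they are
    removed and the remaining reads are renumbered 1..K in original order.
    Indices are 0-based; the returned IDs are 1-based (0 is the root
    sentinel in the parent-ID stream).
    """
    ids: dict[int, int] = {}
    next_id = 1
    for i in range(n_reads):
        if i in duplicate_indices or i in singleton_indices:
            continue
        ids[i] = next_id
        next_id += 1
    return ids


def order_preserving_encode(
    forest: Forest,
    distinct: ReadSet | list[str],
    dedup: DedupResult,
    *,
    check: bool = True,
) -> StreamBundle:
    """One stream-1 line per original read, in original file order.

    Duplicating reads become empty lines (their representative's ID goes to
    the parent-ID stream, with the RC bit in stream 3); roots store their
    raw read with parent ID 0; children store their encoded string with the
    parent's renumbered ID.  A per-distinct-read singleton flag lets the
    decoder reproduce the renumbering.  Streams 4 and 5 are not used.
    """
    seqs = distinct.sequences if isinstance(distinct, ReadSet) else distinct
    bundle = StreamBundle()
    n_orig = len(dedup.orig_to_distinct)

    rep_orig = {rec.rep_original_index: d for d, rec in enumerate(dedup.records)}
    duplicate_orig = {
        i for i in range(n_orig) if i not in rep_orig
    }
    singleton_orig = {
        rec.rep_original_index
        for d, rec in enumerate(dedup.records)
        if forest.is_singleton(d)
    }
    parent_ids_by_orig = renumber_read_ids(n_orig, duplicate_orig, singleton_orig)

    for i in range(n_orig):
        d = int(dedup.orig_to_distinct[i])
        if i in duplicate_orig:
            bundle.s1_lines.append("")
            bundle.parent_ids.append(d + 1)  # distinct numbering, 1-based
            bundle.s2_dir_bits.append(0)
            bundle.s3_rc_bits.append(int(dedup.orig_is_rc[i]))
            continue
        bundle.singleton_bits.append(int(forest.is_singleton(d)))
        if forest.parent_of[d] == ROOT:
            bundle.s1_lines.append(seqs[d])
            bundle.parent_ids.append(0)
            bundle.s2_dir_bits.append(0)
            bundle.s3_rc_bits.append(0)
        else:
            parent = int(forest.parent_of[d])
            delta_cp, rc = _edge_layout(forest, seqs, d)
            text, direction = encode_child(
                seqs[d], seqs[parent], delta_cp, rc, check=check
            )
            bundle.s1_lines.append(text)
            parent_orig = dedup.records[parent].rep_original_index
            bundle.parent_ids.append(parent_ids_by_orig[parent_orig])
            bundle.s2_dir_bits.append(direction)
            bundle.s3_rc_bits.append(int(rc))
    return bundle


def decode_order_preserving(
    bundle: StreamBundle, read_length: int
) -> list[str]:
    """Inverse of :func:`order_preserving_encode` (single-end)."""
    lines = bundle.s1_lines
    n = len(lines)
    non_empty = [i for i in range(n) if lines[i] != ""]
    if len(bundle.singleton_bits) != len(non_empty):
        raise EncodingError("singleton flag stream length mismatch")
    # distinct numbering: all non-empty lines; parent numbering: non-singletons
    parent_numbering = [
        i for i, flag in zip(non_empty, bundle.singleton_bits) if not flag
    ]
    resolved: list[Optional[str]] = [None] * n

    def ref_of(i: int) -> int:
        pid = bundle.parent_ids[i]
        if lines[i] == "":
            if not 1 <= pid <= len(non_empty):
                raise EncodingError(f"duplicate reference {pid} out of range")
            return non_empty[pid - 1]
        if not 1 <= pid <= len(parent_numbering):
            raise EncodingError(f"parent ID {pid} out of range")
        return parent_numbering[pid - 1]

    for start in range(n):
        if resolved[start] is not None:
            continue
        chain = [start]
        while True:
            i = chain[-1]
            if lines[i] != "" and bundle.parent_ids[i] == 0:
                resolved[i] = lines[i]  # root: raw read
                chain.pop()
                break
            ref = ref_of(i)
            if resolved[ref] is not None:
                break
            chain.append(ref)
            if len(chain) > n:
                raise EncodingError("cyclic parent references in archive")
        for i in reversed(chain):
            if resolved[i] is not None:
                continue
            ref_seq = resolved[ref_of(i)]
            assert ref_seq is not None
            if lines[i] == "":
                resolved[i] = (
                    reverse_complement(ref_seq) if bundle.s3_rc_bits[i] else ref_seq
                )
            else:
                resolved[i] = decode_child(
                    ref_seq,
                    lines[i],
                    bundle.s2_dir_bits[i],
                    bundle.s3_rc_bits[i],
                    read_length,
                )
    return [s for s in resolved if s is not None]


# ---------------------------------------------------------------------------
# paired-end pairing streams (Fenwick tree over visiting ranks)
# ---------------------------------------------------------------------------


class Fenwick:
    """Binary indexed tree over 0/1 presence values."""

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)
        for i in range(1, n + 1):  # O(n) build of an all-ones tree
            self.tree[i] += 1
            j = i + (i & -i)
            if j <= n:
                self.tree[j] += self.tree[i]

    def add(self, i: int, delta: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += delta
            i += i & -i

    def prefix(self, i: int) -> int:
        """Sum of presence over positions 0..i inclusive."""
        i += 1
        total = 0
        while i > 0:
            total += self.tree[i]
            i -= i & -i
        return total

    def select(self, target: int) -> int:
        """Smallest index whose prefix sum reaches ``target`` (1-based count)."""
        if target <= 0 or target > self.prefix(self.n - 1):
            raise EncodingError("Fenwick select target out of range")
        pos = 0
        bit = 1 << (self.n.bit_length())
        remaining = target
        while bit:
            nxt = pos + bit
            if nxt <= self.n and self.tree[nxt] < remaining:
                remaining -= self.tree[nxt]
                pos = nxt
            bit >>= 1
        return pos  # 0-based: tree index pos+1 holds the target element


def pair_distance_stream(
    rank_of: np.ndarray, n1: int
) -> tuple[list[int], list[int], list[int]]:
    """Pairing streams from visiting ranks.

    Scanning ranks ascending, each not-yet-processed read opens its pair:
    the stored distance is the number of still-unprocessed reads strictly
    between the two mates' ranks; the order bit records whether the
    earlier-visited mate came from file 1.  Returns (distances, order bits,
    original pair index per processed pair).
    """
    R = len(rank_of)
    if R != 2 * n1:
        raise EncodingError("paired-end read count must be 2*n1")
    rank2orig = np.empty(R, dtype=np.int64)
    rank2orig[rank_of] = np.arange(R)
    fen = Fenwick(R)
    processed = np.zeros(R, dtype=bool)
    distances: list[int] = []
    order_bits: list[int] = []
    original_pair: list[int] = []
    for r in range(R):
        if processed[r]:
            continue
        orig = int(rank2orig[r])
        mate = orig + n1 if orig < n1 else orig - n1
        mr = int(rank_of[mate])
        distances.append(fen.prefix(mr - 1) - fen.prefix(r))
        order_bits.append(1 if orig < n1 else 0)
        original_pair.append(orig if orig < n1 else mate)
        processed[r] = processed[mr] = True
        fen.add(r, -1)
        fen.add(mr, -1)
    return distances, order_bits, original_pair


def resolve_pairs(
    n_reads: int, distances: list[int], order_bits: list[int]
) -> list[tuple[int, int]]:
    """Inverse of :func:`pair_distance_stream`.

    Returns, per processed pair in order, ``(rank in file 1, rank in file
    2)``.
    """
    if n_reads % 2:
        raise EncodingError("odd number of reads cannot be paired")
    fen = Fenwick(n_reads)
    processed = [False] * n_reads
    pairs: list[tuple[int, int]] = []
    it = iter(zip(distances, order_bits))
    for r in range(n_reads):
        if processed[r]:
            continue
        try:
            d, bit = next(it)
        except StopIteration as exc:
            raise EncodingError("pair distance stream truncated") from exc
        processed[r] = True
        fen.add(r, -1)
        target = fen.prefix(r) + d + 1
        mate = fen.select(target)
        processed[mate] = True
        fen.add(mate, -1)
        pairs.append((r, mate) if bit else (mate, r))
    return pairs
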