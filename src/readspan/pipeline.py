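"""End-to-end compression and decompression.

``compress_reads`` runs the whole pipeline -- duplicate collapsing,
multi-round minimizer indexing, candidate-edge search, Kruskal forest,
stream encoding, backend compression -- and returns archive bytes plus run
statistics.  ``decompress_bytes`` inverts it.  Losslessness is on the
sequence lines: exact order in order-preserving mode, read multiset
(single-end) or pair multiset (paired-end) in order-free mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import archive as _archive
from . import codec as _codec
from .archive import ArchiveError
from .codec import StreamBundle
from .dedup import find_duplicates, reverse_complement
from .fastq_io import ReadSet
from .graph import GraphConfig, collect_rounds
from .indexer import RoundConfig
from .msf import kruskal_msf

__all__ = ["CompressionStats", "compress_reads", "decompress_bytes"]


@dataclass
class CompressionStats:
    n_reads: int
    total_bases: int
    n_distinct: int
    n_candidate_edges: int
    n_trees: int
    total_weight: int
    archive_bytes: int

    @property
    def bpb(self) -> float:
        """Bits per base over the whole archive (header included)."""
        if self.total_bases == 0:
            return 0.0
        return 8.0 * self.archive_bytes / self.total_bases


def compress_reads(
    reads: ReadSet,
    *,
    order_preserving: bool = False,
    rounds: RoundConfig | None = None,
    graph_cfg: GraphConfig | None = None,
    check: bool = True,
) -> tuple[bytes, CompressionStats]:
    """Compress a ReadSet into archive bytes.

    ``check`` verifies every emitted reference code by decoding it back
    (cheap insurance against encoder bugs; disable for speed).
    """
    rounds = rounds or RoundConfig()
    graph_cfg = graph_cfg or GraphConfig()
    mode = ("op" if order_preserving else "of") + ("-pe" if reads.paired else "-se")

    ded = find_duplicates(reads)
    n_distinct = ded.n_distinct
    edges = (
        collect_rounds(ded.distinct, rounds, graph_cfg) if n_distinct > 1 else []
    )
    forest = kruskal_msf(n_distinct, edges)

    if mode == "op-se":
        bundle = _codec.order_preserving_encode(forest, ded.distinct, ded, check=check)
    else:
        bundle, rank_of = _codec.dfs_encode(forest, ded.distinct, ded, check=check)
        if reads.paired:
            dist, order_bits, orig_pair = _codec.pair_distance_stream(
                rank_of, reads.n1
            )
            bundle.pair_distances = dist
            bundle.pair_order_bits = order_bits
            if order_preserving:
                bundle.pair_original_order = orig_pair

    meta = {
        "mode": mode,
        "read_length": reads.read_length,
        "read_length2": reads.read_length2,
        "n_reads": reads.origin_count,
        "n1": reads.n1,
    }
    blob = _archive.build_archive(bundle, meta)
    stats = CompressionStats(
        n_reads=reads.origin_count,
        total_bases=reads.total_bases,
        n_distinct=n_distinct,
        n_candidate_edges=len(edges),
        n_trees=len(forest.roots),
        total_weight=forest.total_weight,
        archive_bytes=len(blob),
    )
    return blob, stats


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _decode_nodes(
    bundle: StreamBundle, length_of_node
) -> tuple[list[str], list[tuple[int, int]]]:
    """Decode stream-1 node sequences in emission order.

    ``length_of_node(i)`` supplies the read length of emitted node ``i``.
    Also returns per-node (normal, rc) duplicate counts from streams 4/5.
    """
    nodes = _codec.decode_order_free_structure(bundle.s1_lines)
    if len(bundle.s4_dup_bits) != len(nodes):
        raise ArchiveError("stream 4 bit count does not match node count")
    seqs: list[str] = []
    nonroot = 0
    dup_iter = iter(bundle.s5_dup_counts)
    dup_counts: list[tuple[int, int]] = []
    for i, (text, parent) in enumerate(nodes):
        if parent < 0:
            seqs.append(text)
        else:
            try:
                seqs.append(
                    _codec.decode_child(
                        seqs[parent],
                        text,
                        bundle.s2_dir_bits[nonroot],
                        bundle.s3_rc_bits[nonroot],
                        length_of_node(i),
                    )
                )
            except IndexError as exc:
                raise ArchiveError("direction/strand bit streams truncated") from exc
            nonroot += 1
        if bundle.s4_dup_bits[i]:
            try:
                dup_counts.append(next(dup_iter))
            except StopIteration as exc:
                raise ArchiveError("stream 5 truncated") from exc
        else:
            dup_counts.append((0, 0))
    return seqs, dup_counts


def _materialize_ranks(
    seqs: list[str], dup_counts: list[tuple[int, int]]
) -> list[str]:
    """Expand node sequences into the full visiting-rank read list:
    representative, then normal copies, then reverse-complement copies."""
    out: list[str] = []
    for seq, (n_norm, n_rc) in zip(seqs, dup_counts):
        out.append(seq)
        out.extend([seq] * n_norm)
        if n_rc:
            rc = reverse_complement(seq)
            out.extend([rc] * n_rc)
    return out


def _node_of_rank(dup_counts: list[tuple[int, int]]) -> list[int]:
    owner: list[int] = []
    for i, (n_norm, n_rc) in enumerate(dup_counts):
        owner.extend([i] * (1 + n_norm + n_rc))
    return owner


def decompress_bytes(data: bytes) -> ReadSet:
    """Decode archive bytes back into a ReadSet.

    Raises :class:`ArchiveError` on any structural corruption.
    """
    meta, bundle = _archive.parse_archive(data)
    mode = meta.get("mode")
    L1 = meta.get("read_length", 0)
    L2 = meta.get("read_length2")
    n_reads = meta.get("n_reads", 0)

    if mode == "op-se":
        seqs = _codec.decode_order_preserving(bundle, L1)
        if len(seqs) != n_reads:
            raise ArchiveError("decoded read count does not match header")
        return ReadSet(sequences=seqs, read_length=L1, n1=len(seqs))

    if mode == "of-se":
        seqs, dup_counts = _decode_nodes(bundle, lambda i: L1)
        out = _materialize_ranks(seqs, dup_counts)
        if len(out) != n_reads:
            raise ArchiveError("decoded read count does not match header")
        return ReadSet(sequences=out, read_length=L1, n1=len(out))

    if mode in ("of-pe", "op-pe"):
        # Pass 1: tree structure only (line classification needs no bases),
        # so pairing -- hence each node's file of origin and read length --
        # is known before any sequence is decoded.
        structure = _codec.decode_order_free_structure(bundle.s1_lines)
        if len(bundle.s4_dup_bits) != len(structure):
            raise ArchiveError("stream 4 bit count does not match node count")
        dup_counts: list[tuple[int, int]] = []
        dup_iter = iter(bundle.s5_dup_counts)
        for bit in bundle.s4_dup_bits:
            if bit:
                try:
                    dup_counts.append(next(dup_iter))
                except StopIteration as exc:
                    raise ArchiveError("stream 5 truncated") from exc
            else:
                dup_counts.append((0, 0))
        owner = _node_of_rank(dup_counts)
        R = len(owner)
        if R != n_reads:
            raise ArchiveError("rank count does not match header read count")
        pairs = _codec.resolve_pairs(
            R, bundle.pair_distances, bundle.pair_order_bits
        )
        node_file2 = [False] * len(structure)
        for r1, r2 in pairs:
            node_file2[owner[r2]] = True
            node_file2[owner[r1]] = False
        # All copies of a node share one sequence, hence one length/file.
        seqs, dup_counts2 = _decode_nodes(
            bundle,
            lambda i: (L2 if node_file2[i] and L2 is not None else L1),
        )
        contents = _materialize_ranks(seqs, dup_counts2)
        out1 = [contents[r1] for r1, _ in pairs]
        out2 = [contents[r2] for _, r2 in pairs]
        if mode == "op-pe":
            order = bundle.pair_original_order
            if sorted(order) != list(range(len(pairs))):
                raise ArchiveError("pair original-order stream is not a permutation")
            restored1 = [""] * len(pairs)
            restored2 = [""] * len(pairs)
            for j, orig in enumerate(order):
                restored1[orig] = out1[j]
                restored2[orig] = out2[j]
            out1, out2 = restored1, restored2
        return ReadSet(
            sequences=out1 + out2,
            read_length=L1,
            read_length2=L2 if L2 is not None else L1,
            n1=len(pairs),
        )

    raise ArchiveError(f"unknown archive mode {mode!r}")
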