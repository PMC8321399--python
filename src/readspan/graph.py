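"""Candidate-edge construction for the Hamming-shifting read graph.

An edge links two distinct reads that align with a small shifting offset
``ob`` and few overlap mismatches ``mb``; its weight is ``3*mb + ob``, the
cost proxy of the reference code one read needs given the other.  Within an
indexing block, the shared minimizer is the alignment anchor: the offset is
the difference of the hit positions after strand normalization, and the
overlap is then compared base by base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kmers
from .fastq_io import ReadSet
from .indexer import Block, RoundConfig, build_blocks

__all__ = [
    "Edge",
    "GraphConfig",
    "align_by_anchor",
    "mismatching_distance",
    "edge_weight",
    "find_candidate_edges",
    "collect_rounds",
]

_BASES = "ACGTN"


def edge_weight(mb: int, ob: int) -> int:
    """Edge weight w = 3*mb + ob (mb mismatch bases, ob shifting offset)."""
    if mb < 0 or ob < 0:
        raise ValueError("mb and ob must be non-negative")
    if mb == 0 and ob == 0:
        raise ValueError("identical reads form no edge (deduplicate first)")
    return 3 * mb + ob


@dataclass(frozen=True)
class Edge:
    """Alignment between distinct reads u < v.

    The layout lives in u's forward frame: ``vv`` (v, or its reverse
    complement when ``strand`` is set) starts ``delta`` bases after u.
    Mismatches are (position in u coordinates, u base, vv base), restricted
    to the overlap window.
    """

    u: int
    v: int
    delta: int
    strand: bool
    mismatches: tuple[tuple[int, str, str], ...]

    @property
    def offset(self) -> int:
        return abs(self.delta)

    @property
    def mb(self) -> int:
        return len(self.mismatches)

    @property
    def weight(self) -> int:
        return 3 * self.mb + self.offset

    @property
    def distance(self) -> int:
        """Mismatching distance: overlap mismatches plus (non-zero) offset."""
        return self.mb + self.offset

    @property
    def direction(self) -> str:
        if self.delta == 0:
            return "none"
        return "u_ahead" if self.delta > 0 else "v_ahead"

    def child_layout(self, child: int, L_u: int, L_v: int) -> tuple[int, bool]:
        """Shift of the child relative to its parent, and whether the child
        is encoded on its reverse-complement strand.

        Returns ``(delta_cp, rc)`` where ``delta_cp`` is (child start -
        parent start) in the parent's forward frame, the child taken as its
        RC when ``rc`` is True.
        """
        if child == self.v:
            return self.delta, self.strand
        if child != self.u:
            raise ValueError(f"read {child} is not an endpoint of this edge")
        if not self.strand:
            return -self.delta, False
        # mirror the whole layout so the parent (v) reads forward
        return self.delta + L_v - L_u, True


@dataclass
class GraphConfig:
    """Edge-search knobs.

    ``max_weight`` caps accepted edge weights (None resolves to the read
    length: an edge label costing about a whole read is useless for
    compression).  ``search_limit`` bounds how many preceding block members
    each read is compared against (None = unlimited).
    """

    max_weight: int | None = None
    search_limit: int | None = 32

    def resolved_max_weight(self, read_length: int) -> int:
        w = self.max_weight if self.max_weight is not None else read_length
        if w <= 0:
            raise ValueError("max_weight must be positive")
        return w


class _SeqCache:
    """Per-read uint8 code arrays (forward and reverse complement)."""

    def __init__(self, seqs: list[str]):
        self.fwd = [_kmers.encode_seq(s) for s in seqs]
        self.rc = [_kmers.rc_array(a) for a in self.fwd]


def align_by_anchor(
    L_u: int,
    L_v: int,
    hit_u: tuple[int, bool],
    hit_v: tuple[int, bool],
) -> tuple[int, bool]:
    """Layout implied by a shared anchor k-mer.

    ``hit_*`` are (position, is_rc) of the shared minimizer in each read
    (positions in the coordinates of the hit strand).  Returns ``(delta,
    strand)`` in u's forward frame: vv = rc(v) if strand else v, starting
    ``delta`` bases after u.
    """
    pu, su = hit_u
    pv, sv = hit_v
    d0 = pu - pv  # layout in the frame of u's hit strand
    strand = su != sv
    delta = d0 if not su else L_u - d0 - L_v
    return delta, strand


def mismatching_distance(
    ru: str, rv: str, offset: int, direction: str = "u_ahead", strand: bool = False
) -> tuple[int, int]:
    """(mb, mismatching distance) of two reads under a given layout.

    ``direction`` says which read starts earlier ("u_ahead": u first).
    With offset 0 this is the plain Hamming distance over the overlap.
    """
    if offset >= min(len(ru), len(rv)):
        raise ValueError("offset leaves no overlap")
    delta = offset if direction in ("u_ahead", "none") else -offset
    au = _kmers.encode_seq(ru)
    av = _kmers.rc_array(_kmers.encode_seq(rv)) if strand else _kmers.encode_seq(rv)
    lo, hi = max(0, delta), min(len(ru), delta + len(rv))
    if hi <= lo:
        raise ValueError("layout has no overlap")
    mb = int((au[lo:hi] != av[lo - delta : hi - delta]).sum())
    return mb, mb + offset


def _encodable(L_child: int, L_parent: int, delta_cp: int) -> bool:
    """Whether a child can be coded from a parent as one shifting substring
    plus overlap mismatches under this layout."""
    if delta_cp >= 0:
        return delta_cp <= L_child and L_child <= L_parent
    ob = -delta_cp
    return ob <= L_child and L_child - ob <= L_parent


class _EdgeAccumulator:
    """Best edge per unordered read pair, deduplicated across rounds."""

    def __init__(self, cache: _SeqCache, max_weight: int):
        self.cache = cache
        self.max_weight = max_weight
        self.best: dict[tuple[int, int], Edge] = {}
        self.seen_layouts: set[tuple[int, int, int, bool]] = set()

    def consider(
        self,
        i: int,
        j: int,
        hit_i: tuple[int, bool],
        hit_j: tuple[int, bool],
    ) -> None:
        if i == j:
            return
        if i < j:
            u, v, hu, hv = i, j, hit_i, hit_j
        else:
            u, v, hu, hv = j, i, hit_j, hit_i
        au = self.cache.fwd[u]
        L_u, L_v = len(au), len(self.cache.fwd[v])
        delta, strand = align_by_anchor(L_u, L_v, hu, hv)
        layout = (u, v, delta, strand)
        if layout in self.seen_layouts:
            return
        self.seen_layouts.add(layout)

        offset = abs(delta)
        if offset > self.max_weight:
            return
        lo, hi = max(0, delta), min(L_u, delta + L_v)
        if hi - lo < 1:
            return
        if L_u != L_v and offset == 0:
            # mixed-length pairs must shift (offset is what makes the code
            # length-recoverable)
            return
        if not (
            _encodable(L_v, L_u, delta)
            and _encodable(L_u, L_v, delta + L_v - L_u if strand else -delta)
        ):
            return
        av = self.cache.rc[v] if strand else self.cache.fwd[v]
        wu = au[lo:hi]
        wv = av[lo - delta : hi - delta]
        diff = np.nonzero(wu != wv)[0]
        mb = len(diff)
        weight = 3 * mb + offset
        if weight == 0 or weight > self.max_weight:
            return
        pair = (u, v)
        prev = self.best.get(pair)
        if prev is not None and prev.weight <= weight:
            return
        mismatches = tuple(
            (lo + int(p), _BASES[wu[p]], _BASES[wv[p]]) for p in diff
        )
        self.best[pair] = Edge(u=u, v=v, delta=delta, strand=strand, mismatches=mismatches)

    def scan_blocks(self, blocks: list[Block], search_limit: int | None) -> None:
        for block in blocks:
            members = block.members
            n = len(members)
            if n < 2:
                continue
            for j in range(1, n):
                rj, pj, sj = members[j]
                start = 0 if search_limit is None else max(0, j - search_limit)
                for i in range(start, j):
                    ri, pi, si = members[i]
                    self.consider(ri, rj, (pi, si), (pj, sj))

    def sorted_edges(self) -> list[Edge]:
        # weight bins, stable within a bin by first-discovery order
        bins: dict[int, list[Edge]] = {}
        for edge in self.best.values():
            bins.setdefault(edge.weight, []).append(edge)
        out: list[Edge] = []
        for w in sorted(bins):
            out.extend(bins[w])
        return out


def find_candidate_edges(
    blocks: list[Block],
    distinct: ReadSet | list[str],
    cfg: GraphConfig | None = None,
) -> list[Edge]:
    """Candidate edges from one round's blocks (weight-sorted).

    Each block member is compared against up to ``cfg.search_limit``
    preceding members (block order: minimizer position ascending); edges
    heavier than ``cfg.max_weight`` are dropped; layouts are deduplicated
    keeping the lightest edge per read pair.
    """
    seqs = distinct.sequences if isinstance(distinct, ReadSet) else distinct
    cfg = cfg or GraphConfig()
    max_len = max((len(s) for s in seqs), default=0)
    acc = _EdgeAccumulator(_SeqCache(seqs), cfg.resolved_max_weight(max_len))
    acc.scan_blocks(blocks, cfg.search_limit)
    return acc.sorted_edges()


def collect_rounds(
    distinct: ReadSet | list[str],
    rounds: RoundConfig | None = None,
    cfg: GraphConfig | None = None,
) -> list[Edge]:
    """Run every indexing round and pool the edges.

    The union over rounds is deduplicated per unordered read pair (keeping
    the lightest edge), binned by weight, and returned in nondecreasing
    weight order -- the stream Kruskal consumes.
    """
    seqs = distinct.sequences if isinstance(distinct, ReadSet) else distinct
    rounds = rounds or RoundConfig()
    cfg = cfg or GraphConfig()
    max_len = max((len(s) for s in seqs), default=0)
    acc = _EdgeAccumulator(_SeqCache(seqs), cfg.resolved_max_weight(max_len))
    for k, mode in rounds.rounds():
        blocks = build_blocks(
            seqs,
            k,
            mode,
            ordering=rounds.ordering,
            hash_seed=rounds.hash_seed,
            both_strands=True,
        )
        acc.scan_blocks(blocks, cfg.search_limit)
    return acc.sorted_edges()
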