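"""Multi-round minimizer/maximizer indexing of distinct reads.

Two reads sharing a k-minimizer share an exact substring of length >= k, so
grouping reads by minimizer ("blocks") restricts edge search to promising
pairs.  A single k is fragile -- one mismatch can break every shared window
of a large k -- so indexing runs over a decreasing panel k1 > k2 > ... > kn
(default 29 down to 10), and optionally repeats the whole panel with
k-maximizers, each round contributing candidate pairs independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kmers
from .fastq_io import ReadSet

__all__ = [
    "MinimizerHit",
    "Block",
    "RoundConfig",
    "k_minimizer",
    "k_maximizer",
    "build_blocks",
]


@dataclass(frozen=True)
class MinimizerHit:
    """A selected k-mer occurrence: its string, start, and source strand.

    ``position`` is 0-based in the coordinates of the strand that yielded
    the hit (for ``strand == "rc"``, in the reverse-complemented read).
    """

    kmer: str
    position: int
    strand: str  # "forward" | "rc"


@dataclass
class Block:
    """Reads sharing one minimizer/maximizer key in one indexing round.

    ``members`` are (distinct-read index, position, is_rc) triples sorted by
    hit position ascending.
    """

    key_code: int
    k: int
    members: list[tuple[int, int, bool]]

    @property
    def key(self) -> str:
        return _kmers.kmer_to_string(self.key_code, self.k)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RoundConfig:
    """Indexing-round panel.

    ``k_values`` must be strictly decreasing, each >= 4 and at most 31 (a
    31-mer code fits machine integers and matches the dedup k-mer cap).
    When ``use_maximizers`` is set the same panel is repeated with
    k-maximizers, doubling the number of rounds; disabling it is the speedy
    mode, which trades a little recall for half the indexing work.
    """

    k_values: tuple[int, ...] = tuple(range(29, 9, -1))
    use_maximizers: bool = True
    ordering: str = "lexicographic"  # or "hashed"
    hash_seed: int = 17

    def __post_init__(self) -> None:
        ks = tuple(self.k_values)
        if not ks:
            raise ValueError("k_values must be non-empty")
        if any(k < 4 for k in ks):
            raise ValueError("all k values must be >= 4")
        if ks[0] > 31:
            raise ValueError("k1 must be <= 31")
        if any(b >= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k values must be strictly decreasing")
        object.__setattr__(self, "k_values", ks)
        if self.ordering not in ("lexicographic", "hashed"):
            raise ValueError(f"unknown ordering {self.ordering!r}")

    @classmethod
    def default(
        cls,
        n_rounds: int = 20,
        k1: int = 29,
        speedy: bool = False,
        ordering: str = "lexicographic",
        hash_seed: int = 17,
    ) -> "RoundConfig":
        """Panel k1, k1-1, ..., length ``n_rounds`` (floored at k=4)."""
        ks = tuple(k for k in range(k1, k1 - n_rounds, -1) if k >= 4)
        return cls(
            k_values=ks,
            use_maximizers=not speedy,
            ordering=ordering,
            hash_seed=hash_seed,
        )

    def rounds(self) -> list[tuple[int, str]]:
        """(k, mode) pairs in execution order: all minimizer rounds, then
        maximizer rounds unless disabled."""
        out = [(k, "minimizer") for k in self.k_values]
        if self.use_maximizers:
            out += [(k, "maximizer") for k in self.k_values]
        return out


def _extreme_single(
    seq: str,
    k: int,
    *,
    maximizer: bool,
    ordering: str,
    both_strands: bool,
    hash_seed: int,
) -> MinimizerHit | None:
    if len(seq) < k:
        return None
    mat = _kmers.encode_seq(seq)[None, :]
    codes, pos, strand, valid = _kmers.extreme_kmers(
        mat,
        k,
        maximizer=maximizer,
        both_strands=both_strands,
        ordering=ordering,
        hash_seed=hash_seed,
    )
    if not valid[0]:
        return None
    return MinimizerHit(
        kmer=_kmers.kmer_to_string(int(codes[0]), k),
        position=int(pos[0]),
        strand="rc" if strand[0] else "forward",
    )


def k_minimizer(
    seq: str,
    k: int,
    ordering: str = "lexicographic",
    both_strands: bool = False,
    hash_seed: int = 17,
) -> MinimizerHit | None:
    """Ordering-smallest eligible k-mer of a read (leftmost on ties,
    forward strand preferred).  Returns None when every window contains N
    or the read is shorter than k."""
    return _extreme_single(
        seq,
        k,
        maximizer=False,
        ordering=ordering,
        both_strands=both_strands,
        hash_seed=hash_seed,
    )


def k_maximizer(
    seq: str,
    k: int,
    ordering: str = "lexicographic",
    both_strands: bool = False,
    hash_seed: int = 17,
) -> MinimizerHit | None:
    """Ordering-largest eligible k-mer of a read (leftmost on ties)."""
    return _extreme_single(
        seq,
        k,
        maximizer=True,
        ordering=ordering,
        both_strands=both_strands,
        hash_seed=hash_seed,
    )


def build_blocks(
    distinct: ReadSet | list[str],
    k: int,
    mode: str = "minimizer",
    *,
    ordering: str = "lexicographic",
    hash_seed: int = 17,
    both_strands: bool = True,
) -> list[Block]:
    """Partition distinct reads into minimizer (or maximizer) blocks.

    Mixed-length read sets (different paired-end lengths) are supported:
    each length group is scanned separately and blocks are merged on the
    k-mer key.  Reads with no eligible window are omitted from every block.
    Block members are sorted by hit position ascending (read index breaking
    ties), the order in which the edge search walks them.
    """
    seqs = distinct.sequences if isinstance(distinct, ReadSet) else distinct
    if mode not in ("minimizer", "maximizer"):
        raise ValueError(f"unknown mode {mode!r}")
    maximizer = mode == "maximizer"

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)

    grouped: dict[int, list[tuple[int, int, bool]]] = {}
    for L, idxs in sorted(by_len.items()):
        if L < k:
            continue
        mat = _kmers.encode_matrix([seqs[i] for i in idxs])
        codes, pos, strand, valid = _kmers.extreme_kmers(
            mat,
            k,
            maximizer=maximizer,
            both_strands=both_strands,
            ordering=ordering,
            hash_seed=hash_seed,
        )
        for j, i in enumerate(idxs):
            if valid[j]:
                grouped.setdefault(int(codes[j]), []).append(
                    (i, int(pos[j]), bool(strand[j]))
                )

    blocks = []
    for code in sorted(grouped):
        members = sorted(grouped[code], key=lambda t: (t[1], t[0]))
        blocks.append(Block(key_code=code, k=k, members=members))
    return blocks
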