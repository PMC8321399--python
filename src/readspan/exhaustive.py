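"""Exact all-pairs edge search (the baseline the heuristic approximates).

Exhaustively scans every read pair, every shifting offset and both strands
for the weight-lightest alignment under the same edge model as the graph
stage (weight 3*mb + ob, capped).  Quadratic in the number of reads, so
only usable on small inputs -- which is exactly its role: the reference
against which the minimizer heuristic's recall is measured, and the source
of the per-pair (s, t) values the detection-probability model needs.

Pruning is exact: a layout with offset ob has weight >= ob, so offsets at
or beyond the current per-read best weights cannot change any minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kmers
from .theory import p_multi

__all__ = ["BestPair", "best_partners", "pair_t_values", "proposition_bound"]


@dataclass
class BestPair:
    """Weight-lightest alignment found for one read against all others."""

    read: int
    partner: int
    weight: int
    delta: int  # partner start relative to this read (forward frame)
    strand: bool
    mb: int


def _pair_best(
    a: np.ndarray,
    b_fwd: np.ndarray,
    b_rc: np.ndarray,
    h0: tuple[int, int],
    cap: int,
) -> tuple[int, int, bool, int] | None:
    """Exact lightest layout of one pair: (weight, delta, strand, mb).

    ``h0`` carries the precomputed offset-0 Hamming distances (fwd, rc).
    Only layouts with weight <= cap are considered.
    """
    L = len(a)
    best: tuple[int, int, bool, int] | None = None
    for strand, h in zip((False, True), h0):
        if h > 0 and 3 * h <= cap:
            if best is None or 3 * h < best[0]:
                best = (3 * h, 0, strand, h)
    for ob in range(1, min(cap, L - 1) + 1):
        if best is not None and ob >= best[0]:
            break
        for strand, b in ((False, b_fwd), (True, b_rc)):
            for delta in (ob, -ob):
                lo, hi = max(0, delta), min(L, delta + L)
                mb = int((a[lo:hi] != b[lo - delta : hi - delta]).sum())
                w = 3 * mb + ob
                if w <= cap and (best is None or w < best[0]):
                    best = (w, delta, strand, mb)
    return best


def best_partners(seqs: list[str], max_weight: int | None = None) -> list[BestPair]:
    """Per-read weight-lightest partner over all pairs (equal-length reads).

    ``max_weight`` defaults to the read length.  Reads whose lightest
    alignment exceeds the cap are omitted from the result.
    """
    m = len(seqs)
    if m < 2:
        return []
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("exhaustive search expects equal-length reads")
    cap = max_weight if max_weight is not None else L

    mat = _kmers.encode_matrix(seqs)
    rc = np.stack([_kmers.rc_array(row) for row in mat])

    # offset-0 Hamming distances for every pair, both strands, vectorized
    ham_f = np.zeros((m, m), dtype=np.int64)
    ham_r = np.zeros((m, m), dtype=np.int64)
    step = max(1, 2_000_000 // (m * L))
    for i0 in range(0, m, step):
        i1 = min(m, i0 + step)
        ham_f[i0:i1] = (mat[i0:i1, None, :] != mat[None, :, :]).sum(axis=2)
        ham_r[i0:i1] = (mat[i0:i1, None, :] != rc[None, :, :]).sum(axis=2)

    best_w = np.full(m, cap + 1, dtype=np.int64)
    best_rec: list[BestPair | None] = [None] * m

    def record(i: int, j: int, w: int, delta: int, strand: bool, mb: int) -> None:
        if w < best_w[i]:
            best_w[i] = w
            best_rec[i] = BestPair(i, j, w, delta, strand, mb)

    # visit promising pairs first so the per-read bounds tighten early
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    zero_w = np.minimum(ham_f, ham_r) * 3
    pairs.sort(key=lambda p: min(zero_w[p], cap + 1))

    for i, j in pairs:
        bound = min(int(max(best_w[i], best_w[j])), cap + 1)
        if bound <= 1:
            continue
        found = _pair_best(
            mat[i], mat[j], rc[j], (int(ham_f[i, j]), int(ham_r[i, j])), bound - 1
        )
        if found is None:
            continue
        w, delta, strand, mb = found
        record(i, j, w, delta, strand, mb)
        # mirrored layout for the partner: same offset/strand, delta negated
        # on the same strand frame (weight is symmetric)
        record(j, i, w, -delta if not strand else delta, strand, mb)

    return [rec for rec in best_rec if rec is not None]


def pair_t_values(
    seqs: list[str], pair: BestPair, ks: list[int]
) -> dict[int, int]:
    """Number of differing k-mer windows in the pair's overlap, per k."""
    a = _kmers.encode_seq(seqs[pair.read])
    b = _kmers.encode_seq(seqs[pair.partner])
    if pair.strand:
        b = _kmers.rc_array(b)
    delta = pair.delta
    L = len(a)
    lo, hi = max(0, delta), min(L, delta + len(b))
    diff = a[lo:hi] != b[lo - delta : hi - delta]
    out: dict[int, int] = {}
    olen = hi - lo
    for k in ks:
        if olen < k:
            out[k] = 0
            continue
        windows = np.lib.stride_tricks.sliding_window_view(diff, k)
        out[k] = int(windows.any(axis=1).sum())
    return out


def proposition_bound(L: int, ks: list[int], s: int, t_by_k: dict[int, int]) -> float:
    """Multi-round detection bound 1 - prod(1 - p(k_i)) for one pair,
    with p(k) = ((L-k+1-(s+t_k))/(L-k+1))^2 clamped to 0."""
    ps = []
    for k in ks:
        W = L - k + 1
        shared = W - (s + t_by_k.get(k, 0))
        ps.append((shared / W) ** 2 if shared > 0 else 0.0)
    return p_multi(ps)
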