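"""Vectorized k-mer machinery shared by the dedup and indexing stages.

Reads are held as uint8 code arrays (A=0, C=1, G=2, T=3, N=4).  A k-mer is
represented by its base-4 integer code, so that numeric order on codes of a
fixed k equals lexicographic order on the k-mer strings.  Windows containing
an N are ineligible.  An optional invertible multiply-xorshift hash reorders
the k-mers to approximate a uniform random ordering.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complements: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_U64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)


def encode_seq(seq: str) -> np.ndarray:
    """Encode one read as a uint8 code array."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 4:
        raise ValueError(f"sequence contains non-ACGTN characters: {seq!r}")
    return arr


def decode_seq(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


def rc_array(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array."""
    return _COMP[arr[::-1]]


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Stack equal-length reads into an (m, L) code matrix."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    joined = "".join(seqs).encode()
    mat = _ENCODE[np.frombuffer(joined, dtype=np.uint8)]
    return mat.reshape(len(seqs), len(seqs[0]))


def kmer_to_string(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(bases))


def _window_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes per read.

    Returns ``(codes, valid)`` of shape (m, L-k+1): base-4 integer codes and
    an eligibility mask (False where the window contains an N).
    """
    windows = sliding_window_view(mat, k, axis=1)  # (m, W, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = windows.astype(np.int64) @ powers
    valid = ~(windows == 4).any(axis=2)
    return codes, valid


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Invertible finalizer (splitmix64 style) for hashed k-mer ordering."""
    z = x.astype(np.uint64) ^ np.uint64(seed * 0x9E3779B97F4A7C15 & 0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _order_values(codes: np.ndarray, ordering: str, hash_seed: int) -> np.ndarray:
    if ordering == "lexicographic":
        return codes.astype(np.uint64)
    if ordering == "hashed":
        return _mix64(codes, hash_seed)
    raise ValueError(f"unknown k-mer ordering: {ordering!r}")


def extreme_kmers(
    mat: np.ndarray,
    k: int,
    *,
    maximizer: bool = False,
    both_strands: bool = True,
    ordering: str = "lexicographic",
    hash_seed: int = 17,
):
    """Per-read k-minimizer (or k-maximizer) over one or both strands.

    Parameters
    ----------
    mat:
        (m, L) uint8 code matrix of equal-length reads.
    maximizer:
        Select the ordering-largest k-mer instead of the smallest.

    Returns
    -------
    codes : int64 array (m,) -- k-mer code of the selected window (base-4).
    positions : int64 array (m,) -- 0-based window start, in the coordinates
        of the strand on which it was selected.
    strands : bool array (m,) -- True where the reverse-complement strand won.
    valid : bool array (m,) -- False where no window was eligible.

    Ties are broken toward the leftmost position; on a cross-strand tie the
    forward strand is preferred.
    """
    m, L = mat.shape
    if L < k or m == 0:
        z = np.zeros(m, dtype=np.int64)
        return z, z.copy(), np.zeros(m, dtype=bool), np.zeros(m, dtype=bool)

    worst = np.uint64(0) if maximizer else _U64_MAX

    def strand_extreme(strand_mat):
        codes, ok = _window_codes(strand_mat, k)
        vals = _order_values(codes, ordering, hash_seed)
        vals = np.where(ok, vals, worst)
        pos = vals.argmax(axis=1) if maximizer else vals.argmin(axis=1)
        rows = np.arange(m)
        return codes[rows, pos], vals[rows, pos], pos, ok.any(axis=1)

    code_f, val_f, pos_f, ok_f = strand_extreme(mat)
    if not both_strands:
        return code_f, pos_f.astype(np.int64), np.zeros(m, dtype=bool), ok_f

    rc_mat = _COMP[mat][:, ::-1]
    code_r, val_r, pos_r, ok_r = strand_extreme(rc_mat)

    if maximizer:
        use_rc = ok_r & (~ok_f | (val_r > val_f))
    else:
        use_rc = ok_r & (~ok_f | (val_r < val_f))
    codes = np.where(use_rc, code_r, code_f)
    positions = np.where(use_rc, pos_r, pos_f).astype(np.int64)
    return codes, positions, use_rc, ok_f | ok_r
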