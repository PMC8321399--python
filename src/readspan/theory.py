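"""Analytic model of minimizer co-blocking probability.

Two overlapping reads are only compared if some indexing round puts them in
one block, i.e. they pick the same k-minimizer.  Under the uniformity
hypothesis -- every k-mer of an L-long read is equally likely (1/(L-k+1))
to be its minimizer -- the chance that both reads select one of their
shared k-mers is the squared fraction of shared windows:

    p(k) = ((L - k + 1 - (s + t)) / (L - k + 1))^2

where ``s`` is the shifting-base count of the pair's best alignment and
``t`` the number of differing k-mers in the overlap.  Over n independent
rounds the pair is detected with probability 1 - prod(1 - p(k_i)), which is
at least 1 - (1 - p_min)^n.  A Monte-Carlo simulator checks the model's
consequence empirically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kmers

__all__ = [
    "TheoryParams",
    "p_single",
    "p_multi",
    "p_multi_lower_bound",
    "monte_carlo_coblocking",
]


@dataclass(frozen=True)
class TheoryParams:
    """Inputs to the co-blocking probability formulas.

    L: read length (bases); k: k-mer size; s: shifting bases of the best
    alignment; t: differing k-mers in the overlap substring; n: number of
    indexing rounds.
    """

    L: int
    k: int
    s: int = 0
    t: int = 0
    n: int = 1

    def __post_init__(self) -> None:
        if self.k > self.L:
            raise ValueError("k must not exceed the read length")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.s < 0 or self.t < 0:
            raise ValueError("s and t must be non-negative")
        if self.s + self.t > self.L - self.k + 1:
            raise ValueError("s + t cannot exceed the number of k-mers per read")


def p_single(params: TheoryParams) -> float:
    """Probability that two reads share the same k-minimizer (one round)."""
    windows = params.L - params.k + 1
    shared = windows - (params.s + params.t)
    return (shared / windows) ** 2


def p_multi(p_values: Sequence[float]) -> float:
    """Probability of co-blocking in at least one of the rounds:
    1 - prod(1 - p_i)."""
    if len(p_values) == 0:
        raise ValueError("need at least one per-round probability")
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValueError("probabilities must lie in [0, 1]")
    log_miss = sum(math.log1p(-p) if p < 1.0 else -math.inf for p in p_values)
    return 1.0 - math.exp(log_miss)


def p_multi_lower_bound(p_min: float, n: int) -> float:
    """Lower bound 1 - (1 - p_min)^n using the weakest round only."""
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    return 1.0 - (1.0 - p_min) ** n


def monte_carlo_coblocking(
    L: int,
    k: int,
    error_rate: float,
    shift: int,
    n_pairs: int = 10_000,
    seed: int = 0,
    ordering: str = "hashed",
) -> float:
    """Empirical fraction of read pairs sharing a k-minimizer.

    Pairs are drawn from a common random template: the two reads overlap in
    L - ``shift`` bases and each receives independent substitution errors at
    ``error_rate``.  The hashed k-mer ordering approximates the uniformity
    hypothesis; minimizers are taken forward-strand, matching the model.
    """
    if n_pairs <= 0 or L < k or shift < 0 or shift > L:
        raise ValueError("invalid Monte-Carlo parameters")
    rng = np.random.default_rng(seed)
    genome = rng.integers(0, 4, size=(n_pairs, L + shift), dtype=np.int64)
    reads = [genome[:, :L].copy(), genome[:, shift:].copy()]
    codes = []
    for mat in reads:
        errs = rng.random(mat.shape) < error_rate
        bump = rng.integers(1, 4, size=mat.shape)
        mat[errs] = (mat[errs] + bump[errs]) % 4
        code, _pos, _strand, valid = _kmers.extreme_kmers(
            mat.astype(np.uint8),
            k,
            both_strands=False,
            ordering=ordering,
            hash_seed=seed + 1,
        )
        assert valid.all()  # no N in simulated reads
        codes.append(code)
    return float((codes[0] == codes[1]).mean())
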