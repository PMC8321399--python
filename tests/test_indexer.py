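import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readspan.dedup import reverse_complement
from readspan.indexer import RoundConfig, build_blocks, k_maximizer, k_minimizer
from readspan.simulate import SimConfig, simulate_readset

SEQ = st.text(alphabet="ACGT", min_size=6, max_size=40)


def _brute_minimizer(seq, k, both_strands=False, maximizer=False):
    """Independent oracle: enumerate every eligible window on each strand."""
    candidates = []
    strands = [(seq, "forward")]
    if both_strands:
        strands.append((reverse_complement(seq), "rc"))
    for strand_seq, name in strands:
        for p in range(len(strand_seq) - k + 1):
            kmer = strand_seq[p : p + k]
            if "N" not in kmer:
                candidates.append((kmer, name != "forward", p))
    if not candidates:
        return None
    key = (lambda c: (tuple(-ord(x) for x in c[0]), c[1], c[2])) if maximizer else None
    return min(candidates, key=key) if maximizer else min(candidates)


@pytest.mark.parametrize(
    "seq, k, expected",
    [
        ("ACGT", 2, ("AC", 0)),  # smallest of {AC, CG, GT}
        ("TTTT", 2, ("TT", 0)),  # leftmost on ties
        ("ANGT", 2, ("GT", 2)),  # windows with N are ineligible
    ],
)
def test_k_minimizer_examples(seq, k, expected):
    hit = k_minimizer(seq, k)
    assert (hit.kmer, hit.position) == expected
    assert hit.strand == "forward"


@pytest.mark.parametrize(
    "seq, k, expected",
    [("ACGT", 2, ("GT", 2)), ("AAAA", 3, ("AAA", 0))],
)
def test_k_maximizer_examples(seq, k, expected):
    hit = k_maximizer(seq, k)
    assert (hit.kmer, hit.position) == expected


def test_no_eligible_window_returns_none():
    assert k_minimizer("ANANAN", 3) is None
    assert k_minimizer("ACG", 5) is None


@given(SEQ, st.integers(4, 8), st.booleans())
@settings(deadline=None, max_examples=150)
def test_extreme_kmers_match_enumeration_oracle(seq, k, both_strands):
    if len(seq) < k:
        return
    expected = _brute_minimizer(seq, k, both_strands)
    hit = k_minimizer(seq, k, both_strands=both_strands)
    assert (hit.kmer, hit.strand == "rc", hit.position) == expected
    exp_max = _brute_minimizer(seq, k, both_strands, maximizer=True)
    hit_max = k_maximizer(seq, k, both_strands=both_strands)
    assert (hit_max.kmer, hit_max.strand == "rc", hit_max.position) == exp_max


@given(SEQ, st.integers(4, 8))
@settings(deadline=None, max_examples=80)
def test_hashed_ordering_is_deterministic_and_window_valid(seq, k):
    if len(seq) < k:
        return
    a = k_minimizer(seq, k, ordering="hashed", hash_seed=17)
    b = k_minimizer(seq, k, ordering="hashed", hash_seed=17)
    assert a == b
    assert seq[a.position : a.position + k] == a.kmer  # forward-strand hit


def test_blocks_match_brute_force_grouping():
    reads, _ = simulate_readset(
        SimConfig(genome_length=600, coverage=10, read_length=80,
                  substitution_rate=0.01, seed=5)
    )
    seqs = reads.sequences[:50]
    k = 12
    blocks = build_blocks(seqs, k)

    expected = {}
    for i, s in enumerate(seqs):
        hit = k_minimizer(s, k, both_strands=True)
        if hit is not None:
            expected.setdefault(hit.kmer, []).append(i)
    got = {b.key: sorted(m[0] for m in b.members) for b in blocks}
    assert got == {key: sorted(v) for key, v in expected.items()}

    # each read appears in at most one block per round
    seen = [m[0] for b in blocks for m in b.members]
    assert len(seen) == len(set(seen))

    # members are sorted by hit position, and co-blocked reads share an
    # exact substring of length >= k (on either strand)
    for b in blocks:
        positions = [p for _, p, _ in b.members]
        assert positions == sorted(positions)
        for i, _, _ in b.members:
            assert b.key in seqs[i] or b.key in reverse_complement(seqs[i])


def test_blocks_support_mixed_read_lengths():
    seqs = ["ACGTACGTACGT", "TTACGTACGTACGTAA"]  # share the 12-mer anchor
    blocks = build_blocks(seqs, 12)
    joint = [b for b in blocks if b.size == 2]
    assert len(joint) == 1


@pytest.mark.parametrize(
    "kwargs",
    [
        {"k_values": ()},
        {"k_values": (32, 31)},
        {"k_values": (10, 10)},
        {"k_values": (10, 3)},
        {"k_values": (10, 12)},
        {"k_values": (10, 8), "ordering": "alphabetical"},
    ],
)
def test_round_config_validation(kwargs):
    with pytest.raises(ValueError):
        RoundConfig(**kwargs)


def test_default_round_panel():
    cfg = RoundConfig.default()
    assert cfg.k_values == tuple(range(29, 9, -1))
    assert len(cfg.rounds()) == 40  # minimizer + maximizer rounds
    speedy = RoundConfig.default(speedy=True)
    assert len(speedy.rounds()) == 20
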