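import numpy as np
import pytest

from readspan.codec import decode_child, encode_child
from readspan.dedup import find_duplicates, reverse_complement
from readspan.exhaustive import best_partners
from readspan.fastq_io import ReadSet
from readspan.graph import (
    GraphConfig,
    align_by_anchor,
    collect_rounds,
    edge_weight,
    find_candidate_edges,
    mismatching_distance,
)
from readspan.indexer import RoundConfig, build_blocks, k_minimizer
from readspan.simulate import SimConfig, simulate_readset


def _rand_seq(rng, L):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, L))


@pytest.mark.parametrize("mb, ob, expected", [(1, 0, 3), (0, 1, 1), (2, 3, 9)])
def test_edge_weight_formula(mb, ob, expected):
    assert edge_weight(mb, ob) == expected


def test_edge_weight_rejects_identical_layout():
    with pytest.raises(ValueError):
        edge_weight(0, 0)


def test_mismatching_distance_examples():
    rng = np.random.default_rng(7)
    a = _rand_seq(rng, 100)
    assert mismatching_distance(a, a, 0) == (0, 0)

    b = a[:24] + ("T" if a[24] != "T" else "C") + a[25:]
    assert mismatching_distance(a, b, 0) == (1, 1)

    c = a[1:] + "G"  # perfect 99-base overlap at offset 1
    mb, dist = mismatching_distance(a, c, 1, "u_ahead")
    assert (mb, dist) == (0, 1)


def test_mismatching_distance_requires_overlap():
    with pytest.raises(ValueError):
        mismatching_distance("ACGTACGT", "ACGTACGT", 8)


def test_align_by_anchor_same_strand():
    assert align_by_anchor(100, 100, (5, False), (5, False)) == (0, False)
    # v's anchor one base earlier means v starts one base into u
    assert align_by_anchor(100, 100, (5, False), (4, False)) == (1, False)


def test_align_by_anchor_rc_strand_matches_explicit_rc():
    rng = np.random.default_rng(8)
    L, k = 100, 12
    u = _rand_seq(rng, L)
    # v is the reverse complement of a shifted copy of u
    shift = 7
    v = reverse_complement(u[shift:] + _rand_seq(rng, shift))
    hit_u = k_minimizer(u, k, both_strands=True)
    hit_v = k_minimizer(v, k, both_strands=True)
    assert hit_u.kmer == hit_v.kmer
    assert (hit_u.strand == "rc") != (hit_v.strand == "rc")
    delta, strand = align_by_anchor(
        L, L, (hit_u.position, hit_u.strand == "rc"),
        (hit_v.position, hit_v.strand == "rc"),
    )
    assert strand is True
    vv = reverse_complement(v)
    lo, hi = max(0, delta), min(L, delta + L)
    assert u[lo:hi] == vv[lo - delta : hi - delta]  # perfect overlap recovered
    assert abs(delta) == shift


def test_chain_of_shifted_reads_yields_expected_edges():
    rng = np.random.default_rng(9)
    base = _rand_seq(rng, 102)
    seqs = [base[i : i + 100] for i in range(3)]  # colinear, 1-shifted
    blocks = build_blocks(seqs, 12)
    edges = find_candidate_edges(blocks, seqs, GraphConfig(search_limit=None))
    by_pair = {(e.u, e.v): e.weight for e in edges}
    assert by_pair[(0, 1)] == 1
    assert by_pair[(1, 2)] == 1
    assert by_pair[(0, 2)] == 2


def test_every_edge_decodes_its_endpoints():
    reads, _ = simulate_readset(
        SimConfig(genome_length=800, coverage=15, read_length=90,
                  substitution_rate=0.01, rc_probability=0.5, seed=10)
    )
    ded = find_duplicates(reads)
    seqs = ded.distinct.sequences
    edges = collect_rounds(seqs, RoundConfig.default(n_rounds=10), GraphConfig())
    assert edges, "simulation should produce overlapping reads"
    for e in edges:
        Lu, Lv = len(seqs[e.u]), len(seqs[e.v])
        assert e.weight == 3 * e.mb + e.offset
        for child, parent in ((e.v, e.u), (e.u, e.v)):
            delta_cp, rc = e.child_layout(child, Lu, Lv)
            text, direction = encode_child(
                seqs[child], seqs[parent], delta_cp, rc, check=False
            )
            got = decode_child(seqs[parent], text, direction, rc, len(seqs[child]))
            assert got == seqs[child]


def test_edge_stream_is_weight_sorted_and_deduplicated():
    reads, _ = simulate_readset(
        SimConfig(genome_length=600, coverage=12, read_length=80,
                  substitution_rate=0.02, seed=11)
    )
    ded = find_duplicates(reads)
    edges = collect_rounds(ded.distinct, RoundConfig.default(n_rounds=8))
    weights = [e.weight for e in edges]
    assert weights == sorted(weights)
    pairs = [(e.u, e.v) for e in edges]
    assert len(pairs) == len(set(pairs))
    assert all(e.u < e.v for e in edges)


def test_speedy_mode_edges_are_a_subset():
    reads, _ = simulate_readset(
        SimConfig(genome_length=500, coverage=12, read_length=80,
                  substitution_rate=0.01, seed=12)
    )
    ded = find_duplicates(reads)
    full = collect_rounds(ded.distinct, RoundConfig.default(n_rounds=10))
    speedy = collect_rounds(ded.distinct, RoundConfig.default(n_rounds=10, speedy=True))
    full_pairs = {(e.u, e.v) for e in full}
    assert {(e.u, e.v) for e in speedy} <= full_pairs


def test_candidate_weights_never_beat_the_exhaustive_oracle():
    reads, _ = simulate_readset(
        SimConfig(genome_length=400, coverage=15, read_length=60,
                  substitution_rate=0.02, rc_probability=0.5, seed=13)
    )
    ded = find_duplicates(reads)
    seqs = ded.distinct.sequences[:120]
    edges = collect_rounds(seqs, RoundConfig.default(k1=29), GraphConfig(search_limit=None))
    oracle = {b.read: b.weight for b in best_partners(seqs)}
    lightest = {}
    for e in edges:
        lightest[e.u] = min(lightest.get(e.u, 10 ** 9), e.weight)
        lightest[e.v] = min(lightest.get(e.v, 10 ** 9), e.weight)
    for read, w in lightest.items():
        assert w >= oracle[read]  # heuristic can never undercut the exact search


def test_mixed_length_pairs_require_a_shifting_offset():
    rng = np.random.default_rng(14)
    long_read = _rand_seq(rng, 100)
    seqs = [long_read, long_read[:80]]  # nested at offset 0
    edges = collect_rounds(seqs, RoundConfig.default(n_rounds=10),
                           GraphConfig(search_limit=None))
    assert all(e.offset > 0 for e in edges)
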