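import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readspan.codec import (
    EncodingError,
    Fenwick,
    decode_child,
    decode_order_free_structure,
    decode_order_preserving,
    dfs_encode,
    encode_child,
    is_backtrack_line,
    order_preserving_encode,
    pair_distance_stream,
    parse_encoded_text,
    renumber_read_ids,
    resolve_pairs,
)
from readspan.dedup import find_duplicates, reverse_complement
from readspan.fastq_io import ReadSet
from readspan.graph import Edge
from readspan.msf import kruskal_msf


def _rand_seq(rng, L):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, L))


def _readset(seqs):
    return ReadSet(sequences=list(seqs), read_length=len(seqs[0]), n1=len(seqs))


# ---------------------------------------------------------------------------
# reference codes
# ---------------------------------------------------------------------------


def test_shift_plus_mismatch_reference_code():
    text, direction = encode_child("ATGCAT", "GCATCC", 2, False)
    assert text == "AT2G"
    assert direction == 1  # child starts after the parent: right shift
    assert decode_child("GCATCC", "AT2G", 1, False, 6) == "ATGCAT"


def test_pure_hamming_reference_code():
    rng = np.random.default_rng(20)
    parent = _rand_seq(rng, 100)
    child = parent[:24] + ("T" if parent[24] != "T" else "C") + parent[25:]
    text, direction = encode_child(child, parent, 0, False)
    assert text == f"24{child[24]}"
    assert decode_child(parent, text, direction, False, 100) == child


def test_pure_shift_reference_code():
    rng = np.random.default_rng(21)
    parent = _rand_seq(rng, 100)
    child = parent[1:] + "A"
    text, direction = encode_child(child, parent, 1, False)
    assert (text, direction) == ("A", 1)
    left_child = "G" + parent[:-1]
    text2, direction2 = encode_child(left_child, parent, -1, False)
    assert (text2, direction2) == ("G", 0)


def test_delta_encoding_of_multiple_mismatches():
    parent = "A" * 30
    child = "A" * 5 + "C" + "A" * 11 + "G" + "A" * 12
    text, _ = encode_child(child, parent, 0, False)
    assert text == "5C12G"  # absolute first, then position gaps
    assert decode_child(parent, text, 1, False, 30) == child


@given(st.data())
@settings(deadline=None, max_examples=200)
def test_reference_code_round_trip(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
    Lp = data.draw(st.integers(20, 120))
    delta = data.draw(st.integers(-10, 10))
    rc = data.draw(st.booleans())
    # child no longer than the parent keeps every delta encodable
    Lc = data.draw(st.integers(max(1, abs(delta)), Lp))
    parent = _rand_seq(rng, Lp)
    if delta >= 0:
        base = parent[delta:Lc] + _rand_seq(rng, Lc - (Lc - delta))
    else:
        base = _rand_seq(rng, -delta) + parent[: Lc + delta]
    chars = list(base)
    for _ in range(data.draw(st.integers(0, 4))):
        p = int(rng.integers(0, Lc))
        chars[p] = "ACGT"[int(rng.integers(0, 4))]
    cc = "".join(chars)
    child = reverse_complement(cc) if rc else cc
    try:
        text, direction = encode_child(child, parent, delta, rc, check=False)
    except EncodingError:
        # offset-0 identity: not a legal non-root code
        assert delta == 0 and cc == parent[:Lc]
        return
    assert decode_child(parent, text, direction, rc, Lc) == child
    assert any(c not in "0123456789" for c in text)


@pytest.mark.parametrize("text", ["12", "AC12", "5"])
def test_malformed_encoded_text_is_rejected(text):
    with pytest.raises(EncodingError, match="malformed"):
        parse_encoded_text(text)


def test_backtrack_line_classification():
    assert is_backtrack_line("17")
    assert not is_backtrack_line("AT2G")
    assert not is_backtrack_line("24T")
    assert not is_backtrack_line("")


# ---------------------------------------------------------------------------
# DFS serialization
# ---------------------------------------------------------------------------


def _mutate_at(seq, pos):
    return seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]


def _hamming_edge(seqs, u, v):
    mismatches = tuple(
        (i, a, b) for i, (a, b) in enumerate(zip(seqs[u], seqs[v])) if a != b
    )
    return Edge(u=u, v=v, delta=0, strand=False, mismatches=mismatches)


def test_dfs_emits_backtracking_between_subtrees():
    rng = np.random.default_rng(22)
    r0 = _rand_seq(rng, 50)
    seqs = [r0, _mutate_at(r0, 5), _mutate_at(_mutate_at(r0, 5), 10),
            _mutate_at(r0, 20), _rand_seq(rng, 50)]
    # tree: 0 -> 1 -> 2, 0 -> 3; node 4 isolated
    edges = sorted(
        [_hamming_edge(seqs, 0, 1), _hamming_edge(seqs, 1, 2),
         _hamming_edge(seqs, 0, 3)],
        key=lambda e: e.weight,
    )
    forest = kruskal_msf(5, edges)
    ded = find_duplicates(_readset(seqs))
    bundle, rank_of = dfs_encode(forest, seqs, ded)

    lines = bundle.s1_lines
    assert lines[0] == r0
    assert lines[3] == "2"  # leaf 2 -> back up two levels -> sibling 3
    assert lines[5] == "-"  # tree separator
    assert lines[6] == seqs[4]
    assert all(is_backtrack_line(l) or l == "-" or any(c.isalpha() for c in l)
               for l in lines)
    assert len(bundle.s2_dir_bits) == len(bundle.s3_rc_bits) == 3  # non-roots
    assert bundle.s4_dup_bits == [0] * 5
    assert list(rank_of) == [0, 1, 2, 3, 4]  # preorder visiting ranks

    nodes = decode_order_free_structure(lines)
    assert [p for _, p in nodes] == [-1, 0, 1, 0, -1]


def test_duplicate_counts_travel_in_streams_4_and_5():
    rng = np.random.default_rng(23)
    r0 = _rand_seq(rng, 60)
    seqs = [r0, r0, reverse_complement(r0), _mutate_at(r0, 7)]
    ded = find_duplicates(_readset(seqs))
    assert ded.n_distinct == 2
    edges = [_hamming_edge(ded.distinct.sequences, 0, 1)]
    forest = kruskal_msf(2, edges)
    bundle, rank_of = dfs_encode(forest, ded.distinct.sequences, ded)
    assert bundle.s4_dup_bits == [1, 0]
    assert bundle.s5_dup_counts == [(1, 1)]
    # ranks: representative, normal copy, rc copy, then the child node
    assert list(rank_of) == [0, 1, 2, 3]


# ---------------------------------------------------------------------------
# order-preserving mode
# ---------------------------------------------------------------------------


def test_parent_id_renumbering_drops_duplicates_and_singletons():
    # seven reads; r3 and r6 duplicate earlier reads; r2 is a singleton
    ids = renumber_read_ids(7, duplicate_indices={2, 5}, singleton_indices={1})
    assert ids == {0: 1, 3: 2, 4: 3, 6: 4}


def test_order_preserving_round_trip_with_duplicates_and_singletons():
    rng = np.random.default_rng(24)
    r0 = _rand_seq(rng, 50)
    seqs = [r0, _rand_seq(rng, 50), _mutate_at(r0, 3), r0,
            reverse_complement(_mutate_at(r0, 3))]
    ded = find_duplicates(_readset(seqs))
    assert ded.n_distinct == 3
    edges = [_hamming_edge(ded.distinct.sequences, 0, 2)]
    forest = kruskal_msf(3, edges)
    bundle = order_preserving_encode(forest, ded.distinct.sequences, ded)
    assert bundle.s1_lines[3] == "" and bundle.s1_lines[4] == ""
    assert bundle.singleton_bits == [0, 1, 0]
    assert decode_order_preserving(bundle, 50) == seqs


# ---------------------------------------------------------------------------
# pairing streams
# ---------------------------------------------------------------------------


def test_fenwick_prefix_and_select_against_brute_force():
    rng = np.random.default_rng(25)
    n = 64
    fen = Fenwick(n)
    present = [1] * n
    for i in rng.permutation(n)[:40]:
        fen.add(int(i), -1)
        present[int(i)] = 0
    for i in range(n):
        assert fen.prefix(i) == sum(present[: i + 1])
    alive = [i for i in range(n) if present[i]]
    for rank, idx in enumerate(alive, start=1):
        assert fen.select(rank) == idx


def test_pair_distance_counts_only_unprocessed_reads():
    # pairs by rank: A=(0,3), B=(1,5), C=(2,4)
    # processing B sees ranks 2,3,4 between its mates, rank 3 already done
    rank_of = np.array([0, 1, 2, 3, 5, 4])  # orig -> rank, n1 = 3
    distances, order_bits, original = pair_distance_stream(rank_of, 3)
    assert distances[0] == 2  # A: ranks 1, 2 in between
    assert distances[1] == 2  # B: ranks 2, 4 still unprocessed
    assert distances[2] == 0  # C: adjacent among the remaining
    assert order_bits == [1, 1, 1]
    assert original == [0, 1, 2]
    pairs = resolve_pairs(6, distances, order_bits)
    assert pairs == [(0, 3), (1, 5), (2, 4)]


@given(st.integers(0, 10_000), st.integers(1, 120))
@settings(deadline=None, max_examples=60)
def test_pairing_round_trip_on_random_visit_orders(seed, n_pairs):
    rng = np.random.default_rng(seed)
    R = 2 * n_pairs
    rank_of = rng.permutation(R)
    distances, order_bits, _ = pair_distance_stream(rank_of, n_pairs)
    pairs = resolve_pairs(R, distances, order_bits)
    rank2orig = np.empty(R, dtype=int)
    rank2orig[rank_of] = np.arange(R)
    for r1, r2 in pairs:
        o1, o2 = int(rank2orig[r1]), int(rank2orig[r2])
        assert o1 < n_pairs <= o2  # bit orientation restores file membership
        assert o2 - o1 == n_pairs  # and the mates really are a pair
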