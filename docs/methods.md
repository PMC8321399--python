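# Methods

## The model

`readspan` treats a set of distinct fixed-length reads `RS = {r_1 … r_m}`
as the nodes of an undirected *Hamming-shifting graph*. Two reads are
linkable when they align with a small *mismatching distance*: the Hamming
distance when they do not shift, or the number of overlap mismatches plus
the (non-zero) shifting offset when one read's prefix overlaps the other's
suffix. Reverse-complement alignments are allowed (strand is a per-edge
flag). For compression the edge weight is the code-length proxy

    w = 3·mb + ob

where `mb` is the overlap mismatch count and `ob` the offset: a mismatch
item costs roughly three characters (digits + base) while an offset base
costs one. Each node carries the multiplicity of the read in the raw file,
split into normal-strand and reverse-complement duplicate counts.

A minimum spanning forest of the candidate graph minimises the total edge
weight, hence (to the resolution of the proxy) the total reference-code
length: every non-root read is decoded from its parent alone, so a whole
tree is transferred as one raw root plus per-child codes of a few bytes.

Assumptions: fixed read length per input file (two lengths for paired-end),
substitution-type errors only (no indels — a single shifting event per
edge), alphabet `{A,C,G,T,N}`.

## Edge detection

Exhaustive pairwise search is quadratic, so candidates come from
multi-round k-minimizer indexing:

1. per round, every read picks its minimizer — the ordering-smallest k-mer
   over both strands (ineligible if the window contains an N; ties broken
   to the leftmost position, forward strand first);
2. reads sharing the minimizer form a block, sorted by hit position;
3. each block member is aligned against up to `search_limit` (default 32)
   preceding members, anchored at the shared k-mer: the offset is the
   difference of hit positions after strand normalization, and overlap
   mismatches are counted directly.

The panel is `k_i = k_1 - i + 1` with `k_1 = 29` and 20 rounds (so
`k_20 = 10`), repeated with k-maximizers (ordering-largest k-mer) unless
speedy mode is chosen; each round contributes candidates independently.
Edges heavier than `max_weight` (default: the read length, above which a
code is no cheaper than the raw read) are dropped; per unordered pair only
the lightest discovered edge is kept. Edges are binned by weight and
consumed by Kruskal in nondecreasing order; equal-weight ties keep
first-discovery order, which can change tree shape but never total weight.

The ordering is lexicographic by default; `--hash-order` switches to an
invertible multiply-xorshift ordering (seeded, default 17) that better
matches the uniformity idealization below.

### Detection probability

With `s` shifting bases and `t` differing k-mers in the overlap, a pair
shares `L-k+1-(s+t)` of its `L-k+1` k-mers. Idealizing each read's
minimizer as uniform over its windows and the two choices as independent
gives a per-round co-blocking probability
`p(k) = ((L-k+1-(s+t))/(L-k+1))²` and a multi-round detection probability
`1 - Π(1-p(k_i)) > 1 - (1-p_min)^n`. Two idealizations matter in
practice. First, the independence assumption is conservative: the shared
windows have identical ordering keys in both reads, which positively
correlates the two choices (if both minimizers fall in the common set they
are necessarily equal), so measured co-blocking sits at or above the
formula — the Monte-Carlo check and the recall measurement are therefore
one-sided (observed ≥ predicted − 3 standard errors). Second, the formula
ignores coincidental k-mer sharing outside the overlap, which can anchor a
sub-optimal alignment; the multi-k panel makes a read pair's detection
survive any single bad round.

## Encoding streams

A child read is stored as *shifting substring* + *mismatch items*. The
substring is exactly `ob` bases: the child's tail for a right shift (child
starts after its parent), its head for a left shift; a direction bit
distinguishes the two and a strand bit says whether the child was encoded
as its reverse complement. Items are `(position, base)` with 0-based child
coordinates, the first absolute and the rest as gaps from the previous
position (pure difference). The decoder recovers `ob` as the length of the
leading non-digit run, so codes are self-delimiting; every non-root code
contains at least one letter, which keeps it distinguishable from the
all-digit backtracking lines.

Order-free mode serializes each tree in DFS preorder: root raw, children's
codes in visit order (children sorted by index), and after each subtree an
all-digit line holding the number of consecutive upward steps before the
next descent; trailing pops at a tree's end are omitted and a `-` sentinel
line separates trees (the sentinel is this implementation's convention for
making tree boundaries explicit). Stream 2 holds direction bits, stream 3
strand bits (one per non-root), stream 4 a has-duplicates bit per node and
stream 5 the (normal, RC) duplicate count pairs (varint-coded). On
decompression duplicates re-materialize adjacent to their representative —
their original interleaving is not retained in this mode, by design.

Order-preserving (single-end) mode writes one line per original read in
file order: raw read for roots, reference code for children, an empty line
for a duplicating read. A parent-ID stream gives each child its parent's
ID after renumbering that removes duplicating and singleton reads (they
can never be parents); ID 0 marks roots; a duplicate's entry references
its representative in the distinct-read numbering, with strand in stream 3.
Because a decoder cannot know which roots are childless before resolving
the tree, the archive adds one singleton-flag bit per distinct read so the
renumbering is reproducible; streams 4 and 5 are dropped.

Paired-end input is vertically concatenated (file 1 then file 2; the two
read lengths may differ) and compressed as one read set. Every read —
including duplicates — gets a visiting rank (representative, then normal
copies, then RC copies). Scanning ranks in order, each unprocessed read
opens its pair: the stored distance is the number of still-unprocessed
reads strictly between the mates' ranks, maintained with a Fenwick
(binary indexed) tree, and an extra bit records whether the earlier mate
came from file 1. Decoding replays the scan with Fenwick select. When the
two files have different read lengths, only edges with a non-zero offset
are accepted between unequal-length reads (an offset-0 code would leave
the layout unrecoverable), and additionally each edge must be expressible
as a single shifting substring in *both* orientations — a nested alignment
(shorter read strictly inside a longer one) has two overhangs on one side
and is rejected, since tree orientation is unknown at edge time. The
paired decoder runs two passes: line classification needs no bases, so
pairing — hence each node's file of origin and read length — is resolved
before any sequence is decoded. Order-preserving paired mode appends each
pair's original index as one more integer stream.

All streams are backend-compressed: bz2 (block-sorting family) for text
and bit streams, LZMA for the pair-distance integers, with a raw fallback
when a backend would inflate a tiny stream. The `.mstc` container is
self-describing: magic, version, a JSON header with mode, read lengths,
counts and a per-stream table (backend, sizes, CRC32), then the payloads.
Corruption — bad magic, truncation, checksum mismatch — raises a distinct
archive error.

## Synthetic data

The generator emulates the three characteristics the method exploits:
uniform-position sampling of a uniform random linear genome at a chosen
coverage (default 30×, read length 100), i.i.d. substitution errors to a
uniformly chosen different base (default 1%), per-read reverse complement
(default 0.5), and verbatim duplicate emission (adjacent to the original).
Paired-end mode draws insert sizes from a clipped normal (default
300 ± 20) and reads the mate from the reverse strand. It does **not**
model indels, quality-dependent or position-dependent error profiles,
platform-specific biases, or repetitive genome structure, so passing tests
demonstrate correctness of the algorithms and the expected behaviour on
overlap-rich substitution-error data — not performance on any particular
instrument's output. A truth table (origin position, strand, error count,
duplicate flag) accompanies every simulation; at zero error rate the reads
are re-derivable from it by substring matching.

The deterministic five-read chain fixture (`chain_example_reads`) builds
four reads one substitution apart plus a fifth shifted by one base, with a
shared 31-base A-run far from the mutated positions so that every round
anchors the pairs on an identical window — the clean mutual-reference path
whose codes are `24T`, `14G`, `4G`, `A`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k1` | 29 | largest minimizer k (≤ 31 so a k-mer code fits a machine word) |
| `n_rounds` | 20 | k panel length; `k_i = k_1 - i + 1`, floored at k = 4 |
| maximizers | on | repeat the panel with k-maximizers; off = speedy mode |
| ordering | lexicographic | k-mer order; `hashed` approximates uniformity |
| `hash_seed` | 17 | seed of the invertible hash ordering |
| `search_limit` | 32 | preceding block members compared per read (None = all) |
| `max_weight` | read length | edge weight cap; heavier codes cannot beat the raw read |
| dedup k | 31 | minimizer size for duplicate blocking |

## Numerical and design choices

- K-mers are base-4 integer codes (`A=0 < C < G < T`), so numeric order is
  lexicographic order; windows containing N are ineligible, and a read with
  no eligible window in any round becomes a singleton root. N complements
  to N.
- A read equal to its own reverse complement counts extra copies as
  normal-strand duplicates (tie broken toward normal).
- Duplicate blocking keys on the canonical-orientation 31-minimizer and
  its position, with full-string verification inside each block, so key
  collisions can never merge unequal reads; reads shorter than 31 bases
  fall back to the canonical string itself as the key.
- Tree roots are the smallest distinct-read index per component ("any node
  can be root"); children are visited in index order.
- Every emitted reference code is verified by decoding during compression
  (`check=True`); the cost is linear and it converts any encoder defect
  into an immediate error instead of a corrupt archive.
- The per-weight edge bins are in-memory lists; the design scales to the
  package's target of in-memory data sets, not to disk-spilled billions of
  reads (the stated complexity reduction from `O(m²)` to block-local work
  still applies).
- Parallelism: the CLI accepts `--threads` for interface parity, but the
  implementation is single-threaded; any future parallel edge construction
  must keep archives byte-identical.

Problem sizes in the test suite and acceptance script (≈ 1000 reads for
round trips, 300 distinct reads for the exhaustive-recall comparison,
100-node graphs for the MST oracle) are chosen so the quadratic exact
baselines stay tractable while remaining comfortably above the regime
where every code path (duplicates, RC edges, shifts, multi-tree forests,
pairing) is exercised.

## Known limitations

- Indels between reads are not modelled; a single-base insertion shifts
  every downstream base and typically severs the pair.
- Order-free mode does not preserve the interleaving of duplicate copies
  (only their counts and strands), which is what makes it the smaller
  mode.
- Variable-length reads within one file are rejected; only the two-length
  paired-end case is supported.
- Headers and quality strings are discarded; decompressed FASTQ carries
  synthetic headers.
- The archive format is this package's own; it is not interoperable with
  other read compressors.
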