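# readspan

Reference-free, lossless compression of fixed-length genomic short reads.

Next-generation sequencing reads a genome at high coverage, so a FASTQ file
is full of near-redundancy: exact duplicate reads (on either strand), reads
that differ only by a few base-call errors, and reads that overlap because
fragmentation is random. `readspan` turns that redundancy into a graph
problem. Distinct reads become nodes of a *Hamming-shifting graph*: an edge
links two reads whose best alignment has `mb` mismatching bases in the
overlap and a shifting offset of `ob` bases, weighted

```
w(e(r_i, r_j)) = 3·mb + ob
```

A minimum spanning forest of this graph (Kruskal over a disjoint set)
gives every read a parent it can be expressed against, and each non-root
read is stored as a tiny reference code — the offset bases plus
delta-encoded `(position, base)` mismatch items. A read `ATGCAT` whose
parent is `GCATCC` at shift 2 costs just the four characters `AT2G`.

Because pairwise comparison of millions of reads is infeasible, candidate
edges are found by *multi-round minimizer indexing*: in round *i* the reads
are bucketed by their lexicographically (or hash-order) smallest k-mer with
`k = k1 - i + 1` (default `k1 = 29`, 20 rounds, repeated with k-maximizers),
and only neighbours within a bucket are aligned, anchored at the shared
k-mer. Under the uniformity hypothesis the chance that a pair sharing
`L-k+1-(s+t)` of its `L-k+1` k-mers is bucketed together at least once in
`n` rounds is at least `1 - (1 - p(k))^n` with
`p(k) = ((L-k+1-(s+t))/(L-k+1))²` — above 0.96 already for `p(k) = 0.15`
and `n = 20`. The `theory` module implements these formulas; the
`exhaustive` module provides the quadratic exact search used to measure the
heuristic's recall.

The package is for bioinformaticians who need smaller FASTQ archives than
general-purpose compressors achieve, and for anyone studying read-overlap
graph structure. Single-end and paired-end inputs (including mates of
different lengths) are supported, in two modes: *order-free* (smallest
archives; decompression restores the read multiset / pair multiset) and
*order-preserving* (exact original order). Only sequence lines are
compressed; headers and qualities are out of scope.

## Worked example

```bash
readspan simulate /tmp/demo --genome-length 3333 --coverage 30 \
    --read-length 100 --error-rate 0.01 --duplicate-rate 0.02 --seed 3
readspan compress /tmp/demo.fastq /tmp/demo.mstc
readspan decompress /tmp/demo.mstc /tmp/restored
```

The compressor logs (stderr):

```
[read] 1011 reads, 101100 bases (0.00s)
[graph] 977 distinct reads, 11982 candidate edges, 34 trees, forest weight 7621 (0.74s)
[done] 5718 bytes, 0.4525 bpb
```

Reading: 1011 simulated 100-bp reads (34 exact duplicates collapsed) were
linked by 11,982 candidate edges; the spanning forest has 34 trees whose
edges cost 7,621 weight units in total; the archive is 5,718 bytes, i.e.
**0.45 bits per base** — well below the 2 bits/base of raw 2-bit packing.
Decompression restores the exact read multiset (add `--order-preserving`
to restore the original file order byte-for-byte; add `-2 mate.fastq` for
paired-end input).

The analytic detection model is available from the same CLI:

```bash
$ readspan theory --n 20 --p 0.15
p_multi(n=20, p=0.15) = 0.961240
```

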