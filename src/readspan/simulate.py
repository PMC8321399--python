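"""Synthetic short-read generator.

Emulates the three sequencing characteristics the compressor exploits:
multi-coverage sampling of a genome (many shifted overlaps), low-rate
base-call substitution errors, and duplicate reads on either strand.
Reads are sampled at uniform random positions from a uniform random linear
genome; no indels are introduced (the alignment model covers substitutions
and shifts only).  Fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kmers
from .dedup import reverse_complement
from .fastq_io import ReadSet, write_fastq

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_readset",
    "simulate",
    "chain_example_reads",
]


def chain_example_reads(seed: int = 0) -> list[str]:
    """Five 100-bp reads forming a weight-light mutual-reference path.

    Reads 1-4 differ from their predecessor by one substitution (at
    positions 24, 14 and 4 respectively) and read 5 is read 4 shifted right
    by one base.  The reads carry a shared A-run well away from the mutated
    positions, so every indexing round anchors the pairs on an identical
    error-free window -- the clean-overlap situation the path illustrates.
    """
    rng = np.random.default_rng(seed)
    chars = ["CGT"[b] for b in rng.integers(0, 3, 100)]  # no stray A runs
    for i in range(7, 100):  # cap T runs: keep the RC strand run-free too
        if all(c == "T" for c in chars[i - 7 : i + 1]):
            chars[i] = "G"
    chars[60:91] = ["A"] * 31  # shared anchor run for every k <= 31
    chars[4], chars[14], chars[24] = "T", "A", "C"
    r1 = "".join(chars)
    r2 = r1[:24] + "T" + r1[25:]
    r3 = r2[:14] + "G" + r2[15:]
    r4 = r3[:4] + "G" + r3[5:]
    r5 = r4[1:] + "A"
    return [r1, r2, r3, r4, r5]


@dataclass(frozen=True)
class TruthRecord:
    """Origin of one emitted read: genome position, strand, error count,
    and whether it is a verbatim duplicate of the previous emission."""

    read_id: int
    position: int
    strand: str  # "+" or "-"
    n_errors: int
    is_duplicate: bool = False


@dataclass
class SimConfig:
    genome_length: int = 10_000
    coverage: float = 30.0
    read_length: int = 100
    read_length2: int | None = None  # paired-end mate length (defaults to L1)
    substitution_rate: float = 0.01
    rc_probability: float = 0.5
    duplicate_rate: float = 0.0
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.rc_probability, self.duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.genome_length < self.read_length:
            raise ValueError("genome must be at least one read long")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def L2(self) -> int:
        return self.read_length2 if self.read_length2 is not None else self.read_length


def _mutate(mat: np.ndarray, rate: float, rng) -> np.ndarray:
    """Per-base substitution to a uniformly chosen different base."""
    errs = rng.random(mat.shape) < rate
    bump = rng.integers(1, 4, size=mat.shape)
    out = mat.copy()
    out[errs] = (out[errs] + bump[errs]) % 4
    return out, errs.sum(axis=1)


def _to_strings(mat: np.ndarray) -> list[str]:
    return [_kmers.decode_seq(row.astype(np.uint8)) for row in mat]


def simulate_readset(config: SimConfig) -> tuple[ReadSet, list[TruthRecord]]:
    """Generate reads in memory together with their origin truth records.

    For paired-end output, truth records cover file-1 reads then file-2
    reads (matching the vertical-concatenation read order).
    """
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    genome = rng.integers(0, 4, size=G, dtype=np.int64)

    if not config.paired:
        L = config.read_length
        n = max(1, int(round(config.coverage * G / L)))
        pos = rng.integers(0, G - L + 1, size=n)
        mat = genome[pos[:, None] + np.arange(L)]
        mat, n_errs = _mutate(mat, config.substitution_rate, rng)
        rc_mask = rng.random(n) < config.rc_probability
        dup_mask = rng.random(n) < config.duplicate_rate
        seqs: list[str] = []
        truth: list[TruthRecord] = []
        raw = _to_strings(mat)
        for i in range(n):
            seq = reverse_complement(raw[i]) if rc_mask[i] else raw[i]
            strand = "-" if rc_mask[i] else "+"
            seqs.append(seq)
            truth.append(
                TruthRecord(len(seqs) - 1, int(pos[i]), strand, int(n_errs[i]))
            )
            if dup_mask[i]:
                seqs.append(seq)
                truth.append(
                    TruthRecord(
                        len(seqs) - 1, int(pos[i]), strand, int(n_errs[i]), True
                    )
                )
        rs = ReadSet(sequences=seqs, read_length=L, n1=len(seqs))
        return rs, truth

    L1, L2 = config.read_length, config.L2
    min_insert = max(L1, L2)
    if G < min_insert:
        raise ValueError("genome shorter than the minimum insert")
    n = max(1, int(round(config.coverage * G / (L1 + L2))))
    inserts = np.clip(
        np.round(rng.normal(config.insert_mean, config.insert_sd, size=n)),
        min_insert,
        G,
    ).astype(np.int64)
    pos = np.array([rng.integers(0, G - ins + 1) for ins in inserts])
    mat1 = genome[pos[:, None] + np.arange(L1)]
    ends = pos + inserts
    mat2 = genome[(ends - L2)[:, None] + np.arange(L2)]
    mat1, errs1 = _mutate(mat1, config.substitution_rate, rng)
    mat2, errs2 = _mutate(mat2, config.substitution_rate, rng)
    dup_mask = rng.random(n) < config.duplicate_rate
    raw1, raw2 = _to_strings(mat1), _to_strings(mat2)
    file1: list[str] = []
    file2: list[str] = []
    truth1: list[TruthRecord] = []
    truth2: list[TruthRecord] = []
    for i in range(n):
        r1 = raw1[i]
        r2 = reverse_complement(raw2[i])  # mate 2 reads the reverse strand
        reps = 2 if dup_mask[i] else 1
        for rep in range(reps):
            file1.append(r1)
            file2.append(r2)
            truth1.append(
                TruthRecord(len(file1) - 1, int(pos[i]), "+", int(errs1[i]), rep > 0)
            )
            truth2.append(
                TruthRecord(
                    len(file2) - 1, int(ends[i]) - L2, "-", int(errs2[i]), rep > 0
                )
            )
    rs = ReadSet(
        sequences=file1 + file2,
        read_length=L1,
        read_length2=L2,
        n1=len(file1),
    )
    return rs, truth1 + truth2


def simulate(config: SimConfig, out_prefix) -> list[str]:
    """Write simulated FASTQ file(s) plus a truth TSV; returns the paths."""
    reads, truth = simulate_readset(config)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if config.paired:
        paths = [f"{prefix}_1.fastq", f"{prefix}_2.fastq"]
        write_fastq(reads, paths[0], paths[1])
    else:
        paths = [f"{prefix}.fastq"]
        write_fastq(reads, paths[0])
    truth_path = f"{prefix}.truth.tsv"
    with open(truth_path, "w") as out:
        out.write("read_id\tposition\tstrand\tn_errors\tis_duplicate\n")
        for rec in truth:
            out.write(
                f"{rec.read_id}\t{rec.position}\t{rec.strand}\t"
                f"{rec.n_errors}\t{int(rec.is_duplicate)}\n"
            )
    return paths + [truth_path]
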