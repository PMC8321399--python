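"""FASTQ sequence I/O.

Only the sequence lines of a FASTQ file are of interest here: headers and
quality strings are parsed (so that malformed records are caught) and then
discarded.  Decompressed output therefore carries synthetic headers and no
original qualities -- losslessness is defined on the sequence lines.

Paired-end input is handled by vertically concatenating the two files: the
reads of file 1 are followed by the reads of file 2, and pair *i* maps to
indices ``(i, n1 + i)``.  The two files may have different read lengths.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["ReadSet", "FastqFormatError", "read_fastq", "concat_paired", "write_fastq"]

_VALID = set("ACGTN")


class FastqFormatError(ValueError):
    """Raised for malformed records, bad alphabets or length violations."""


@dataclass
class ReadSet:
    """An ordered collection of fixed-length nucleotide reads.

    Attributes
    ----------
    sequences:
        Uppercase strings over ``{A, C, G, T, N}`` in file order.  For
        paired-end data this is file 1 followed by file 2.
    read_length:
        Common length of the file-1 reads (all reads, if single-end).
    read_length2:
        Common length of the file-2 reads; ``None`` for single-end input.
    n1:
        Number of reads that came from file 1 (``len(sequences)`` if
        single-end).
    """

    sequences: list[str] = field(default_factory=list)
    read_length: int = 0
    read_length2: Optional[int] = None
    n1: int = 0

    @property
    def paired(self) -> bool:
        return self.read_length2 is not None

    @property
    def origin_count(self) -> int:
        return len(self.sequences)

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.sequences)

    def pairing(self) -> dict[int, tuple[int, int]]:
        """Map pair index -> (index in file 1, index in file 2)."""
        if not self.paired:
            return {}
        return {i: (i, self.n1 + i) for i in range(self.n1)}

    def length_of(self, index: int) -> int:
        """Read length of the read at ``index`` (handles mixed-length PE)."""
        if self.paired and index >= self.n1:
            return self.read_length2  # type: ignore[return-value]
        return self.read_length


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_sequences(path) -> Iterator[str]:
    with _open_text(path) as handle:
        count = 0
        try:
            for _title, seq, _qual in FastqGeneralIterator(handle):
                yield seq.upper()
                count += 1
        except ValueError as exc:  # biopython signals truncated/odd records
            raise FastqFormatError(
                f"{path}: malformed FASTQ near record {count + 1}: {exc}"
            ) from exc


def read_fastq(path) -> ReadSet:
    """Parse a single-end FASTQ file (optionally gzipped) into a ReadSet.

    Raises
    ------
    FastqFormatError
        If a record is malformed, a sequence contains characters outside
        ``{A, C, G, T, N}``, or the reads do not all share one length.
    """
    sequences: list[str] = []
    length: Optional[int] = None
    for i, seq in enumerate(_iter_sequences(path)):
        if not set(seq) <= _VALID:
            bad = sorted(set(seq) - _VALID)
            raise FastqFormatError(
                f"{path}: record {i + 1} contains non-ACGTN characters {bad}"
            )
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise FastqFormatError(
                f"{path}: record {i + 1} has length {len(seq)}, expected {length}"
            )
        sequences.append(seq)
    rs = ReadSet(sequences=sequences, read_length=length or 0)
    rs.n1 = len(sequences)
    return rs


def concat_paired(path1, path2) -> ReadSet:
    """Vertically concatenate two paired-end FASTQ files.

    The mate files must contain equal record counts; their read lengths may
    differ (both are recorded).
    """
    rs1 = read_fastq(path1)
    rs2 = read_fastq(path2)
    if rs1.origin_count != rs2.origin_count:
        raise FastqFormatError(
            f"paired-end record counts differ: {rs1.origin_count} in {path1} "
            f"vs {rs2.origin_count} in {path2}"
        )
    return ReadSet(
        sequences=rs1.sequences + rs2.sequences,
        read_length=rs1.read_length,
        read_length2=rs2.read_length,
        n1=rs1.origin_count,
    )


def write_fastq(reads: ReadSet, path, path2=None) -> None:
    """Write sequences as 4-line FASTQ records with synthetic headers.

    For a paired ReadSet, file-1 reads go to ``path`` and file-2 reads to
    ``path2`` (required in that case).
    """
    if reads.paired:
        if path2 is None:
            raise ValueError("paired ReadSet requires two output paths")
        groups = [
            (path, reads.sequences[: reads.n1]),
            (path2, reads.sequences[reads.n1 :]),
        ]
    else:
        groups = [(path, reads.sequences)]
    for out_path, seqs in groups:
        with _open_text(out_path, "wt") as out:
            for i, seq in enumerate(seqs):
                out.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
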