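"""Shared sequence records and FASTQ/FASTA input-output.

All FASTQ handling assumes 4-line records with Phred+33 quality encoding.
Files ending in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (case preserved)."""
    return sequence.translate(_RC_TABLE)[::-1]


def phred_to_error_prob(qchar: str) -> float:
    """Error probability encoded by a single Phred+33 character."""
    return 10.0 ** (-(ord(qchar) - PHRED_OFFSET) / 10.0)


@dataclass
class Read:
    """A single sequencing read: identifier, bases and Phred+33 qualities."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A forward/reverse read pair, optionally assigned to a sample."""

    forward: Read
    reverse: Read
    sample: str | None = None


@dataclass
class JoinedSequence:
    """Forward read + pad + reverse-complemented reverse read.

    ``layout`` holds the three half-open index ranges (forward, pad,
    reverse-complement part) within ``sequence``.
    """

    sample: str | None
    sequence: str
    quality: str
    layout: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = field(
        default=((0, 0), (0, 0), (0, 0))
    )

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("joined sequence/quality length mismatch")


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    with open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield Read(id=title.split()[0], sequence=seq, quality=qual)


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    n = 0
    with open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Iterate paired FASTQ files in lock-step.

    Raises if the two files have different numbers of records.
    """
    _SENTINEL = object()
    it1, it2 = read_fastq(path1), read_fastq(path2)
    from itertools import zip_longest

    for fwd, rev in zip_longest(it1, it2, fillvalue=_SENTINEL):
        if fwd is _SENTINEL or rev is _SENTINEL:
            raise ValueError("paired FASTQ files have unequal record counts")
        yield ReadPair(forward=fwd, reverse=rev)  # type: ignore[arg-type]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (full header, sequence) tuples from a FASTA file."""
    with open_text(path) as handle:
        yield from SimpleFastaParser(handle)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 0) -> int:
    """Write (name, sequence) records; ``width`` > 0 wraps lines."""
    n = 0
    with open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            if width > 0:
                for i in range(0, len(seq), width):
                    handle.write(seq[i : i + width] + "\n")
            else:
                handle.write(seq + "\n")
            n += 1
    return n
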