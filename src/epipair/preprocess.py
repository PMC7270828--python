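"""Demultiplexing, trimming, joining, quality filtering, clone removal and
bisulfite conversion-rate estimation for raw paired reads.

The stages mirror a conventional GBS front end: inline barcodes on read 1
(no restriction-site check), fixed-position trimming so all samples end up
with equal-length reads, joining with an artificial pad, an expected-error
rate filter, and PCR-clone removal keyed on degenerate wobble bases at the
start of read 2.  Stream order is preserved throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .io import JoinedSequence, Read, ReadPair, phred_to_error_prob, reverse_complement

DEFAULT_STRIP_FORWARD = 4
DEFAULT_STRIP_REVERSE = 14
DEFAULT_TRUNCATE = 86
DEFAULT_PADGAP = "ATATATAT"
DEFAULT_PAD_QUALITY = 40
DEFAULT_MAXEE_RATE = 0.01
DEFAULT_CHECK_INDEX = 12


def load_barcode_table(path: str | Path) -> dict[str, str]:
    """Read a headerless ``sample<TAB>barcode`` TSV."""
    table: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, barcode = line.split("\t")[:2]
            table[sample] = barcode.upper()
    _validate_barcode_table(table)
    return table


def _validate_barcode_table(table: Mapping[str, str]) -> None:
    if not table:
        raise ValueError("empty barcode table")
    seen: dict[str, str] = {}
    for sample, barcode in table.items():
        if barcode in seen:
            raise ValueError(
                f"duplicate barcode {barcode!r} for samples {seen[barcode]!r} and {sample!r}"
            )
        seen[barcode] = sample


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_barcode(
    sequence: str, table: Mapping[str, str], max_mismatches: int = 1
) -> str | None:
    """Match the start of ``sequence`` against every barcode.

    The best (lowest Hamming distance) barcode wins if within
    ``max_mismatches``; among equal-distance candidates the longest
    barcode wins, and a remaining tie is ambiguous (returns None).
    N in the read counts as a mismatch.
    """
    best: list[tuple[int, int, str]] = []  # (distance, length, sample)
    for sample, barcode in table.items():
        if len(sequence) < len(barcode):
            continue
        d = _hamming(sequence[: len(barcode)], barcode)
        if d <= max_mismatches:
            best.append((d, len(barcode), sample))
    if not best:
        return None
    best_d = min(d for d, _, _ in best)
    at_best = [(ln, s) for d, ln, s in best if d == best_d]
    max_len = max(ln for ln, _ in at_best)
    longest = [s for ln, s in at_best if ln == max_len]
    if len(longest) != 1:
        return None
    return longest[0]


@dataclass
class DemuxResult:
    by_sample: dict[str, list[ReadPair]]
    unassigned: int = 0

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(p) for s, p in self.by_sample.items()}


def demultiplex(
    pairs: Iterable[ReadPair],
    table: Mapping[str, str],
    max_mismatches: int = 1,
) -> DemuxResult:
    """Assign each pair to a sample by its read-1 barcode prefix and strip
    the barcode from read 1 (sequence and quality).  No restriction-site
    remnant check is performed."""
    _validate_barcode_table(table)
    result = DemuxResult(by_sample={s: [] for s in table})
    for pair in pairs:
        sample = assign_barcode(pair.forward.sequence, table, max_mismatches)
        if sample is None:
            result.unassigned += 1
            continue
        n = len(table[sample])
        fwd = Read(
            pair.forward.id,
            pair.forward.sequence[n:],
            pair.forward.quality[n:],
        )
        result.by_sample[sample].append(
            ReadPair(forward=fwd, reverse=pair.reverse, sample=sample)
        )
    return result


def trim_pair(
    pair: ReadPair,
    strip_forward: int = DEFAULT_STRIP_FORWARD,
    strip_reverse: int = DEFAULT_STRIP_REVERSE,
    truncate_to: int = DEFAULT_TRUNCATE,
) -> ReadPair | None:
    """Strip fixed adapter-derived prefixes and truncate both reads to a
    common length.  Returns None (pair dropped) if either read is too short."""
    if (
        len(pair.forward) < strip_forward + truncate_to
        or len(pair.reverse) < strip_reverse + truncate_to
    ):
        return None
    fwd = Read(
        pair.forward.id,
        pair.forward.sequence[strip_forward : strip_forward + truncate_to],
        pair.forward.quality[strip_forward : strip_forward + truncate_to],
    )
    rev = Read(
        pair.reverse.id,
        pair.reverse.sequence[strip_reverse : strip_reverse + truncate_to],
        pair.reverse.quality[strip_reverse : strip_reverse + truncate_to],
    )
    return ReadPair(forward=fwd, reverse=rev, sample=pair.sample)


def join_pair(
    pair: ReadPair,
    padgap: str = DEFAULT_PADGAP,
    pad_quality: int = DEFAULT_PAD_QUALITY,
) -> JoinedSequence:
    """Concatenate forward read + pad + reverse complement of reverse read."""
    if len(pair.forward) != len(pair.reverse):
        raise ValueError(
            f"cannot join reads of unequal lengths "
            f"({len(pair.forward)} vs {len(pair.reverse)})"
        )
    f = len(pair.forward)
    p = len(padgap)
    sequence = pair.forward.sequence + padgap + reverse_complement(pair.reverse.sequence)
    quality = (
        pair.forward.quality + chr(pad_quality + 33) * p + pair.reverse.quality[::-1]
    )
    return JoinedSequence(
        sample=pair.sample,
        sequence=sequence,
        quality=quality,
        layout=((0, f), (f, f + p), (f + p, f + p + len(pair.reverse))),
    )


def expected_errors(sequence: str, quality: str) -> float:
    """Sum of per-base error probabilities; N bases contribute 1.0."""
    if len(sequence) != len(quality):
        raise ValueError("sequence/quality length mismatch")
    total = 0.0
    for base, q in zip(sequence, quality):
        total += 1.0 if base in "Nn" else phred_to_error_prob(q)
    return total


def passes_maxee_rate(
    sequence: str, quality: str, max_rate: float = DEFAULT_MAXEE_RATE
) -> bool:
    """True iff expected errors per base are strictly below ``max_rate``."""
    if not sequence:
        raise ValueError("empty sequence")
    return expected_errors(sequence, quality) / len(sequence) < max_rate


def filter_maxee_rate(
    joined: Iterable[JoinedSequence], max_rate: float = DEFAULT_MAXEE_RATE
) -> tuple[list[JoinedSequence], int]:
    """Keep sequences passing the expected-error-rate filter; also return
    the number discarded."""
    kept, dropped = [], 0
    for js in joined:
        if passes_maxee_rate(js.sequence, js.quality, max_rate):
            kept.append(js)
        else:
            dropped += 1
    return kept, dropped


def clone_filter(
    pairs: Iterable[ReadPair], wobble_length: int = 5
) -> tuple[list[ReadPair], int]:
    """Remove PCR clones from raw (pre-trim) pairs.

    The key is (read-2 wobble prefix, read-1 sequence, rest of read 2);
    the first occurrence of each key is kept.
    """
    seen: set[tuple[str, str, str]] = set()
    kept: list[ReadPair] = []
    clones = 0
    for pair in pairs:
        key = (
            pair.reverse.sequence[:wobble_length],
            pair.forward.sequence,
            pair.reverse.sequence[wobble_length:],
        )
        if key in seen:
            clones += 1
        else:
            seen.add(key)
            kept.append(pair)
    return kept, clones


@dataclass
class ConversionStats:
    """Tally of the base observed at the adapter conversion-check position."""

    converted: int = 0  # T
    unconverted: int = 0  # C
    other: int = 0

    @property
    def examined(self) -> int:
        return self.converted + self.unconverted + self.other

    @property
    def rate(self) -> float | None:
        informative = self.converted + self.unconverted
        if informative == 0:
            return None
        return self.converted / informative


def conversion_rate(
    reverse_reads: Iterable[Read | str], check_index: int = DEFAULT_CHECK_INDEX
) -> ConversionStats:
    """Estimate bisulfite efficiency from the unmethylated adapter cytosine
    at ``check_index`` (0-based) of each raw reverse read."""
    stats = ConversionStats()
    for read in reverse_reads:
        seq = read if isinstance(read, str) else read.sequence
        if len(seq) <= check_index:
            continue
        base = seq[check_index].upper()
        if base == "T":
            stats.converted += 1
        elif base == "C":
            stats.unconverted += 1
        else:
            stats.other += 1
    return stats


@dataclass
class SampleReport:
    sample: str
    assigned: int = 0
    clones: int = 0
    trimmed: int = 0
    joined: int = 0
    passed: int = 0


@dataclass
class PreprocessResult:
    by_sample: dict[str, list[JoinedSequence]]
    reports: dict[str, SampleReport]
    unassigned: int
    input_pairs: int
    conversion: ConversionStats = field(default_factory=ConversionStats)


def run_preprocess(
    pairs: Iterable[ReadPair],
    barcode_table: Mapping[str, str],
    max_mismatches: int = 1,
    strip_forward: int = DEFAULT_STRIP_FORWARD,
    strip_reverse: int = DEFAULT_STRIP_REVERSE,
    truncate_to: int = DEFAULT_TRUNCATE,
    padgap: str = DEFAULT_PADGAP,
    pad_quality: int = DEFAULT_PAD_QUALITY,
    maxee_rate: float = DEFAULT_MAXEE_RATE,
    do_clone_filter: bool = True,
    check_index: int = DEFAULT_CHECK_INDEX,
) -> PreprocessResult:
    """Full front end: demultiplex -> (clone filter) -> trim -> join ->
    quality filter, with per-sample accounting and a conversion-rate
    estimate from the raw reverse reads."""
    pairs = list(pairs)
    conv = conversion_rate((p.reverse for p in pairs), check_index)
    demux = demultiplex(pairs, barcode_table, max_mismatches)
    by_sample: dict[str, list[JoinedSequence]] = {}
    reports: dict[str, SampleReport] = {}
    for sample, sample_pairs in demux.by_sample.items():
        report = SampleReport(sample=sample, assigned=len(sample_pairs))
        if do_clone_filter:
            sample_pairs, report.clones = clone_filter(sample_pairs)
        trimmed = [
            t
            for p in sample_pairs
            if (t := trim_pair(p, strip_forward, strip_reverse, truncate_to))
            is not None
        ]
        report.trimmed = len(trimmed)
        joined = [join_pair(t, padgap, pad_quality) for t in trimmed]
        report.joined = len(joined)
        passed, _ = filter_maxee_rate(joined, maxee_rate)
        report.passed = len(passed)
        by_sample[sample] = passed
        reports[sample] = report
    return PreprocessResult(
        by_sample=by_sample,
        reports=reports,
        unassigned=demux.unassigned,
        input_pairs=len(pairs),
        conversion=conv,
    )
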