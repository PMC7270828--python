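"""Reconstruction of pre-bisulfite fragment sequences from a catalog.

Bisulfite conversion turns a pyrimidine (C) into another pyrimidine (T),
so the purine/pyrimidine (RY) image of a sequence is conversion-invariant.
The two catalog entries derived from the two strands of one genomic
fragment therefore have RY images that are exact reverse complements of
each other.  Pairing entries on that key and comparing one entry with the
reverse complement of its partner recovers the original sequence together
with a per-position methylation call:

==========  ==========  ===========  =========================
watson      partner     base         call
==========  ==========  ===========  =========================
C           C           C            methylated C
C/T         T/C         C            unmethylated C
G           G           G            methylated C opposite
G/A         A/G         G            unmethylated C opposite
A           A           A            (no cytosine involved)
T           T           T            (no cytosine involved)
other combinations      N            conflict
==========  ==========  ===========  =========================

Reconstructed fragments are stitched into a single mock-genome record
with a boundary table mapping mock coordinates back to fragments.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalog import Catalog, Locus
from .io import reverse_complement

# methylation call labels
METH_C = "meth-C"
UNMETH_C = "unmeth-C"
OPP_METH_C = "opp-meth-C"
OPP_UNMETH_C = "opp-unmeth-C"
NONE = "none"
CONFLICT = "conflict"

DEFAULT_MAX_CONFLICT_FRACTION = 0.05
DEFAULT_MIN_OVERLAP = 10
DEFAULT_OVERLAP_MISMATCHES = 0

_RY_TABLE = str.maketrans("AGCT", "RRYY")
_RY_SWAP = str.maketrans("RY", "YR")

#: complete decode table over ordered (watson, rc-of-crick) base pairs
DECODE_TABLE: dict[tuple[str, str], tuple[str, str]] = {}
for _w in "ACGT":
    for _p in "ACGT":
        DECODE_TABLE[(_w, _p)] = ("N", CONFLICT)
DECODE_TABLE.update(
    {
        ("C", "C"): ("C", METH_C),
        ("T", "C"): ("C", UNMETH_C),
        ("C", "T"): ("C", UNMETH_C),
        ("G", "G"): ("G", OPP_METH_C),
        ("G", "A"): ("G", OPP_UNMETH_C),
        ("A", "G"): ("G", OPP_UNMETH_C),
        ("A", "A"): ("A", NONE),
        ("T", "T"): ("T", NONE),
    }
)


def ry_encode(sequence: str) -> str:
    """Purine/pyrimidine image: A,G -> R and C,T -> Y."""
    seq = sequence.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence contains bases outside A/C/G/T; RY encoding invalid")
    return seq.translate(_RY_TABLE)


def try_ry_encode(sequence: str) -> str | None:
    try:
        return ry_encode(sequence)
    except ValueError:
        return None


def partner_key(ry: str) -> str:
    """RY image of the reverse complement: swap R<->Y, then reverse."""
    return ry.translate(_RY_SWAP)[::-1]


def decode_position(w: str, p: str) -> tuple[str, str]:
    """Decode one position of (watson base, base of reverse-complemented
    crick) into (original base, methylation call)."""
    try:
        return DECODE_TABLE[(w, p)]
    except KeyError as exc:
        raise ValueError(f"invalid base pair ({w!r}, {p!r})") from exc


def decode_pair(watson: str, crick: str) -> tuple[str, list[str], int]:
    """Decode a full watson/crick consensus pair.

    Returns (reconstructed sequence, per-position calls, conflict count);
    conflict positions become N.
    """
    if len(watson) != len(crick):
        raise ValueError("watson/crick length mismatch")
    rc = reverse_complement(crick)
    bases: list[str] = []
    calls: list[str] = []
    conflicts = 0
    for w, p in zip(watson, rc):
        base, call = decode_position(w, p)
        if call == CONFLICT:
            conflicts += 1
        bases.append(base)
        calls.append(call)
    return "".join(bases), calls, conflicts


@dataclass
class LocusPair:
    watson: Locus
    crick: Locus
    conflicts: int

    def __post_init__(self) -> None:
        if self.watson is self.crick:
            raise ValueError("a locus cannot pair with itself")
        if len(self.watson.consensus) != len(self.crick.consensus):
            raise ValueError("paired loci must have equal length")


def find_pairs(
    catalog: Catalog,
    max_conflict_fraction: float = DEFAULT_MAX_CONFLICT_FRACTION,
) -> tuple[list[LocusPair], list[Locus]]:
    """Pair each catalog locus with the locus whose RY image is the
    reverse complement of its own.

    Loci are visited in catalog order; among candidate partners the one
    with the fewest decode conflicts wins (ties: lowest line index).
    Pairs whose conflict fraction exceeds ``max_conflict_fraction`` are
    rejected.  Within a pair the member with the lower line index is
    designated Watson.
    """
    loci = catalog.loci
    buckets: dict[str, list[int]] = defaultdict(list)
    ry_images: list[str | None] = []
    for i, locus in enumerate(loci):
        ry = try_ry_encode(locus.consensus)
        ry_images.append(ry)
        if ry is not None:
            buckets[ry].append(i)

    paired: set[int] = set()
    pairs: list[LocusPair] = []
    for i, locus in enumerate(loci):
        if i in paired or ry_images[i] is None:
            continue
        key = partner_key(ry_images[i])
        candidates = [
            j for j in buckets.get(key, []) if j != i and j not in paired
        ]
        if not candidates:
            continue
        scored = []
        for j in candidates:
            _, _, conflicts = decode_pair(locus.consensus, loci[j].consensus)
            scored.append((conflicts, _line_key(loci[j], j), j))
        scored.sort()
        best_conflicts, _, best_j = scored[0]
        if best_conflicts / len(locus.consensus) > max_conflict_fraction:
            continue
        a, b = sorted((i, best_j), key=lambda k: _line_key(loci[k], k))
        pairs.append(LocusPair(watson=loci[a], crick=loci[b], conflicts=best_conflicts))
        paired.update((i, best_j))
    unpaired = [locus for i, locus in enumerate(loci) if i not in paired]
    return pairs, unpaired


def _line_key(locus: Locus, fallback: int) -> int:
    return locus.line_index if locus.line_index is not None else fallback


@dataclass
class ReconstructedFragment:
    """Decoded original sequence of a locus pair."""

    name: str
    sequence: str
    calls: list[str]
    merged: bool = False
    overlap_length: int = 0
    conflicts: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.calls):
            raise ValueError("sequence/calls length mismatch")


def reconstruct_pair(
    pair: LocusPair,
    max_conflict_fraction: float = DEFAULT_MAX_CONFLICT_FRACTION,
) -> tuple[str, list[str], int] | None:
    """Decode a pair; returns None if the conflict fraction is too high."""
    sequence, calls, conflicts = decode_pair(
        pair.watson.consensus, pair.crick.consensus
    )
    if conflicts / len(sequence) > max_conflict_fraction:
        return None
    return sequence, calls, conflicts


def strip_padgap_and_merge(
    sequence: str,
    calls: Sequence[str],
    layout: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    overlap_mismatches: int = DEFAULT_OVERLAP_MISMATCHES,
) -> tuple[str, list[str], bool, int]:
    """Remove the pad and merge overlapping forward/tail halves.

    The largest overlap k (min_overlap <= k <= |tail|) where the forward
    suffix matches the tail prefix with at most ``overlap_mismatches``
    mismatches is removed from the tail.  Returns (sequence, calls,
    merged, overlap_length).
    """
    (f0, f1), _, (t0, t1) = layout
    fwd, fwd_calls = sequence[f0:f1], list(calls[f0:f1])
    tail, tail_calls = sequence[t0:t1], list(calls[t0:t1])
    for k in range(min(len(fwd), len(tail)), min_overlap - 1, -1):
        mismatches = sum(a != b for a, b in zip(fwd[len(fwd) - k :], tail[:k]))
        if mismatches <= overlap_mismatches:
            return fwd + tail[k:], fwd_calls + tail_calls[k:], True, k
    return fwd + tail, fwd_calls + tail_calls, False, 0


def infer_layout(
    length: int, padgap: str, forward_length: int | None = None
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Layout of a joined sequence; defaults to a symmetric split around
    the pad (equal-length forward and reverse parts)."""
    p = len(padgap)
    if forward_length is None:
        if (length - p) % 2 != 0:
            raise ValueError(
                f"cannot infer layout: length {length} minus pad {p} is odd"
            )
        forward_length = (length - p) // 2
    f = forward_length
    if not 0 <= f <= length - p:
        raise ValueError("forward length inconsistent with sequence length")
    return ((0, f), (f, f + p), (f + p, length))


@dataclass
class MockGenome:
    """Concatenated reconstructed fragments plus a 1-based inclusive
    boundary table mapping mock coordinates back to fragments."""

    sequence: str
    boundaries: list[tuple[str, int, int]]
    spacer_length: int = 0


def _name_sort_key(name: str):
    try:
        return (0, int(name), name)
    except ValueError:
        return (1, 0, name)


def build_mock_genome(
    fragments: Iterable[ReconstructedFragment], spacer_length: int = 0
) -> MockGenome:
    """Concatenate fragments in name order with optional N spacers."""
    frags = sorted(fragments, key=lambda f: _name_sort_key(f.name))
    if not frags:
        raise ValueError("cannot build a mock genome from zero fragments")
    parts: list[str] = []
    boundaries: list[tuple[str, int, int]] = []
    cursor = 0
    for idx, frag in enumerate(frags):
        if idx > 0 and spacer_length > 0:
            parts.append("N" * spacer_length)
            cursor += spacer_length
        start = cursor + 1  # 1-based inclusive
        end = cursor + len(frag.sequence)
        parts.append(frag.sequence)
        boundaries.append((frag.name, start, end))
        cursor = end
    return MockGenome(
        sequence="".join(parts), boundaries=boundaries, spacer_length=spacer_length
    )


@dataclass
class ReconstructionResult:
    fragments: list[ReconstructedFragment]
    mock: MockGenome | None
    unpaired: list[Locus]
    rejected_pairs: int


def reconstruct_catalog(
    catalog: Catalog,
    padgap: str = "ATATATAT",
    forward_length: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    overlap_mismatches: int = DEFAULT_OVERLAP_MISMATCHES,
    max_conflict_fraction: float = DEFAULT_MAX_CONFLICT_FRACTION,
    spacer_length: int = 0,
) -> ReconstructionResult:
    """Full reconstruction stage: pair, decode, strip pad/merge, stitch.

    Fragment names are the catalog line index (0-based record index) of
    the pair's first-encountered member.
    """
    pairs, unpaired = find_pairs(catalog, max_conflict_fraction)
    fragments: list[ReconstructedFragment] = []
    rejected = 0
    for pair in pairs:
        decoded = reconstruct_pair(pair, max_conflict_fraction)
        if decoded is None:
            rejected += 1
            continue
        sequence, calls, conflicts = decoded
        layout = infer_layout(len(sequence), padgap, forward_length)
        merged_seq, merged_calls, merged, overlap = strip_padgap_and_merge(
            sequence, calls, layout, min_overlap, overlap_mismatches
        )
        fragments.append(
            ReconstructedFragment(
                name=str(_line_key(pair.watson, 0)),
                sequence=merged_seq,
                calls=merged_calls,
                merged=merged,
                overlap_length=overlap,
                conflicts=conflicts,
            )
        )
    mock = build_mock_genome(fragments, spacer_length) if fragments else None
    return ReconstructionResult(
        fragments=fragments, mock=mock, unpaired=unpaired, rejected_pairs=rejected
    )
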