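"""Map mock-genome positions back to reconstructed fragments.

Positions (e.g. differentially methylated cytosines reported by an
external caller against the mock genome) are resolved to the owning
fragment and a 1-based offset within it via the boundary table.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class PositionHit:
    """Resolution of one mock-genome coordinate.

    ``fragment`` is None for positions inside spacers or outside the mock
    genome; ``offset`` is 1-based within the fragment.
    """

    position: int
    fragment: str | None
    offset: int | None


def load_positions(path: str | Path, column: int = 2) -> list[int]:
    """Read 1-based integer positions from the given 1-based column of a
    whitespace/tab-separated table; a non-numeric first line is treated
    as a header and skipped."""
    if column < 1:
        raise ValueError("column is 1-based")
    positions: list[int] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle):
            line = line.strip()
            if not line:
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < column:
                raise ValueError(
                    f"line {lineno + 1}: expected at least {column} columns"
                )
            token = fields[column - 1].strip('"')
            try:
                positions.append(int(token))
            except ValueError:
                if lineno == 0:  # header
                    continue
                raise ValueError(
                    f"line {lineno + 1}: non-integer position {token!r}"
                ) from None
    return positions


def validate_boundaries(boundaries: Sequence[tuple[str, int, int]]) -> None:
    prev_end = 0
    for name, start, end in boundaries:
        if start > end:
            raise ValueError(f"boundary {name!r}: start {start} > end {end}")
        if start <= prev_end:
            raise ValueError(
                f"boundary table not sorted/disjoint at fragment {name!r}"
            )
        prev_end = end


def seek_fragments(
    positions: Iterable[int], boundaries: Sequence[tuple[str, int, int]]
) -> list[PositionHit]:
    """Resolve each 1-based position to its fragment by interval search;
    output order follows input order."""
    boundaries = list(boundaries)
    validate_boundaries(boundaries)
    starts = [b[1] for b in boundaries]
    hits: list[PositionHit] = []
    for pos in positions:
        idx = bisect.bisect_right(starts, pos) - 1
        if idx >= 0:
            name, start, end = boundaries[idx]
            if start <= pos <= end:
                hits.append(PositionHit(pos, name, pos - start + 1))
                continue
        hits.append(PositionHit(pos, None, None))
    return hits


def read_boundaries_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a boundary table with at least (name, start, end) columns;
    a header line is detected and skipped."""
    rows: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno + 1}: expected >= 3 columns")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError:
                if lineno == 0:
                    continue
                raise
    return rows
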