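"""Per-sample locus stacking and cross-sample catalog construction.

A deliberately simplified functional stand-in for the ustacks/cstacks
stage: reads are dereplicated into exact-match stacks, nearby stacks are
merged into per-sample loci, and sample loci are folded into a catalog of
consensus sequences allowing a configurable number of mismatches.  Real
Stacks v2 ``catalog.fa``/``catalog.fa.gz`` files are accepted as an
alternative entry point.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import JoinedSequence, open_text, read_fasta, write_fasta

DEFAULT_MIN_DEPTH = 3
DEFAULT_MERGE_MISMATCHES = 2
DEFAULT_CATALOG_MISMATCHES = 4


@dataclass
class Locus:
    """A consensus sequence with its supporting depth and member samples."""

    consensus: str
    depth: int
    samples: set[str] = field(default_factory=set)
    line_index: int | None = None  # 0-based record index in the catalog file
    locus_id: int | None = None


@dataclass
class Catalog:
    loci: list[Locus]
    min_depth: int = DEFAULT_MIN_DEPTH
    merge_mismatches: int = DEFAULT_MERGE_MISMATCHES
    catalog_mismatches: int = DEFAULT_CATALOG_MISMATCHES

    def __len__(self) -> int:
        return len(self.loci)


def _as_sequences(items: Iterable[JoinedSequence | str]) -> list[str]:
    return [i.sequence if isinstance(i, JoinedSequence) else i for i in items]


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_stacks(
    sequences: Iterable[JoinedSequence | str],
    min_depth: int = DEFAULT_MIN_DEPTH,
    merge_mismatches: int = DEFAULT_MERGE_MISMATCHES,
) -> list[Locus]:
    """Collapse equal-length sequences of one sample into loci.

    Exact-match stacks with depth >= ``min_depth`` become primary; primary
    stacks within ``merge_mismatches`` of each other merge by single
    linkage, taking a depth-weighted per-position majority consensus (ties
    broken by the deepest stack).  Shallower stacks are absorbed by a
    unique matching locus (adding depth only) or discarded.
    """
    seqs = _as_sequences(sequences)
    if not seqs:
        return []
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all sequences must have equal length")

    counts = Counter(seqs)
    # stable order: by first appearance
    order: dict[str, int] = {}
    for s in seqs:
        if s not in order:
            order[s] = len(order)
    stacks = sorted(counts.items(), key=lambda kv: order[kv[0]])
    primary = [(s, d) for s, d in stacks if d >= min_depth]
    secondary = [(s, d) for s, d in stacks if d < min_depth]

    # single-linkage clustering of primary stacks
    n = len(primary)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if n > 1:
        mat = _seq_matrix([s for s, _ in primary])
        for i in range(n):
            dists = np.count_nonzero(mat[i + 1 :] != mat[i], axis=1)
            for off in np.nonzero(dists <= merge_mismatches)[0]:
                union(i, i + 1 + int(off))

    clusters: dict[int, list[tuple[str, int]]] = {}
    for i, (s, d) in enumerate(primary):
        clusters.setdefault(find(i), []).append((s, d))

    loci: list[Locus] = []
    primary_to_locus: dict[str, Locus] = {}
    for root in sorted(clusters):
        members = clusters[root]
        if len(members) == 1:
            consensus = members[0][0]
        else:
            consensus = _weighted_consensus(members)
        locus = Locus(consensus=consensus, depth=sum(d for _, d in members))
        loci.append(locus)
        for s, _ in members:
            primary_to_locus[s] = locus

    # absorb sub-threshold stacks into a unique matching locus
    for s, d in secondary:
        hits = {
            id(locus): locus
            for ps, locus in primary_to_locus.items()
            if _hamming(ps, s) <= merge_mismatches
        }
        if len(hits) == 1:
            next(iter(hits.values())).depth += d
    return loci


def _weighted_consensus(members: list[tuple[str, int]]) -> str:
    """Depth-weighted per-position majority; ties take the deepest stack's base."""
    deepest = max(members, key=lambda m: m[1])[0]
    length = len(members[0][0])
    out = []
    for i in range(length):
        weights: Counter[str] = Counter()
        for s, d in members:
            weights[s[i]] += d
        best = max(weights.values())
        winners = [b for b, w in weights.items() if w == best]
        out.append(deepest[i] if len(winners) > 1 else winners[0])
    return "".join(out)


def build_catalog(
    per_sample_loci: Iterable[tuple[str, Sequence[Locus]]],
    catalog_mismatches: int = DEFAULT_CATALOG_MISMATCHES,
    min_depth: int = DEFAULT_MIN_DEPTH,
    merge_mismatches: int = DEFAULT_MERGE_MISMATCHES,
) -> Catalog:
    """Fold per-sample loci into a catalog, processing samples in input
    order.  A sample locus joins its unique nearest entry within
    ``catalog_mismatches`` (the entry keeps its consensus and gains the
    sample); equal-distance ties go to the earliest-founded entry;
    otherwise it founds a new entry."""
    entries: list[Locus] = []
    for sample, loci in per_sample_loci:
        for locus in loci:
            target = None
            if entries:
                if any(len(e.consensus) != len(locus.consensus) for e in entries):
                    raise ValueError("catalog loci must all have equal length")
                mat = _seq_matrix([e.consensus for e in entries])
                q = _seq_matrix([locus.consensus])[0]
                dists = np.count_nonzero(mat != q, axis=1)
                best = int(dists.min())
                if best <= catalog_mismatches:
                    target = entries[int(np.argmin(dists))]  # earliest-founded on ties
            if target is None:
                entries.append(
                    Locus(
                        consensus=locus.consensus,
                        depth=locus.depth,
                        samples={sample},
                    )
                )
            else:
                target.depth += locus.depth
                target.samples.add(sample)
    for i, entry in enumerate(entries):
        entry.line_index = i
        entry.locus_id = i + 1
    return Catalog(
        loci=entries,
        min_depth=min_depth,
        merge_mismatches=merge_mismatches,
        catalog_mismatches=catalog_mismatches,
    )


def write_catalog_fasta(catalog: Catalog, path: str | Path) -> None:
    """One record per locus, header ``>{integer id}``."""
    write_fasta(
        (
            (str(l.locus_id if l.locus_id is not None else i + 1), l.consensus)
            for i, l in enumerate(catalog.loci)
        ),
        path,
    )


def read_catalog_fasta(path: str | Path) -> Catalog:
    """Read our own catalog files or a Stacks v2 ``catalog.fa``(.gz).

    The header token before the first whitespace is the locus id; each
    consensus records its 0-based record index as ``line_index``.
    """
    loci: list[Locus] = []
    seen_ids: set[int] = set()
    for index, (header, seq) in enumerate(read_fasta(path)):
        token = header.split()[0] if header.split() else ""
        try:
            locus_id = int(token)
        except ValueError as exc:
            raise ValueError(f"malformed catalog header {header!r}") from exc
        if locus_id in seen_ids:
            raise ValueError(f"duplicate locus id {locus_id}")
        seen_ids.add(locus_id)
        if not seq:
            raise ValueError(f"empty sequence for locus {locus_id}")
        loci.append(
            Locus(
                consensus=seq.upper(),
                depth=0,
                line_index=index,
                locus_id=locus_id,
            )
        )
    return Catalog(loci=loci)
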