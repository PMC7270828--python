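"""Forward model of a single-enzyme bisulfite GBS library.

Generates paired FASTQ reads with full ground truth (fragment sequences,
per-strand methylation states, per-read provenance), plus an in-silico
restriction digestion utility used both to derive fragments from a genome
and to count expected fragments per size range.

Library geometry
----------------
Each genomic fragment is inserted in two orientations between a barcoded
P1 adapter and a wobble-carrying common P2 adapter.  Read 1 starts with
the sample barcode followed by the 4-base restriction overhang remnant
(``TGCA``) and then the bisulfite image of the sequenced strand from its
5' end.  Read 2 starts with 5 wobble bases and a 9-base adapter remnant
(``AACTGTGCA``) whose final cytosine (raw-read index 12) is the
unmethylated conversion-check position, followed by the reverse
complement of the same bisulfite strand from its 3' end.  Orientation "A"
sequences the converted top strand of the fragment, orientation "B" the
converted bottom strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Read, ReadPair, reverse_complement

PSTI_SITE = "CTGCAG"
PSTI_CUT_OFFSET = 5  # CTGCA^G

#: restriction-overhang remnant at the start of the genomic part of read 1
R1_OVERHANG = "TGCA"
#: adapter remnant on raw read 2 after the 5 wobble bases
R2_ADAPTER = "AACTGTGCA"
#: 0-based index (within R2_ADAPTER) of the always-methylated cytosine
R2_METH_C = 2
#: 0-based index (within R2_ADAPTER) of the unmethylated conversion-check C
R2_CHECK_C = 7
WOBBLE_LENGTH = 5
WOBBLE_ALPHABET = "AGT"  # IUPAC D

TOP = "top"
BOTTOM = "bottom"


# ---------------------------------------------------------------------------
# genome generation and digestion
# ---------------------------------------------------------------------------

def generate_genome(length: int, gc_fraction: float, seed: int) -> str:
    """Random genome of the given length and expected GC content."""
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[at, gc, gc, at])
    return bases.tobytes().decode("ascii")


@dataclass(frozen=True)
class DigestFragment:
    """One restriction fragment on a source sequence.

    ``start``/``end`` are 0-based cut coordinates (end exclusive);
    ``internal`` is true iff the fragment is flanked by a recognition
    site on both sides (i.e. both boundaries are cuts, not sequence ends).
    """

    sequence_id: str
    start: int
    end: int
    internal: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")


def find_cut_positions(sequence: str, site: str = PSTI_SITE, cut_offset: int = PSTI_CUT_OFFSET) -> list[int]:
    """All cut coordinates: occurrence start + cut_offset, for every
    (possibly overlapping) case-insensitive occurrence of ``site``."""
    if not 0 <= cut_offset <= len(site):
        raise ValueError(f"cut_offset {cut_offset} outside site of length {len(site)}")
    seq = sequence.upper()
    needle = site.upper()
    cuts = []
    start = 0
    while True:
        i = seq.find(needle, start)
        if i < 0:
            break
        cuts.append(i + cut_offset)
        start = i + 1  # overlapping occurrences allowed
    return cuts


def digest(
    sequence: str,
    site: str = PSTI_SITE,
    cut_offset: int = PSTI_CUT_OFFSET,
    sequence_id: str = "seq",
) -> list[DigestFragment]:
    """Cut ``sequence`` at every occurrence of ``site`` and return the
    ordered, non-overlapping fragments that partition it."""
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    cuts = find_cut_positions(sequence, site, cut_offset)
    interior = sorted({c for c in cuts if 0 < c < len(sequence)})
    boundaries = [0] + interior + [len(sequence)]
    fragments = []
    cut_set = set(cuts)
    for k in range(len(boundaries) - 1):
        start, end = boundaries[k], boundaries[k + 1]
        # a flank counts as a cut even at coordinate 0 or len(sequence)
        # (site cutting exactly at a sequence end)
        left_is_cut = start in cut_set
        right_is_cut = end in cut_set
        fragments.append(
            DigestFragment(
                sequence_id=sequence_id,
                start=start,
                end=end,
                internal=left_is_cut and right_is_cut,
            )
        )
    return fragments


def digest_fasta_records(records: Iterable[tuple[str, str]], site: str = PSTI_SITE, cut_offset: int = PSTI_CUT_OFFSET) -> list[DigestFragment]:
    """Digest every record of a (name, sequence) iterable."""
    out: list[DigestFragment] = []
    for name, seq in records:
        out.extend(digest(seq, site, cut_offset, sequence_id=name.split()[0]))
    return out


def count_fragments_in_range(
    fragments: Sequence[DigestFragment],
    min_len: int,
    max_len: int,
    internal_only: bool = True,
) -> int:
    """Count fragments with length in the closed interval [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError(f"empty length range [{min_len}, {max_len}]")
    return sum(
        1
        for f in fragments
        if min_len <= f.length <= max_len and (f.internal or not internal_only)
    )


# ---------------------------------------------------------------------------
# methylation truth and bisulfite conversion
# ---------------------------------------------------------------------------

def methylation_context(sequence: str, pos: int) -> str:
    """Context (CG / CHG / CHH) of the cytosine at ``pos`` of ``sequence``.

    Cytosines too close to the 3' end to resolve their context are
    classified CHH.
    """
    if sequence[pos] != "C":
        raise ValueError(f"position {pos} is {sequence[pos]!r}, not C")
    if pos + 1 < len(sequence) and sequence[pos + 1] == "G":
        return "CG"
    if pos + 2 < len(sequence) and sequence[pos + 2] == "G":
        return "CHG"
    return "CHH"


@dataclass
class MethylTruth:
    """Ground-truth methylation state for every cytosine of every fragment,
    on both strands.  Keys are (fragment id, strand, 0-based position on
    that strand's 5'->3' sequence)."""

    states: dict[tuple[str, str, int], bool] = field(default_factory=dict)
    contexts: dict[tuple[str, str, int], str] = field(default_factory=dict)

    def strand_states(self, fragment: str, strand: str) -> dict[int, bool]:
        return {
            pos: state
            for (frag, strd, pos), state in self.states.items()
            if frag == fragment and strd == strand
        }


def assign_methylation(
    fragments: Mapping[str, str],
    p_cg: float,
    p_chg: float,
    p_chh: float,
    symmetric_cg: bool = True,
    seed: int = 0,
) -> MethylTruth:
    """Draw a methylation state for every cytosine on both strands.

    Each cytosine is methylated independently with the probability of its
    context; with ``symmetric_cg`` the two cytosines of a CpG dyad share
    a single Bernoulli draw.
    """
    for name, p in (("p_cg", p_cg), ("p_chg", p_chg), ("p_chh", p_chh)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    probs = {"CG": p_cg, "CHG": p_chg, "CHH": p_chh}
    rng = np.random.default_rng(seed)
    truth = MethylTruth()
    for frag_id in fragments:
        seq = fragments[frag_id].upper()
        strands = {TOP: seq, BOTTOM: reverse_complement(seq)}
        for strand, sseq in strands.items():
            for pos, base in enumerate(sseq):
                if base != "C":
                    continue
                ctx = methylation_context(sseq, pos)
                truth.contexts[(frag_id, strand, pos)] = ctx
                truth.states[(frag_id, strand, pos)] = bool(rng.random() < probs[ctx])
        if symmetric_cg:
            length = len(seq)
            for pos in range(length - 1):
                if seq[pos] == "C" and seq[pos + 1] == "G":
                    bottom_pos = length - 2 - pos  # bottom-strand C of the dyad
                    key_top = (frag_id, TOP, pos)
                    key_bot = (frag_id, BOTTOM, bottom_pos)
                    if key_bot in truth.states:
                        truth.states[key_bot] = truth.states[key_top]
    return truth


def bisulfite_convert(
    strand_sequence: str,
    strand_states: Mapping[int, bool],
    efficiency: float,
    failed_conversion_of_methylated: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> str:
    """Convert unmethylated cytosines to thymine with the given efficiency.

    Methylated cytosines convert with probability
    ``failed_conversion_of_methylated`` (default: never).  Non-C bases are
    untouched and the length is preserved.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = list(strand_sequence)
    for pos, base in enumerate(strand_sequence):
        if base != "C":
            continue
        if pos not in strand_states:
            raise ValueError(f"no methylation state for C at position {pos}")
        p_convert = (
            failed_conversion_of_methylated if strand_states[pos] else efficiency
        )
        if rng.random() < p_convert:
            out[pos] = "T"
    return "".join(out)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All knobs of the library simulation."""

    barcode_table: Mapping[str, str]
    genome_length: int = 100_000
    gc_fraction: float = 0.4
    recognition_site: str = PSTI_SITE
    cut_offset: int = PSTI_CUT_OFFSET
    size_min: int = 100
    size_max: int = 300
    p_cg: float = 0.3
    p_chg: float = 0.05
    p_chh: float = 0.02
    symmetric_cg: bool = True
    conversion_efficiency: float = 1.0
    failed_conversion_of_methylated: float = 0.0
    read_length: int = 100
    depth_per_orientation: int = 5
    sequencing_error_rate: float = 0.0
    base_quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.barcode_table:
            raise ValueError("barcode_table must not be empty")
        for p_name in (
            "gc_fraction",
            "p_cg",
            "p_chg",
            "p_chh",
            "conversion_efficiency",
            "failed_conversion_of_methylated",
            "sequencing_error_rate",
        ):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name} must be in [0, 1], got {p}")
        if self.size_min < self.min_fragment_length:
            raise ValueError(
                f"size_min {self.size_min} below the floor "
                f"{self.min_fragment_length} imposed by read geometry "
                "(reads must not run into the far adapter)"
            )

    @property
    def min_fragment_length(self) -> int:
        """Shortest fragment whose reads never reach the far adapter."""
        min_barcode = min(len(b) for b in self.barcode_table.values())
        return self.read_length - min_barcode - len(R1_OVERHANG)


@dataclass
class ReadProvenance:
    read_id: str
    fragment: str
    sample: str
    orientation: str  # "A" (top strand) or "B" (bottom strand)
    replicate: int


@dataclass
class SimResult:
    """Everything the simulation produced: reads plus ground truth."""

    pairs: list[ReadPair]
    fragments: dict[str, str]
    truth: MethylTruth
    provenance: list[ReadProvenance]


def _apply_errors(sequence: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return sequence
    out = list(sequence)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def simulate_library(
    config: SimConfig,
    fragments: Mapping[str, str] | None = None,
    genome: str | None = None,
) -> SimResult:
    """Simulate read pairs for every size-selected fragment, sample and
    insertion orientation, at ``depth_per_orientation`` pairs each.

    Either an explicit ``fragments`` mapping (name -> sequence) or a
    ``genome`` string may be given; with a genome, internal restriction
    fragments within the configured size range are used.  With neither,
    a random genome is generated from the config.
    """
    rng = np.random.default_rng(config.seed)
    if fragments is None:
        if genome is None:
            genome = generate_genome(
                config.genome_length, config.gc_fraction, seed=int(rng.integers(2**31))
            )
        digs = digest(genome, config.recognition_site, config.cut_offset)
        selected = [
            f
            for f in digs
            if f.internal and config.size_min <= f.length <= config.size_max
        ]
        if not selected:
            raise ValueError("no internal fragment passed size selection")
        fragments = {
            f"frag_{i:05d}": genome[f.start : f.end] for i, f in enumerate(selected)
        }
    floor = config.min_fragment_length
    for name, seq in fragments.items():
        if len(seq) < floor:
            raise ValueError(
                f"fragment {name!r} of length {len(seq)} is shorter than the "
                f"minimum {floor} required by the read geometry"
            )

    truth = assign_methylation(
        fragments,
        config.p_cg,
        config.p_chg,
        config.p_chh,
        symmetric_cg=config.symmetric_cg,
        seed=int(rng.integers(2**31)),
    )

    qual_char = chr(config.base_quality + 33)
    pairs: list[ReadPair] = []
    provenance: list[ReadProvenance] = []
    strand_names = {"A": TOP, "B": BOTTOM}
    states_by_frag: dict[tuple[str, str], dict[int, bool]] = {}
    for (frag_id, strand, pos), state in truth.states.items():
        states_by_frag.setdefault((frag_id, strand), {})[pos] = state
    for frag_id in fragments:
        seq = fragments[frag_id].upper()
        strand_seqs = {"A": seq, "B": reverse_complement(seq)}
        for sample, barcode in config.barcode_table.items():
            for orientation in ("A", "B"):
                strand_seq = strand_seqs[orientation]
                states = states_by_frag.get(
                    (frag_id, strand_names[orientation]), {}
                )
                for rep in range(config.depth_per_orientation):
                    image = bisulfite_convert(
                        strand_seq,
                        states,
                        config.conversion_efficiency,
                        config.failed_conversion_of_methylated,
                        rng=rng,
                    )
                    bio1_len = config.read_length - len(barcode) - len(R1_OVERHANG)
                    r1_seq = barcode + R1_OVERHANG + image[:bio1_len]
                    wobble = "".join(
                        WOBBLE_ALPHABET[int(rng.integers(len(WOBBLE_ALPHABET)))]
                        for _ in range(WOBBLE_LENGTH)
                    )
                    adapter = list(R2_ADAPTER)
                    if rng.random() < config.conversion_efficiency:
                        adapter[R2_CHECK_C] = "T"
                    r2_seq = (
                        wobble
                        + "".join(adapter)
                        + reverse_complement(image)[
                            : config.read_length - WOBBLE_LENGTH - len(R2_ADAPTER)
                        ]
                    )
                    r1_seq = _apply_errors(r1_seq, config.sequencing_error_rate, rng)
                    r2_seq = _apply_errors(r2_seq, config.sequencing_error_rate, rng)
                    read_id = f"{frag_id}:{sample}:{orientation}:{rep}"
                    pairs.append(
                        ReadPair(
                            forward=Read(read_id, r1_seq, qual_char * len(r1_seq)),
                            reverse=Read(read_id, r2_seq, qual_char * len(r2_seq)),
                        )
                    )
                    provenance.append(
                        ReadProvenance(read_id, frag_id, sample, orientation, rep)
                    )
    return SimResult(
        pairs=pairs, fragments=dict(fragments), truth=truth, provenance=provenance
    )
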