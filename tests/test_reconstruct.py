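from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epipair.catalog import Catalog, Locus, build_catalog, build_stacks
from epipair.io import reverse_complement
from epipair.preprocess import run_preprocess
from epipair.reconstruct import (
    CONFLICT,
    DECODE_TABLE,
    METH_C,
    NONE,
    OPP_METH_C,
    OPP_UNMETH_C,
    UNMETH_C,
    ReconstructedFragment,
    build_mock_genome,
    decode_pair,
    decode_position,
    find_pairs,
    infer_layout,
    partner_key,
    reconstruct_catalog,
    reconstruct_pair,
    ry_encode,
    strip_padgap_and_merge,
    try_ry_encode,
)
from epipair.simulate import SimConfig, assign_methylation, bisulfite_convert, simulate_library
from conftest import expected_reconstruction, random_dna, random_fragments

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestRYEncoding:
    def test_direct_mapping(self):
        assert ry_encode("GATC") == "RRYY"
        assert ry_encode("ACGT") == "RYRY"

    def test_invalid_base(self):
        with pytest.raises(ValueError):
            ry_encode("ANGT")
        assert try_ry_encode("ANGT") is None

    def test_partner_key_examples(self):
        assert partner_key("RYRY") == "RYRY"
        assert partner_key("RRRR") == "YYYY"

    @given(seq=dna)
    @settings(max_examples=200, deadline=None)
    def test_partner_key_is_ry_of_reverse_complement(self, seq):
        assert partner_key(ry_encode(seq)) == ry_encode(reverse_complement(seq))

    @given(seq=dna, eff=st.floats(0, 1), seed=st.integers(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_bisulfite_invariance(self, seq, eff, seed):
        """RY image is invariant under bisulfite conversion: the method's
        enabling property."""
        rng = np.random.default_rng(seed)
        states = {i: bool(rng.random() < 0.5) for i, b in enumerate(seq) if b == "C"}
        converted = bisulfite_convert(seq, states, efficiency=eff, seed=seed)
        assert ry_encode(converted) == ry_encode(seq)


class TestDecode:
    def test_informative_outcomes(self):
        assert decode_position("C", "C") == ("C", METH_C)
        assert decode_position("T", "C") == ("C", UNMETH_C)
        assert decode_position("C", "T") == ("C", UNMETH_C)
        assert decode_position("G", "G") == ("G", OPP_METH_C)
        assert decode_position("G", "A") == ("G", OPP_UNMETH_C)
        assert decode_position("A", "G") == ("G", OPP_UNMETH_C)
        assert decode_position("A", "A") == ("A", NONE)
        assert decode_position("T", "T") == ("T", NONE)

    def test_conflict(self):
        assert decode_position("A", "C") == ("N", CONFLICT)

    def test_totality_sixteen_pairs_eight_informative(self):
        outcomes = {(w, p): decode_position(w, p) for w in "ACGT" for p in "ACGT"}
        assert len(outcomes) == 16
        non_conflict = [k for k, (_, call) in outcomes.items() if call != CONFLICT]
        assert len(non_conflict) == 8
        conflict = [k for k, (base, call) in outcomes.items() if call == CONFLICT]
        assert all(DECODE_TABLE[k][0] == "N" for k in conflict)

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            decode_position("N", "A")

    def test_decode_pair_example(self):
        # the two bisulfite strand images of duplex "ACGT"
        seq, calls, conflicts = decode_pair("ATGT", "ATGT")
        assert seq == "ACGT"
        assert calls == [NONE, UNMETH_C, OPP_UNMETH_C, NONE]
        assert conflicts == 0

    def test_all_conflict_rejected(self):
        pair_seq = decode_pair("AAAA", "AAAA")
        assert pair_seq[0] == "NNNN"
        assert pair_seq[2] == 4
        locus_a = Locus("AAAA", 1, line_index=0)
        locus_b = Locus("AAAA", 1, line_index=1)
        from epipair.reconstruct import LocusPair

        assert reconstruct_pair(LocusPair(locus_a, locus_b, 4)) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_pair("AAAA", "AAA")


class TestFindPairs:
    def test_single_locus_unpaired(self):
        cat = Catalog(loci=[Locus("ACGT", 1, line_index=0)])
        pairs, unpaired = find_pairs(cat)
        assert pairs == []
        assert len(unpaired) == 1

    def test_two_strand_images_pair(self):
        cat = Catalog(
            loci=[Locus("ATGT", 1, line_index=0), Locus("ATGT", 1, line_index=1)]
        )
        pairs, unpaired = find_pairs(cat)
        assert len(pairs) == 1 and unpaired == []
        assert pairs[0].watson.line_index == 0  # lower line index is Watson

    def test_incompatible_loci_unpaired(self):
        cat = Catalog(
            loci=[Locus("AAAA", 1, line_index=0), Locus("CCCC", 1, line_index=1)]
        )
        pairs, unpaired = find_pairs(cat)
        # RY images: RRRR and YYYY are partners, but decoding (A,G)x4 vs...
        # rc(CCCC)=GGGG -> (A,G) everywhere -> opp-unmeth, zero conflicts
        assert len(pairs) == 1

    def test_no_ry_partner_unpaired(self):
        # ry(ACAC) = RYRY with partner key RYRY; ry(TGTG) = YRYR, so the
        # two loci are not RY-compatible and stay unpaired
        cat = Catalog(
            loci=[Locus("ACAC", 1, line_index=0), Locus("TGTG", 1, line_index=1)]
        )
        pairs, unpaired = find_pairs(cat, max_conflict_fraction=0.05)
        assert pairs == []
        assert len(unpaired) == 2

    def test_bucketed_candidates_never_conflict(self):
        """RY-compatible partners agree in RY class at every position, so
        decoding a true candidate pair can never hit the conflict branch."""
        rng = np.random.default_rng(59)
        for _ in range(50):
            s = random_dna(rng, 40)
            # any sequence whose RY image equals ry(rc(s)) position-wise
            partner = reverse_complement(s)
            _, _, conflicts = decode_pair(s, partner)
            assert conflicts == 0

    def test_invalid_ry_excluded(self):
        cat = Catalog(
            loci=[Locus("ANGT", 1, line_index=0), Locus("ACGT", 1, line_index=1)]
        )
        pairs, unpaired = find_pairs(cat)
        assert pairs == []
        assert len(unpaired) == 2

    def test_equal_conflict_tie_takes_lowest_line_index(self):
        # two equally good candidates: the earlier catalog record wins
        cat = Catalog(
            loci=[
                Locus("ATGT", 1, line_index=0),
                Locus("ATGT", 1, line_index=1),
                Locus("ATGT", 1, line_index=2),
            ]
        )
        pairs, unpaired = find_pairs(cat)
        assert pairs[0].watson.line_index == 0
        assert pairs[0].crick.line_index == 1
        assert [l.line_index for l in unpaired] == [2]


class TestStripAndMerge:
    def test_overlap_merge(self):
        # true fragment ACGTACGTACGT read as two overlapping 10-mers
        F, T = "ACGTACGTAC", "GTACGTACGT"
        seq = F + "ATATATAT" + T
        calls = [NONE] * len(seq)
        layout = ((0, 10), (10, 18), (18, 28))
        merged_seq, merged_calls, merged, k = strip_padgap_and_merge(
            seq, calls, layout, min_overlap=8
        )
        assert merged and k == 8
        assert merged_seq == "ACGTACGTACGT"
        assert len(merged_calls) == 12

    def test_no_overlap_concatenates(self):
        F, T = "A" * 10, "C" * 10
        seq = F + "ATATATAT" + T
        layout = ((0, 10), (10, 18), (18, 28))
        merged_seq, _, merged, k = strip_padgap_and_merge(
            seq, [NONE] * len(seq), layout, min_overlap=5
        )
        assert not merged and k == 0
        assert merged_seq == F + T

    def test_pad_absent_from_output(self):
        seq = "GGGGGGGGGG" + "ATATATAT" + "CCCCCCCCCC"
        layout = ((0, 10), (10, 18), (18, 28))
        out, _, _, _ = strip_padgap_and_merge(seq, [NONE] * len(seq), layout)
        assert "ATATATAT" not in out

    def test_overlap_with_mismatch_tolerance(self):
        F, T = "ACGTACGTAC", "GTACGAACGT"  # one mismatch inside the overlap
        seq = F + "ATATATAT" + T
        layout = ((0, 10), (10, 18), (18, 28))
        _, _, merged0, _ = strip_padgap_and_merge(
            seq, [NONE] * len(seq), layout, min_overlap=8, overlap_mismatches=0
        )
        _, _, merged1, k1 = strip_padgap_and_merge(
            seq, [NONE] * len(seq), layout, min_overlap=8, overlap_mismatches=1
        )
        assert not merged0
        assert merged1 and k1 == 8

    def test_infer_layout_symmetric(self):
        assert infer_layout(180, "ATATATAT") == ((0, 86), (86, 94), (94, 180))
        with pytest.raises(ValueError):
            infer_layout(181, "ATATATAT")


class TestMockGenome:
    def test_boundary_arithmetic(self):
        frags = [
            ReconstructedFragment("1", "A" * 100, [NONE] * 100),
            ReconstructedFragment("2", "C" * 120, [NONE] * 120),
            ReconstructedFragment("3", "G" * 80, [NONE] * 80),
        ]
        mock = build_mock_genome(frags, spacer_length=0)
        assert len(mock.sequence) == 300
        assert mock.boundaries == [("1", 1, 100), ("2", 101, 220), ("3", 221, 300)]

    def test_spacer(self):
        frags = [
            ReconstructedFragment("1", "A" * 100, [NONE] * 100),
            ReconstructedFragment("2", "C" * 120, [NONE] * 120),
        ]
        mock = build_mock_genome(frags, spacer_length=10)
        assert len(mock.sequence) == 230
        assert mock.boundaries[1] == ("2", 111, 230)
        assert mock.sequence[100:110] == "N" * 10

    def test_single_fragment(self):
        frag = ReconstructedFragment("7", "ACGT", [NONE] * 4)
        mock = build_mock_genome([frag])
        assert mock.sequence == "ACGT"
        assert mock.boundaries == [("7", 1, 4)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_mock_genome([])

    def test_name_order(self):
        frags = [
            ReconstructedFragment("10", "AA", [NONE] * 2),
            ReconstructedFragment("2", "CC", [NONE] * 2),
        ]
        mock = build_mock_genome(frags)
        assert [b[0] for b in mock.boundaries] == ["2", "10"]

    def test_boundary_faithfulness(self):
        rng = np.random.default_rng(47)
        frags = [
            ReconstructedFragment(str(i), random_dna(rng, int(L)), [NONE] * int(L))
            for i, L in enumerate(rng.integers(50, 200, size=30))
        ]
        by_name = {f.name: f.sequence for f in frags}
        mock = build_mock_genome(frags, spacer_length=5)
        for name, start, end in mock.boundaries:
            assert mock.sequence[start - 1 : end] == by_name[name]


@pytest.fixture(scope="module")
def pipeline(four_barcodes):
    rng = np.random.default_rng(53)
    lengths = list(rng.integers(100, 161, size=10)) + list(
        rng.integers(172, 301, size=5)
    )
    fragments = random_fragments(rng, lengths)
    config = SimConfig(
        barcode_table=four_barcodes,
        depth_per_orientation=5,
        conversion_efficiency=1.0,
        seed=54,
    )
    sim = simulate_library(config, fragments=fragments)
    pre = run_preprocess(sim.pairs, four_barcodes)
    per_sample = [(s, build_stacks(js)) for s, js in pre.by_sample.items()]
    cat = build_catalog(per_sample)
    result = reconstruct_catalog(cat)
    return fragments, sim, cat, result


class TestRoundTrip:
    """Simulate -> preprocess -> catalog -> reconstruct recovers the truth."""

    def test_catalog_has_two_entries_per_fragment(self, pipeline):
        fragments, _, cat, _ = pipeline
        assert len(cat) == 2 * len(fragments)

    def test_all_fragments_reconstructed_exactly(self, pipeline):
        fragments, _, _, result = pipeline
        expected = {expected_reconstruction(s) for s in fragments.values()}
        assert {f.sequence for f in result.fragments} == expected
        assert result.unpaired == []
        assert result.rejected_pairs == 0

    def test_merge_flags_match_geometry(self, pipeline):
        fragments, _, _, result = pipeline
        by_seq = {expected_reconstruction(s): len(s) for s in fragments.values()}
        for frag in result.fragments:
            true_len = by_seq[frag.sequence]
            assert frag.merged == (true_len < 172)

    def test_methylation_calls_match_truth(self, pipeline):
        fragments, sim, _, result = pipeline
        by_seq = {expected_reconstruction(s): (n, s) for n, s in fragments.items()}
        checked = 0
        for frag in result.fragments:
            name, S = by_seq[frag.sequence]
            L = len(S)
            for o, (base, call) in enumerate(zip(frag.sequence, frag.calls)):
                si = o if (len(frag.sequence) == L or o < 86) else L - 172 + o
                if base == "C":
                    want = (
                        METH_C if sim.truth.states[(name, "top", si)] else UNMETH_C
                    )
                elif base == "G":
                    want = (
                        OPP_METH_C
                        if sim.truth.states[(name, "bottom", L - 1 - si)]
                        else OPP_UNMETH_C
                    )
                else:
                    want = NONE
                assert call == want
                checked += 1
        assert checked > 1000

    def test_mock_genome_boundaries_recover_fragments(self, pipeline):
        _, _, _, result = pipeline
        mock = result.mock
        frag_by_name = {f.name: f.sequence for f in result.fragments}
        for name, start, end in mock.boundaries:
            assert mock.sequence[start - 1 : end] == frag_by_name[name]
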