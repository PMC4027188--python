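"""Cut maps, strand fragments, labelling and band tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transpososim.kinetic_models import (
    D,
    INTEGRATED,
    MoleculeState,
    N,
    SYNAPSED,
    U,
)
from transpososim.substrate_model import cleavage_positions
from transpososim.virtual_gel import (
    BB_ETF,
    Break,
    CutMap,
    LIN,
    OC,
    SC,
    build_cutmap,
    label_and_band,
    lane_profile,
    native_species,
    seb_band_table,
    single_strand_fragments,
    ascii_gel,
)


def walk_oracle(length, break_positions):
    """Independent fragment-length oracle: walk every nucleotide of a circular
    strand and group contiguous stretches between cut boundaries."""
    cuts = sorted(set(break_positions))
    if not cuts:
        return [length]
    frag_of = {}
    for base in range(1, length + 1):  # base i sits between boundaries i-1 and i
        # count how many cuts lie strictly before this base (boundary < base)
        k = sum(1 for c in cuts if c <= base - 1)
        frag_of[base] = k % len(cuts)
    sizes = {}
    for base, fid in frag_of.items():
        sizes[fid] = sizes.get(fid, 0) + 1
    return sorted(sizes.values())


class TestNativeSpecies:
    @pytest.mark.parametrize(
        "state,expected",
        [
            (MoleculeState(), SC),
            (MoleculeState(SYNAPSED, U, U), SC),
            (MoleculeState(SYNAPSED, N, U), OC),
            (MoleculeState(SYNAPSED, N, N), OC),
            (MoleculeState(SYNAPSED, D, N, True), LIN),
            (MoleculeState(SYNAPSED, N, D, True), LIN),
            (MoleculeState(SYNAPSED, D, D, True), BB_ETF),
            (MoleculeState(INTEGRATED, D, D, True), INTEGRATED),
        ],
    )
    def test_classification(self, state, expected):
        assert native_species(state) == expected


class TestCutMap:
    def test_uncut_state_has_no_breaks(self, wt_sub):
        cm = build_cutmap(MoleculeState(SYNAPSED, U, U), wt_sub, digest=False)
        assert cm.breaks == ()
        assert cm.circular

    def test_seb_with_nick_and_digest(self, wt_sub):
        cm = build_cutmap(
            MoleculeState(SYNAPSED, D, N, True), wt_sub, digest=True
        )
        kinds = sorted(b.kind for b in cm.breaks)
        assert kinds == [
            "nick",
            "restriction",
            "restriction",
            "transposition_cut",
            "transposition_cut",
        ]
        assert not cm.circular

    def test_break_positions_round_trip_cleavage_positions(self, wt_sub):
        cm = build_cutmap(
            MoleculeState(SYNAPSED, D, D, True), wt_sub, digest=False
        )
        expected = set()
        for end in ("left", "right"):
            for cut in cleavage_positions(wt_sub, end):
                expected.add((cut.strand, cut.position))
        assert {(b.strand, b.position) for b in cm.breaks} == expected

    def test_positions_validated(self):
        with pytest.raises(ValueError):
            CutMap(100, (Break("fwd", 200, "nick"),))


class TestFragments:
    def test_uncut_circular_strand_is_one_wrap(self):
        cm = CutMap(4000, ())
        frags = single_strand_fragments(cm)
        assert [f.length for f in frags] == [4000, 4000]
        assert all(f.circular for f in frags)

    def test_linearized_with_one_internal_nick(self):
        cm = CutMap(
            4000,
            (
                Break("fwd", 1000, "restriction"),
                Break("rev", 1000, "restriction"),
                Break("fwd", 2500, "nick"),
            ),
            circular=False,
        )
        frags = single_strand_fragments(cm)
        fwd = sorted(f.length for f in frags if f.strand == "fwd")
        rev = [f.length for f in frags if f.strand == "rev"]
        assert fwd == [1500, 2500]
        assert rev == [4000]

    @given(
        length=st.integers(100, 5000),
        cuts=st.lists(st.integers(0, 4999), max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_lengths_match_nucleotide_walk_oracle(self, length, cuts):
        cuts = [c % length for c in cuts]
        cm = CutMap(length, tuple(Break("fwd", c, "nick") for c in set(cuts)))
        frags = [f for f in single_strand_fragments(cm) if f.strand == "fwd"]
        assert sorted(f.length for f in frags) == walk_oracle(length, cuts)
        assert sum(f.length for f in frags) == length

    def test_nucleotide_conservation_per_molecule(self, wt_sub):
        for state in (
            MoleculeState(SYNAPSED, N, U),
            MoleculeState(SYNAPSED, D, N, True),
            MoleculeState(SYNAPSED, D, D, True),
        ):
            cm = build_cutmap(state, wt_sub, digest=True)
            frags = single_strand_fragments(cm)
            assert sum(f.length for f in frags) == 2 * wt_sub.total_length


class TestLabeling:
    def test_five_prime_labels_every_linear_fragment(self, wt_sub):
        cm = build_cutmap(MoleculeState(SYNAPSED, D, N, True), wt_sub, digest=True)
        frags = single_strand_fragments(cm)
        table = label_and_band(frags, "five_prime_kinase", cm.restriction_boundaries)
        assert table["intensity"].sum() == len(frags)

    def test_circular_strands_take_no_kinase_label(self):
        cm = CutMap(4000, ())
        table = label_and_band(
            single_strand_fragments(cm), "five_prime_kinase", ()
        )
        assert table["intensity"].sum() == 0

    def test_fill_in_labels_only_restriction_termini(self, wt_sub):
        cm = build_cutmap(MoleculeState(SYNAPSED, U, U), wt_sub, digest=True)
        frags = single_strand_fragments(cm)
        table = label_and_band(frags, "three_prime_fill_in", cm.restriction_boundaries)
        # both full-length strands end 3' at the restriction site
        assert table["intensity"].sum() == 2

    def test_excised_transposon_has_no_fill_in_label(self, wt_sub):
        """Both ETF termini are transposition cuts, so Klenow fill-in at
        restriction ends leaves the excised fragment unlabelled — which is
        why its strands are scored via the labelled flanking fragments."""
        cm = build_cutmap(MoleculeState(SYNAPSED, D, D, True), wt_sub, digest=False)
        frags = single_strand_fragments(cm)
        etf = [
            f
            for f in frags
            if (f.start + f.length / 2) % wt_sub.total_length < wt_sub.element_length
        ]
        table = label_and_band(etf, "three_prime_fill_in", ())
        assert table["intensity"].sum() == 0

    def test_unknown_labeling_rejected(self):
        with pytest.raises(ValueError):
            label_and_band([], "random_priming", ())


class TestSebDiagnostic:
    @pytest.mark.parametrize("cleaved_end", ["left", "right"])
    def test_three_equal_bands_with_partner_nick(self, wt_sub, cleaved_end):
        table = seb_band_table(wt_sub, cleaved_end=cleaved_end, partner_nicked=True)
        assert len(table) == 3
        assert np.allclose(table["intensity"], table["intensity"].iloc[0])

    @pytest.mark.parametrize("cleaved_end", ["left", "right"])
    def test_two_bands_without_partner_nick(self, wt_sub, cleaved_end):
        table = seb_band_table(wt_sub, cleaved_end=cleaved_end, partner_nicked=False)
        assert len(table) == 2

    def test_seb_left_and_right_resolve(self, wt_sub):
        left = seb_band_table(wt_sub, cleaved_end="left", partner_nicked=True)
        right = seb_band_table(wt_sub, cleaved_end="right", partner_nicked=True)
        assert set(left["length"]) != set(right["length"])


class TestLaneProfile:
    def test_t0_shows_only_full_length_band(self, timecourses, wt_sub):
        table = lane_profile(timecourses["constrained"], 0.0, wt_sub)
        assert len(table) == 1
        assert table["length"].iloc[0] == wt_sub.total_length

    def test_abundances_weighted_by_state_occupancy(self, timecourses, wt_sub):
        table = lane_profile(timecourses["constrained"], 900.0, wt_sub)
        # each state contributes 2 strands (plus nick products), so the molar
        # abundance across all bands is >= 2 per molecule
        assert table["molar_abundance"].sum() >= 2.0 - 1e-9

    def test_ascii_gel_renders(self, timecourses, wt_sub):
        lanes = {
            "t=0": lane_profile(timecourses["constrained"], 0.0, wt_sub),
            "t=900": lane_profile(timecourses["constrained"], 900.0, wt_sub),
        }
        art = ascii_gel(lanes)
        assert "t=0" in art and len(art.splitlines()) > 5
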