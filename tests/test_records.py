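"""Record parsing, scoring, and species-level summary statistics."""

import io
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from triturus_axial.records import (
    EmptySelectionError,
    RecordFormatError,
    RecordValidationError,
    VertebralRecord,
    expand_distribution,
    read_records,
    round_half_up,
    summarize_species,
    tally_transformations,
    thoracic_score,
    write_records,
)

CSV_HEADER = (
    "specimen_id,species,population_id,zone,cervical_state,"
    "thoracic_complete,sacral_state,asymmetry\n"
)


def make_record(**kw):
    base = dict(
        specimen_id="s1",
        species="cristatus",
        population_id="p1",
        zone="central",
        cervical_state="regular",
        thoracic_complete=15,
        sacral_state="regular",
        asymmetry="none",
    )
    base.update(kw)
    return VertebralRecord(**base)


class TestIO:
    def test_three_row_file_preserves_order(self):
        text = CSV_HEADER + (
            "a,cristatus,p1,central,regular,15,regular,none\n"
            "b,cristatus,p1,central,regular,14,regular,none\n"
            "c,marmoratus,p2,fringe,regular,12,transitional_single,left\n"
        )
        recs = read_records(io.StringIO(text))
        assert [r.specimen_id for r in recs] == ["a", "b", "c"]
        assert recs[2].sacral_state == "transitional_single"

    def test_roundtrip_is_byte_identical(self):
        text = CSV_HEADER + (
            "a,cristatus,p1,central,regular,15,regular,none\n"
            "b,marmoratus,p2,fringe,complete_to_thoracic,12,transitional_two_vertebra,right\n"
        )
        recs = read_records(io.StringIO(text))
        out = io.StringIO()
        write_records(recs, out)
        assert out.getvalue() == text

    def test_thoracic_bound_violation_names_specimen(self):
        text = CSV_HEADER + "bad1,cristatus,p1,central,regular,9,regular,none\n"
        with pytest.raises(RecordValidationError, match="bad1"):
            read_records(io.StringIO(text))

    def test_unknown_zone_is_format_error_naming_row(self):
        text = CSV_HEADER + "a,cristatus,p1,middle,regular,15,regular,none\n"
        with pytest.raises(RecordFormatError, match="row 1"):
            read_records(io.StringIO(text))

    def test_bad_header_rejected(self):
        with pytest.raises(RecordFormatError, match="header"):
            read_records(io.StringIO("x,y\n1,2\n"))


class TestRecordInvariants:
    def test_asymmetry_required_iff_transitional(self):
        with pytest.raises(RecordValidationError):
            make_record(sacral_state="transitional_single", asymmetry="none")
        with pytest.raises(RecordValidationError):
            make_record(sacral_state="regular", asymmetry="left")
        # thoracic_incomplete is not transitional: no asymmetry allowed
        with pytest.raises(RecordValidationError):
            make_record(sacral_state="thoracic_incomplete", asymmetry="right")
        make_record(sacral_state="transitional_two_vertebra", asymmetry="left")

    @pytest.mark.parametrize("count", [9, 21])
    def test_thoracic_bounds(self, count):
        with pytest.raises(RecordValidationError):
            make_record(thoracic_complete=count)


class TestScoring:
    @pytest.mark.parametrize(
        "count,sacral,asym,expected",
        [
            (12, "regular", "none", 12.0),
            (12, "transitional_single", "right", 12.5),
            (16, "transitional_two_vertebra", "left", 16.5),
            (13, "thoracic_incomplete", "none", 13.0),
        ],
    )
    def test_half_score_rule(self, count, sacral, asym, expected):
        r = make_record(thoracic_complete=count, sacral_state=sacral, asymmetry=asym)
        assert thoracic_score(r) == expected


# printed central-population values: (n, T_n, T_range, S_tr, T_var)
TABLE1_EXPECTED = {
    "marmoratus": (58, 12, 1, 6.9, 13.8),
    "pygmaeus": (55, 12, 1, 1.8, 3.6),
    "ivanbureschi": (175, 13, 2, 4.0, 10.3),
    "karelinii": (43, 13, 2, 2.3, 4.7),
    "carnifex": (66, 14, 3, 7.6, 12.1),
    "macedonicus": (67, 14, 2, 9.0, 14.9),
    "cristatus": (122, 15, 3, 4.9, 14.8),
    "dobrogicus": (57, 17, 3, 1.8, 24.6),
}


class TestSummaries:
    @pytest.mark.parametrize("species", sorted(TABLE1_EXPECTED))
    def test_all_published_species_statistics(self, table1_records, species):
        n, t_n, t_range, s_tr, t_var = TABLE1_EXPECTED[species]
        s = summarize_species(table1_records, species, zone_filter="central")
        assert s.n == n
        assert s.t_n == t_n
        assert s.t_range == t_range
        assert s.s_tr_rounded() == pytest.approx(s_tr)
        assert s.t_var_rounded() == pytest.approx(t_var)

    def test_half_score_specimens_excluded_from_tvar_numerator(self, table1_records):
        # dobrogicus: 14 of 57 non-modal *integral* specimens despite a 16.5
        # specimen whose complete count (16) is also non-modal
        s = summarize_species(table1_records, "dobrogicus")
        assert s.t_var == pytest.approx(100 * 14 / 57)
        # each record feeds at most one of the two numerators
        assert s.t_var + s.s_tr <= 100.0

    def test_hybrid_summary(self, table3_records):
        s = summarize_species(table3_records, "cristatus_x_marmoratus")
        assert (s.t_n, s.n) == (13, 68)
        assert s.t_var_rounded() == 35.3
        assert s.s_tr_rounded() == 7.4

    def test_uniform_sample_has_zero_variation(self):
        recs = expand_distribution("sp", {13.0: 9})
        s = summarize_species(recs, "sp")
        assert (s.t_var, s.s_tr, s.t_range) == (0.0, 0.0, 0)

    def test_order_invariance(self, table1_records):
        shuffled = list(table1_records)
        random.Random(3).shuffle(shuffled)
        for sp in ("cristatus", "dobrogicus"):
            a = summarize_species(table1_records, sp)
            b = summarize_species(shuffled, sp)
            assert (a.t_n, a.t_var, a.s_tr, a.t_range) == (
                b.t_n,
                b.t_var,
                b.s_tr,
                b.t_range,
            )

    def test_modal_tie_broken_small_with_warning(self, caplog):
        recs = expand_distribution("sp", {12.0: 5, 14.0: 5, 13.0: 1})
        with caplog.at_level("WARNING"):
            s = summarize_species(recs, "sp")
        assert s.t_n == 12
        assert any("tie" in m for m in caplog.messages)

    def test_empty_selection_raises(self, table1_records):
        with pytest.raises(EmptySelectionError):
            summarize_species(table1_records, "marmoratus", zone_filter="fringe")


TABLE2_EXPECTED = {
    # species: (n, any, cerv_complete, cerv_incomplete, left, right, thor_inc)
    "marmoratus": (58, 5, 0, 1, 1, 3, 0),
    "ivanbureschi": (361, 25, 1, 3, 6, 12, 3),
    "cristatus": (286, 16, 2, 1, 10, 3, 0),
}


class TestTallies:
    @pytest.mark.parametrize("species", sorted(TABLE2_EXPECTED))
    def test_published_transformation_counts(self, table2_records, species):
        n, any_, cc, ci, left, right, ti = TABLE2_EXPECTED[species]
        t = tally_transformations(table2_records, species)
        assert (
            t.n,
            t.any_transformation,
            t.cervical_complete,
            t.cervical_incomplete,
            t.sacral_left,
            t.sacral_right,
            t.thoracic_to_sacral_incomplete,
        ) == (n, any_, cc, ci, left, right, ti)

    def test_category_sum_equals_any(self, table2_records):
        from triturus_axial.tables import SPECIES_ORDER

        for sp in SPECIES_ORDER:
            t = tally_transformations(table2_records, sp)
            assert t.any_transformation == (
                t.cervical_complete
                + t.cervical_incomplete
                + t.sacral_left
                + t.sacral_right
                + t.thoracic_to_sacral_incomplete
            )

    def test_all_regular_records_tally_zero(self):
        recs = expand_distribution("sp", {13.0: 4})
        t = tally_transformations(recs, "sp")
        assert t.any_transformation == 0
        assert t.n == 4


@st.composite
def score_distributions(draw):
    ints = draw(
        st.dictionaries(
            st.integers(11, 19), st.integers(1, 40), min_size=1, max_size=5
        )
    )
    halves = draw(
        st.dictionaries(
            st.integers(11, 19), st.integers(0, 5), max_size=3
        )
    )
    dist = {float(k): v for k, v in ints.items()}
    for k, v in halves.items():
        if v:
            dist[k + 0.5] = v
    return dist


class TestExpansion:
    def test_trivial_expansion(self):
        recs = expand_distribution("sp", {12.0: 2})
        assert len(recs) == 2
        assert all(r.sacral_state == "regular" for r in recs)

    def test_cristatus_row_reproduces_printed_statistics(self):
        dist = {13.0: 1, 14.0: 6, 14.5: 1, 15.0: 98, 15.5: 5, 16.0: 11}
        recs = expand_distribution("cristatus", dist)
        s = summarize_species(recs, "cristatus")
        assert s.n == 122
        assert s.t_var_rounded() == 14.8
        assert s.s_tr_rounded() == 4.9

    def test_inconsistent_annotations_rejected(self):
        with pytest.raises(RecordFormatError):
            expand_distribution(
                "sp", {13.0: 5, 13.5: 2}, annotations={"sacral_left": 3, "sacral_right": 3}
            )

    @given(dist=score_distributions())
    def test_roundtrip_distribution_identity(self, dist):
        recs = expand_distribution("sp", dist)
        s = summarize_species(recs, "sp")
        assert s.score_distribution == dist
        assert sum(s.score_distribution.values()) == s.n == len(recs)
        assert 0.0 <= s.t_var <= 100.0
        assert 0.0 <= s.s_tr <= 100.0
        assert s.t_range >= 0


def test_round_half_up_matches_table_convention():
    assert round_half_up(14.7540983, 1) == 14.8
    assert round_half_up(0.7516394, 2) == 0.75
    assert round_half_up(2.25, 1) == 2.3  # ties go up, not to even
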