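import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forkasym as fa
from forkasym.geometry import Orientation
from forkasym.mispair import (
    BASES,
    COMPLEMENT,
    GAP,
    ROW_MISPAIRS,
    Mispair,
    substitution_row,
)
from oracles import exact_conditional_two_sided_p

SUBSTITUTIONS = [(r, a) for r in BASES for a in BASES if r != a]


class TestEnumerateMispairs:
    @pytest.mark.parametrize(
        ("ref", "alt", "via_top", "via_bottom"),
        [
            ("A", "G", "T:dG", "A:dC"),  # A:T -> G:C with A on top
            ("G", "A", "C:dA", "G:dT"),  # G:C -> A:T with G on top
            ("T", "C", "A:dC", "T:dG"),
        ],
    )
    def test_known_hypothesis_pairs(self, ref, alt, via_top, via_bottom):
        pair = fa.enumerate_mispairs(ref, alt)
        assert (str(pair.via_top), str(pair.via_bottom)) == (via_top, via_bottom)

    def test_identity_change_rejected(self):
        with pytest.raises(ValueError):
            fa.enumerate_mispairs("A", "A")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            fa.enumerate_mispairs("A", "N")

    @pytest.mark.parametrize(("ref", "alt"), SUBSTITUTIONS)
    def test_complementing_the_substitution_swaps_the_hypotheses(self, ref, alt):
        pair = fa.enumerate_mispairs(ref, alt)
        comp = fa.enumerate_mispairs(COMPLEMENT[ref], COMPLEMENT[alt])
        assert comp.via_top == pair.via_bottom
        assert comp.via_bottom == pair.via_top

    @pytest.mark.parametrize(("ref", "alt"), SUBSTITUTIONS)
    def test_hypotheses_are_complementary_and_never_watson_crick(self, ref, alt):
        pair = fa.enumerate_mispairs(ref, alt)
        assert pair.via_bottom == pair.via_top.complement()
        for mp in (pair.via_top, pair.via_bottom):
            assert COMPLEMENT[mp.template] != mp.incoming

    def test_watson_crick_pair_is_not_a_valid_mispair(self):
        with pytest.raises(ValueError):
            Mispair("A", "T")

    def test_mispair_display_round_trips(self):
        for text in ("T:dG", "ΔA"):
            assert str(Mispair.parse(text)) == text


class TestClassification:
    def _record(self, ref, alt, mclass, orientation):
        return fa.MutationRecord("ura4", 10, ref, alt, mclass, orientation)

    def test_forward_transition_attributed_to_lagging_tdg(self, roles, geometry):
        cm = fa.classify_transcribed_strand(
            self._record("A", "G", "substitution", Orientation.FORWARD), roles, geometry
        )
        assert (cm.row, str(cm.mispair), cm.role) == ("AT>GC", "T:dG", "lagging")

    def test_same_base_pair_change_in_reverse_gives_complement_and_leading(
        self, roles, geometry
    ):
        # The genomic A:T->G:C that reads A->G on the forward sense strand
        # reads T->C on the reverse sense strand.
        cm = fa.classify_transcribed_strand(
            self._record("T", "C", "substitution", Orientation.REVERSE), roles, geometry
        )
        assert (cm.row, str(cm.mispair), cm.role) == ("AT>GC", "A:dC", "leading")

    def test_template_convention_flips_mispair_and_role(self, roles, geometry):
        cm = fa.classify_transcribed_strand(
            self._record("A", "G", "substitution", Orientation.FORWARD),
            roles,
            geometry,
            convention="template",
        )
        assert (str(cm.mispair), cm.role) == ("A:dC", "leading")

    def test_single_base_deletion_classifies_as_skipped_template_base(self, roles, geometry):
        cm = fa.classify_transcribed_strand(
            self._record("T", GAP, "del1", Orientation.FORWARD), roles, geometry
        )
        assert (cm.row, str(cm.mispair), cm.role) == ("ΔAT", "ΔA", "lagging")

    @pytest.mark.parametrize("mclass", ["duplication", "deletion", "ins1", "other"])
    def test_complex_classes_are_not_classifiable(self, roles, geometry, mclass):
        ref, alt = (GAP, "A") if mclass == "ins1" else (".", ".")
        rec = fa.MutationRecord("ura4", 3, ref, alt, mclass, Orientation.FORWARD)
        with pytest.raises(fa.NotClassifiableError):
            fa.classify_transcribed_strand(rec, roles, geometry)

    def test_substitution_row_is_strand_symmetric(self):
        for ref, alt in SUBSTITUTIONS:
            assert substitution_row(ref, alt) == substitution_row(
                COMPLEMENT[ref], COMPLEMENT[alt]
            )


class TestTabulate:
    def test_single_class_catalog_lands_in_one_cell(self, roles, geometry):
        records = [
            fa.MutationRecord("ura4", i, "A", "G", "substitution", Orientation.FORWARD)
            for i in range(10)
        ]
        table = fa.tabulate(records, roles, geometry)
        assert table.count("AT>GC", "T:dG", "forward") == 10
        assert table.classified_total("forward") == 10

    def test_count_conservation_on_mixed_catalog(self, roles, geometry):
        records = [
            fa.MutationRecord("ura4", 0, "A", "G", "substitution", Orientation.FORWARD),
            fa.MutationRecord("ura4", 1, "G", "T", "substitution", Orientation.REVERSE),
            fa.MutationRecord("ura4", 2, "C", GAP, "del1", Orientation.FORWARD),
            fa.MutationRecord("ura4", 3, ".", ".", "duplication", Orientation.FORWARD),
            fa.MutationRecord("ura4", 4, GAP, "T", "ins1", Orientation.REVERSE),
            fa.MutationRecord("ura4", 5, ".", ".", "other", Orientation.REVERSE),
        ]
        table = fa.tabulate(records, roles, geometry)
        classified = sum(table.classified_total(o) for o in ("forward", "reverse"))
        unclassified = sum(table.unclassified_total(o) for o in ("forward", "reverse"))
        assert classified == 3  # two substitutions + one del1
        assert classified + unclassified == len(records)

    def test_empty_catalog_gives_empty_table(self, roles, geometry):
        table = fa.tabulate([], roles, geometry)
        assert table.total_records == 0

    def test_orientation_swap_mirrors_columns_exactly(self, mutant_table):
        swapped = mutant_table.swapped_orientations()
        for row, pair in ROW_MISPAIRS.items():
            for mp in pair:
                assert swapped.count(row, mp, "forward") == mutant_table.count(
                    row, mp, "reverse"
                )

    def test_fixture_round_trips_through_tsv(self, tmp_path, mutant_table):
        path = tmp_path / "counts.tsv"
        mutant_table.to_tsv(path)
        again = fa.MispairCountTable.from_tsv(path)
        assert again.to_frame().equals(mutant_table.to_frame())
        assert again.orientation_role == mutant_table.orientation_role


class TestBiasRatio:
    def test_forward_transition_biases_match_observed_counts(self, mutant_table):
        assert fa.bias_ratio(mutant_table, "AT>GC", "forward").value == 12.5
        assert fa.bias_ratio(mutant_table, "GC>AT", "forward").value == 3.0

    def test_reverse_gc_at_cda_excess(self, mutant_table):
        br = fa.bias_ratio(mutant_table, "GC>AT", "reverse", numerator="C:dA")
        assert br.value == pytest.approx(27 / 8)
        assert br.value >= 3.0

    def test_zero_denominator_flags_infinite(self, mutant_table):
        br = fa.bias_ratio(mutant_table, "GC>CG", "forward", numerator="G:dG")
        assert math.isinf(br.value) and br.flag == "infinite"

    def test_zero_over_zero_flags_undefined(self, mutant_table):
        br = fa.bias_ratio(mutant_table, "GC>CG", "reverse", numerator="G:dG")
        assert math.isnan(br.value) and br.flag == "undefined"

    def test_unknown_row_rejected(self, mutant_table):
        with pytest.raises(ValueError):
            fa.bias_ratio(mutant_table, "AT>XY", "forward")


def _table_2x2(a, b, c, d, row="AT>GC"):
    m1, m2 = ROW_MISPAIRS[row]
    table = fa.MispairCountTable()
    table.add(row, m1, "forward", a)
    table.add(row, m2, "forward", b)
    table.add(row, m1, "reverse", c)
    table.add(row, m2, "reverse", d)
    return table


class TestOrientationTest:
    def test_matches_enumeration_oracle_on_biased_table(self):
        res = fa.orientation_test(_table_2x2(25, 2, 4, 10), "AT>GC")
        assert res.p_value == pytest.approx(
            exact_conditional_two_sided_p(25, 2, 4, 10), rel=1e-9
        )
        assert not res.degenerate

    def test_identical_rows_show_no_association(self):
        res = fa.orientation_test(_table_2x2(7, 3, 7, 3), "AT>GC")
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)
        assert not res.haldane_corrected

    def test_zero_cell_triggers_flagged_haldane_correction(self):
        res = fa.orientation_test(_table_2x2(5, 0, 2, 6), "AT>GC")
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 6.5) / (0.5 * 2.5))

    def test_all_zero_margin_is_degenerate(self):
        res = fa.orientation_test(_table_2x2(0, 0, 3, 4), "AT>GC")
        assert res.degenerate and res.p_value == 1.0

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        res = fa.orientation_test(_table_2x2(a, b, c, d), "AT>GC")
        if res.degenerate:
            assert res.p_value == 1.0
        else:
            assert res.p_value == pytest.approx(
                exact_conditional_two_sided_p(a, b, c, d), rel=1e-9, abs=1e-12
            )


class TestAssignStrand:
    def test_observed_mutant_counts_call_lagging(self, mutant_table, prior):
        sa = fa.assign_strand(mutant_table, prior)
        assert sa.decision == "lagging"
        assert sa.log_odds > 0

    def test_orientation_swap_negates_log_odds(self, mutant_table, prior):
        sa = fa.assign_strand(mutant_table, prior)
        mirrored = fa.assign_strand(mutant_table.swapped_orientations(), prior)
        assert mirrored.log_odds == pytest.approx(-sa.log_odds)
        assert mirrored.decision == "leading"

    def test_uniform_prior_is_indeterminate(self, mutant_table):
        uniform = fa.InVitroBiasPrior(
            rates={str(m): 1.0 for pair in ROW_MISPAIRS.values() for m in pair}
        )
        assert not uniform.informative
        sa = fa.assign_strand(mutant_table, uniform)
        assert sa.decision == "indeterminate"
        assert sa.log_odds == 0.0

    def test_control_counts_are_far_less_decisive_than_mutant(
        self, mutant_table, control_table, prior
    ):
        sa_mut = fa.assign_strand(mutant_table, prior)
        sa_ctl = fa.assign_strand(control_table, prior)
        assert abs(sa_ctl.log_odds) < abs(sa_mut.log_odds) / 3
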