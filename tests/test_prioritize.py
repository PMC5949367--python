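"""Consensus voting, functional selection, and splice flags."""

import pytest
from hypothesis import given, settings, strategies as st

from exomesieve import FilterConfig, SchemaError
from exomesieve.model import (
    AnnotatedVariant,
    Consequence,
    DataError,
    PREDICTORS,
    PredictorCall,
    make_predictor_calls,
)
from exomesieve.prioritize import (
    SelectionMode,
    SelectionReason,
    consensus_damaging_count,
    select_functional_candidates,
    splice_effect,
)

PANEL = frozenset({"RINT1", "ERBB2", "NIN", "PDGFRB"})


def _variant(consequence, gene="ERBB2", count=0, ada=None, rf=None, pos=100):
    return AnnotatedVariant(
        chrom="1", pos=pos, ref="A", alt="G", gene=gene,
        consequence=consequence,
        predictor_calls=make_predictor_calls(count),
        splice_ada=ada, splice_rf=rf,
        qd=5.0, fs=1.0, depth=50, vaf=0.5,
    )


class TestConsensusVote:
    def test_five_of_six_passes_both_rules(self):
        # e.g. the RINT1 Phe321Ile vote
        vote = consensus_damaging_count(make_predictor_calls(5))
        assert vote.damaging_count == 5
        assert vote.passes_discovery and vote.passes_validation

    def test_three_of_six_passes_only_validation(self):
        # e.g. the cosegregating ERBB2 Arg188His vote
        vote = consensus_damaging_count(make_predictor_calls(3))
        assert not vote.passes_discovery and vote.passes_validation

    def test_all_missing_counts_zero(self):
        vote = consensus_damaging_count(make_predictor_calls(None))
        assert vote.damaging_count == 0 and vote.missing_count == 6
        assert not vote.passes_validation

    def test_wrong_key_count_is_schema_error(self):
        calls = make_predictor_calls(2)
        calls.pop("SIFT")
        with pytest.raises(SchemaError):
            consensus_damaging_count(calls)

    @given(st.lists(
        st.sampled_from([PredictorCall.damaging, PredictorCall.tolerated,
                         PredictorCall.missing]),
        min_size=6, max_size=6))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_discovery_rule_nests_in_validation_rule(self, calls):
        vote = consensus_damaging_count(dict(zip(PREDICTORS, calls)))
        assert vote.passes_validation or not vote.passes_discovery


class TestFunctionalSelection:
    def test_lof_selected_regardless_of_gene(self):
        # nonsense in a non-cancer gene (DNAH7-style) is still selected
        [c] = select_functional_candidates(
            [_variant(Consequence.stop_gained, gene="DNAH7")],
            PANEL, SelectionMode.unrelated,
        )
        assert c.selection_reason == SelectionReason.lof_any_gene

    def test_panel_missense_needs_four_of_six_when_unrelated(self):
        strong = _variant(Consequence.missense, count=5)
        weak = _variant(Consequence.missense, count=1, pos=101)
        selected = select_functional_candidates(
            [strong, weak], PANEL, SelectionMode.unrelated
        )
        assert [c.key for c in selected] == [strong.key]
        assert selected[0].selection_reason == SelectionReason.missense_panel_consensus

    def test_sibling_mode_waives_the_vote(self):
        # a 1-of-6 shared missense (PRDM16-style) is kept for the sisters
        weak = _variant(Consequence.missense, count=1)
        [c] = select_functional_candidates(
            [weak], PANEL, SelectionMode.sibling_shared
        )
        assert c.selection_reason == SelectionReason.sibling_shared_panel

    def test_off_panel_missense_never_selected(self):
        v = _variant(Consequence.missense, gene="NOTAPANELGENE", count=6)
        assert select_functional_candidates(
            [v], PANEL, SelectionMode.unrelated) == []

    @pytest.mark.parametrize("mode", list(SelectionMode))
    def test_inframe_indel_bypasses_vote_in_both_modes(self, mode):
        v = _variant(Consequence.inframe_indel, gene="NIN", count=None)
        [c] = select_functional_candidates([v], PANEL, mode)
        assert c.selection_reason in (
            SelectionReason.inframe_panel_consensus,
            SelectionReason.sibling_shared_panel,
        )

    def test_synonymous_never_selected(self):
        v = _variant(Consequence.synonymous, count=6)
        assert select_functional_candidates(
            [v], PANEL, SelectionMode.unrelated) == []

    def test_sibling_selection_is_superset_of_unrelated(self, small_cohort):
        variants = [v for _, v in small_cohort.annotations[:500]]
        panel = {v.gene for v in variants[:100]}
        unrelated = {c.key for c in select_functional_candidates(
            variants, panel, SelectionMode.unrelated)}
        sibling = {c.key for c in select_functional_candidates(
            variants, panel, SelectionMode.sibling_shared)}
        assert unrelated <= sibling


class TestSpliceFlag:
    @pytest.mark.parametrize("ada,rf,expected", [
        (0.95, 0.2, True),    # "and/or": one score suffices
        (None, 0.61, True),
        (0.6, 0.6, False),    # strict > at the cutoff
        (None, None, False),
    ])
    def test_disjunction_and_boundary(self, ada, rf, expected, config):
        v = _variant(Consequence.missense, ada=ada, rf=rf)
        assert splice_effect(v, config) is expected

    def test_out_of_range_score_is_error(self, config):
        v = _variant(Consequence.missense)
        v.splice_ada = 1.2
        with pytest.raises(DataError):
            splice_effect(v, config)

    def test_flag_is_annotative_not_selective(self, config):
        with_flag = _variant(Consequence.missense, count=5, ada=0.99)
        without = _variant(Consequence.missense, count=5, pos=101)
        selected = select_functional_candidates(
            [with_flag, without], PANEL, SelectionMode.unrelated, config
        )
        assert len(selected) == 2
        assert [c.splice_flag for c in selected] == [True, False]
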