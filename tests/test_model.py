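"""Variant identity, normalization, and consequence classification."""

import pytest
from hypothesis import given, settings, strategies as st

from exomesieve.model import (
    AnnotatedVariant,
    Consequence,
    DataError,
    RefWindow,
    VariantKey,
    classify_consequence,
    make_predictor_calls,
    normalize_variant,
    parse_consequence_term,
)


class TestVariantKey:
    def test_rejects_degenerate_alleles(self):
        with pytest.raises(DataError):
            VariantKey("1", 100, "A", "A")
        with pytest.raises(DataError):
            VariantKey("1", 0, "A", "G")
        with pytest.raises(DataError):
            VariantKey("1", 100, "", "G")


class TestNormalization:
    def test_already_minimal_snv_unchanged(self):
        ctx = RefWindow("chr1", 95, "GGGGCATGGGG")
        key = normalize_variant("chr1", 100, "A", "T", ctx)
        assert key == VariantKey("chr1", 100, "A", "T")

    def test_snv_without_context_is_identity(self):
        # the BRCA1 missense locus shared by the sisters
        key = normalize_variant("17", 41222968, "A", "G")
        assert key == VariantKey("17", 41222968, "A", "G")

    def test_left_alignment_in_homopolymer_run(self):
        # deleting one T from the run in ...C ATTTT G... : every spelling
        # must collapse to the leftmost anchored representation
        seq = "CATTTTG"
        ctx = RefWindow("chr1", 99, seq)  # A at 100, run TTTT at 101-104
        expected = normalize_variant("chr1", 100, "AT", "A", ctx)
        assert expected.pos == 100 and (expected.ref, expected.alt) == ("AT", "A")
        # brute-force oracle: enumerate every equivalent placement of the
        # single-T deletion and check all normalize to the same key
        for anchor in range(100, 104):
            ref = ctx.slice(anchor, anchor + 1)
            alt = ctx.base(anchor)
            assert normalize_variant("chr1", anchor, ref, alt, ctx) == expected

    def test_trailing_base_trimming(self):
        ctx = RefWindow("1", 95, "GGGGGATTTTTGG")
        # ATT>AT at 100 == delete one T
        k1 = normalize_variant("1", 100, "ATT", "AT", ctx)
        k2 = normalize_variant("1", 100, "AT", "A", ctx)
        assert k1 == k2

    def test_ref_mismatch_is_error(self):
        ctx = RefWindow("1", 95, "GGGGGATTTTTGG")
        with pytest.raises(DataError):
            normalize_variant("1", 100, "C", "G", ctx)

    @given(
        pos=st.integers(min_value=20, max_value=60),
        ins=st.text(alphabet="ACGT", min_size=1, max_size=4),
        seq=st.text(alphabet="ACGT", min_size=80, max_size=80),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_idempotence(self, pos, ins, seq):
        ctx = RefWindow("1", 1, seq)
        ref = ctx.base(pos)
        key = normalize_variant("1", pos, ref, ref + ins, ctx)
        again = normalize_variant(key.chrom, key.pos, key.ref, key.alt, ctx)
        assert again == key


class TestConsequence:
    @pytest.mark.parametrize(
        "term,hgvs,expected,lof",
        [
            # the PZP nonsense identified in two independent studies
            ("nonsense", "c.2038C>T", Consequence.stop_gained, True),
            # canonical donor site (+1)
            ("splice site", "c.34+1G>A", Consequence.splice_canonical, True),
            # canonical acceptor (-1)
            ("Splice acceptor", "c.613-1G>C", Consequence.splice_canonical, True),
            # a substitution cannot truncate
            ("Missense", "c.1984G>A", Consequence.missense, False),
            ("Frameshift", "c.226delG", Consequence.frameshift, True),
            ("in frame del", "c.1736_1738delAAG", Consequence.inframe_indel, False),
            ("frameshift ins", "c.4787dupA", Consequence.frameshift, True),
            # deep intronic offsets are splice-region, not canonical
            ("splice site", "c.100+5G>A", Consequence.other, False),
            ("completely unknown term", "", Consequence.other, False),
        ],
    )
    def test_term_parsing(self, term, hgvs, expected, lof):
        assert parse_consequence_term(term, hgvs) == expected
        v = AnnotatedVariant(chrom="1", pos=10, ref="A", alt="G",
                             consequence=expected, hgvs_c=hgvs)
        cls, is_lof = classify_consequence(v)
        assert cls == expected and is_lof == lof

    def test_classification_is_pure(self):
        v = AnnotatedVariant(chrom="1", pos=10, ref="A", alt="G",
                             consequence=Consequence.stop_gained)
        assert classify_consequence(v) == classify_consequence(v)


class TestPredictorExpansion:
    @pytest.mark.parametrize("count", [0, 3, 6])
    def test_count_roundtrip(self, count):
        calls = make_predictor_calls(count)
        assert sum(c.value == "damaging" for c in calls.values()) == count
        assert len(calls) == 6

    def test_unscored_is_all_missing(self):
        calls = make_predictor_calls(None)
        assert all(c.value == "missing" for c in calls.values())
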