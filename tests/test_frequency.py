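"""Rarity, internal-panel, and recurrence filters."""

import pytest

from exomesieve import FilterConfig, VariantKey
from exomesieve.frequency import (
    exclude_internal_panel,
    frequency_stage,
    passes_population_frequency,
    recurrence_filter,
)
from exomesieve.model import AnnotatedVariant, DataError
from exomesieve.quality import quality_stage


def _variant(freqs, subpop=None):
    return AnnotatedVariant(chrom="1", pos=100, ref="A", alt="G",
                            freqs=freqs, subpop_max_freq=subpop,
                            qd=5.0, fs=1.0, depth=50, vaf=0.5)


def _key(i):
    return VariantKey("1", i + 1, "A", "G")


class TestPopulationFrequency:
    def test_overall_rule_ignores_subpopulation_excess(self, config):
        # the recurrent ERCC1 nonsense: overall 0.002 but one
        # sub-population at 0.026 — retained under the overall rule
        v = _variant({"ExAC": 0.002, "Abraom": 0.0008}, subpop=0.02627)
        assert passes_population_frequency(v, config)

    def test_common_variant_fails(self, config):
        assert not passes_population_frequency(_variant({"ExAC": 0.02}), config)

    def test_all_missing_passes(self, config):
        v = _variant({"ExAC": None, "Abraom": None})
        assert passes_population_frequency(v, config)

    def test_frequency_outside_unit_interval_is_error(self, config):
        v = _variant({})
        object.__setattr__(v, "freqs", {"ExAC": 1.5})  # bypass constructor
        with pytest.raises(DataError):
            passes_population_frequency(v, config)

    def test_raising_maf_max_never_shrinks_survivors(self, config, rng):
        variants = [_variant({"ExAC": float(f)}) for f in rng.uniform(0, 0.05, 200)]
        keep_strict = {i for i, v in enumerate(variants)
                       if passes_population_frequency(v, config)}
        relaxed = config.with_overrides(maf_max=0.03)
        keep_relaxed = {i for i, v in enumerate(variants)
                        if passes_population_frequency(v, relaxed)}
        assert keep_strict <= keep_relaxed


class TestInternalPanel:
    def test_present_in_one_carrier_is_excluded(self):
        cands = {_key(1), _key(2)}
        assert exclude_internal_panel(cands, [{_key(1)}, set(), set()]) == {_key(2)}

    def test_set_algebra_oracle(self, rng):
        cands = {_key(int(i)) for i in rng.integers(0, 500, 200)}
        panels = [{_key(int(i)) for i in rng.integers(0, 500, 80)}
                  for _ in range(5)]
        got = exclude_internal_panel(cands, panels)
        union = set().union(*panels)
        assert got == cands - union

    def test_empty_panel_is_identity(self):
        cands = {_key(1)}
        assert exclude_internal_panel(cands, []) == cands


class TestRecurrence:
    FAMS = {"S1": "FAM1", "S2": "FAM1", "P1": None, "P2": None,
            "P3": None, "P4": None}

    def test_four_unrelated_carriers_excluded(self, config):
        k = _key(7)
        callsets = {p: {k} for p in ("P1", "P2", "P3", "P4")}
        assert recurrence_filter(callsets, self.FAMS, config) == set()

    def test_three_unrelated_retained_at_boundary(self, config):
        k = _key(7)
        callsets = {p: {k} for p in ("P1", "P2", "P3")}
        assert recurrence_filter(callsets, self.FAMS, config) == {k}

    def test_sisters_collapse_to_one_carrier(self, config):
        # both sisters + 2 unrelated = 3 relatedness units -> retained
        k = _key(7)
        callsets = {"S1": {k}, "S2": {k}, "P1": {k}, "P2": {k}}
        assert recurrence_filter(callsets, self.FAMS, config) == {k}
        # without collapsing, the same pattern counts 4 and is excluded
        no_collapse = config.with_overrides(collapse_families=False)
        assert recurrence_filter(callsets, self.FAMS, no_collapse) == set()

    def test_family_collapse_count_oracle(self, config, rng):
        patients = list(self.FAMS)
        keys = [_key(i) for i in range(30)]
        callsets = {
            p: {k for k in keys if rng.random() < 0.5} for p in patients
        }
        surviving = recurrence_filter(callsets, self.FAMS, config)
        for k in keys:
            carriers = [p for p in patients if k in callsets[p]]
            units = {self.FAMS[p] or p for p in carriers}
            assert (k in surviving) == (len(units) <= 3) or not carriers

    def test_raising_recurrence_cap_never_shrinks_survivors(self, config, rng):
        callsets = {
            p: {_key(int(i)) for i in rng.integers(0, 40, 25)}
            for p in self.FAMS
        }
        strict = recurrence_filter(callsets, self.FAMS, config)
        relaxed = recurrence_filter(
            callsets, self.FAMS, config.with_overrides(max_unrelated_recurrence=5)
        )
        assert strict <= relaxed


class TestStageCommutativity:
    def test_quality_and_frequency_commute(self, config, small_cohort):
        variants = [v for _, v in small_cohort.annotations[:400]]
        q_then_f = frequency_stage(
            quality_stage(variants, config)[0], config
        )[0]
        f_then_q = quality_stage(
            frequency_stage(variants, config)[0], config
        )[0]
        assert {v.key for v in q_then_f} == {v.key for v in f_then_q}
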