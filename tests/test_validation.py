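"""Pool screen, overlap, panel assembly, and the cohort screen."""

import numpy as np
import pytest

from exomesieve import FilterConfig, VariantKey
from exomesieve.model import AnnotatedVariant, Consequence, make_predictor_calls
from exomesieve.simulate import SimulationConfig, simulate_control_pools
from exomesieve.validation import (
    CatalogEntry,
    PoolObservation,
    PriorStudyCatalog,
    apply_confirmation_and_controls,
    assemble_candidate_panel,
    cross_study_overlap,
    detect_in_pools,
    detected_keys,
    exclude_control_positives,
    screen_independent_cohort,
)


def _key(i):
    return VariantKey("1", i + 1, "A", "G")


class TestPoolDetection:
    def test_single_het_carrier_is_detectable(self, config):
        # one heterozygote in a 5-person pool: expected VAF 1/10
        obs = PoolObservation("POOL1", _key(1), pool_vaf=0.10, pool_depth=1000)
        assert detect_in_pools(obs, config)

    def test_vaf_threshold_is_strict(self, config):
        obs = PoolObservation("POOL1", _key(1), pool_vaf=0.02, pool_depth=1000)
        assert not detect_in_pools(obs, config)

    def test_depth_threshold_is_inclusive(self, config):
        assert detect_in_pools(
            PoolObservation("P", _key(1), 0.5, 10), config)
        assert not detect_in_pools(
            PoolObservation("P", _key(1), 0.5, 9), config)

    def test_decisions_match_binomial_oracle_at_same_seed(self, config):
        keys = [_key(i) for i in range(40)]
        carriers = {k: {"POOL1": int(i % 3)} for i, k in enumerate(keys)}
        sim_cfg = SimulationConfig(seed=7, n_control_pools=1, pool_depth=1000)
        obs = simulate_control_pools(keys, carriers, sim_cfg)
        got = {o.key for o in obs if detect_in_pools(o, config)}
        # brute-force oracle: replay the identical binomial draws and
        # apply the thresholds independently
        oracle_rng = np.random.default_rng(7)
        want = set()
        for i, k in enumerate(keys):
            alleles = i % 3
            p = min(alleles / 10, 1.0)
            reads = int(oracle_rng.binomial(1000, p)) if p > 0 else 0
            if reads / 1000 > 0.02 and 1000 >= 10:
                want.add(k)
        assert got == want


class TestControlExclusion:
    def test_detected_in_one_pool_is_excluded(self, config):
        cands = {_key(1), _key(2)}
        obs = [PoolObservation("POOL3", _key(1), 0.08, 500)]
        surviving = exclude_control_positives(cands, detected_keys(obs, config))
        assert surviving == {_key(2)}

    def test_no_detections_is_identity(self):
        cands = {_key(1), _key(2)}
        assert exclude_control_positives(cands, set()) == cands

    def test_set_algebra_oracle(self, rng):
        cands = {_key(int(i)) for i in rng.integers(0, 300, 150)}
        detected = {_key(int(i)) for i in rng.integers(0, 300, 60)}
        assert exclude_control_positives(cands, detected) == cands - detected


class TestConfirmationFunnel:
    def test_discovery_bookkeeping_replay(self):
        # 208 selected; 133 tested of which 126 confirmed; 8 control
        # positives -> 193 survive (118 validated + 75 not evaluated)
        keys = [_key(i) for i in range(208)]
        result = apply_confirmation_and_controls(
            set(keys), tested=set(keys[:133]), confirmed=set(keys[:126]),
            control_positive=set(keys[:8]),
        )
        assert result.n_surviving == 193
        assert result.n_confirmation_failed == 7
        assert result.n_surviving_validated == 118
        assert result.n_surviving_untested == 75

    def test_confirmed_must_be_subset_of_tested(self):
        from exomesieve.model import DataError
        with pytest.raises(DataError):
            apply_confirmation_and_controls(
                {_key(1)}, tested=set(), confirmed={_key(1)},
                control_positive=set(),
            )


class TestCrossStudyOverlap:
    CATALOG = PriorStudyCatalog([
        CatalogEntry("PZP", "studyA", "c.2038C>T", "nonsense"),
        CatalogEntry("MSH3", "studyA", "c.162_179del", "in frame del"),
    ])

    def test_identical_variant_detected(self):
        records = cross_study_overlap(
            [("PZP", "c.2038C>T", True)], self.CATALOG
        )
        [r] = records
        assert r.identical_variant and r.lof_in_any_study

    def test_missense_only_gene_has_no_lof(self):
        [r] = cross_study_overlap(
            [("MSH3", "c.2659G>A", False)], self.CATALOG
        )
        assert not r.identical_variant and not r.lof_in_any_study

    def test_empty_catalog_gives_empty_list(self):
        assert cross_study_overlap(
            [("PZP", "c.2038C>T", True)], PriorStudyCatalog([])
        ) == []


class TestPanelAssembly:
    def test_disjoint_components_sum(self):
        panel = assemble_candidate_panel(
            {"a": ["G1", "G2"], "b": ["G3", "G4"], "c": ["G5", "G6"]}
        )
        assert len(panel) == 6

    def test_union_bounded_by_component_sum(self, rng):
        comps = {
            name: [f"G{int(i)}" for i in rng.integers(0, 30, 10)]
            for name in "abc"
        }
        panel = assemble_candidate_panel(comps)
        total = sum(len(set(c)) for c in comps.values())
        assert len(panel) <= total
        disjoint = not (set(comps["a"]) & set(comps["b"])
                        or set(comps["a"]) & set(comps["c"])
                        or set(comps["b"]) & set(comps["c"]))
        assert (len(panel) == total) == disjoint

    def test_empty_component_is_neutral(self):
        panel = assemble_candidate_panel({"a": ["G1"], "b": [], "c": ["G2"]})
        assert panel.genes == frozenset({"G1", "G2"})

    def test_provenance_keeps_every_source(self):
        panel = assemble_candidate_panel({"a": ["ROS1"], "b": ["ROS1"]})
        assert panel.provenance["ROS1"] == ["a", "b"]
        assert len(panel) == 1


class TestCohortScreen:
    def _variant(self, gene, consequence, count, maf=0.001, pos=100):
        return AnnotatedVariant(
            chrom="1", pos=pos, ref="A", alt="G", gene=gene,
            consequence=consequence,
            predictor_calls=make_predictor_calls(count),
            freqs={"ExAC": maf},
        )

    PANEL = frozenset({"ERCC1", "NOTCH2"})

    def test_two_of_six_missense_rejected(self):
        v = self._variant("NOTCH2", Consequence.missense, 2)
        hits, _ = screen_independent_cohort([("P1", v)], self.PANEL)
        assert hits == []

    def test_lof_needs_no_vote(self):
        v = self._variant("ERCC1", Consequence.stop_gained, None)
        hits, tally = screen_independent_cohort([("P1", v)], self.PANEL)
        assert len(hits) == 1 and hits[0].reason == "lof"
        assert tally == {"ERCC1": 1}

    def test_off_panel_and_common_rejected(self):
        off = self._variant("ELSEWHERE", Consequence.stop_gained, None)
        common = self._variant("NOTCH2", Consequence.missense, 6, maf=0.05,
                               pos=101)
        hits, _ = screen_independent_cohort(
            [("P1", off), ("P1", common)], self.PANEL)
        assert hits == []

    def test_lowering_consensus_threshold_grows_selection(self, config):
        cohort = [
            ("P1", self._variant("NOTCH2", Consequence.missense, c, pos=100 + c))
            for c in range(7)
        ]
        sizes = []
        for threshold in (6, 4, 2, 0):
            cfg = config.with_overrides(consensus_validation_min=threshold)
            hits, _ = screen_independent_cohort(cohort, self.PANEL, cfg)
            sizes.append(len(hits))
        assert sizes == sorted(sizes)
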