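"""Orchestration of the discovery cascade and the validation screen,
with a complete filter trace.

Stage order: quality -> frequency (population MAF, internal carrier
panel, recurrence) -> functional prioritization -> family analysis ->
confirmation/control exclusion -> cross-study overlap -> candidate
panel assembly.  The trace records, for every stage, the input count,
the exclusions per criterion, and the surviving count; conservation
(input = excluded + surviving) is asserted at every stage.  The whole
pipeline is deterministic: identical inputs give byte-identical
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .family import (
    cosegregating_keys,
    cosegregation_filter,
    novel_segregating_genes,
    shared_variants,
)
from .frequency import frequency_stage, recurrence_filter
from .model import (
    AnnotatedVariant,
    FilterConfig,
    Patient,
    RefWindow,
    StageError,
    VariantKey,
)
from .prioritize import CandidateVariant, SelectionMode, select_functional_candidates
from .quality import flag_homopolymer, intersect_platforms, quality_stage
from .validation import (
    CandidatePanel,
    FunnelResult,
    OverlapRecord,
    PriorStudyCatalog,
    apply_confirmation_and_controls,
    assemble_candidate_panel,
    cross_study_overlap,
    exclude_control_positives,
)

logger = logging.getLogger(__name__)


@dataclass
class StageTally:
    stage: str
    n_input: int
    excluded: dict[str, int]
    n_surviving: int

    def __post_init__(self) -> None:
        n_excluded = sum(self.excluded.values())
        if self.n_input != n_excluded + self.n_surviving:
            raise StageError(
                f"conservation violated at stage {self.stage}: "
                f"{self.n_input} != {n_excluded} + {self.n_surviving}"
            )


@dataclass
class FilterTrace:
    """Ordered per-stage tallies plus per-variant decision records."""

    tallies: list[StageTally] = field(default_factory=list)
    decisions: list[dict] = field(default_factory=list)

    def add_stage(self, stage: str, n_input: int, excluded: Mapping[str, int],
                  n_surviving: int) -> None:
        self.tallies.append(StageTally(stage, n_input, dict(excluded), n_surviving))

    def record(self, stage: str, key: VariantKey, verdict: str,
               reasons: Sequence[str] = ()) -> None:
        self.decisions.append({
            "stage": stage, "variant": str(key), "verdict": verdict,
            "reasons": list(reasons),
        })

    def funnel(self) -> list[dict]:
        return [
            {"stage": t.stage, "input": t.n_input, "excluded": t.excluded,
             "surviving": t.n_surviving}
            for t in self.tallies
        ]

    def to_dict(self) -> dict:
        return {"funnel": self.funnel(), "decisions": self.decisions}


@dataclass
class DiscoveryResult:
    candidates: list[tuple[str, CandidateVariant]]
    trace: FilterTrace
    shared_keys: set[VariantKey]
    cosegregating: set[VariantKey]
    novel_segregating: set[str]
    funnel: Optional[FunnelResult]
    overlap: list[OverlapRecord]
    panel: Optional[CandidatePanel]


def run_discovery_pipeline(
    annotations: Mapping[str, Sequence[AnnotatedVariant]],
    patients: Mapping[str, Patient],
    panel832: frozenset[str] | set[str],
    known_panel: frozenset[str] | set[str] = frozenset(),
    family_map: Optional[Mapping[str, Optional[str]]] = None,
    internal_callsets: Sequence[set[VariantKey]] = (),
    platform_callsets: Optional[Mapping[str, Mapping[str, set[VariantKey]]]] = None,
    relative_callsets: Optional[Mapping[str, set[VariantKey]]] = None,
    pool_detections: Optional[set[VariantKey]] = None,
    tested: Optional[set[VariantKey]] = None,
    confirmed: Optional[set[VariantKey]] = None,
    catalog: Optional[PriorStudyCatalog] = None,
    lof_cancer_genes: Sequence[str] = (),
    reference: Optional[RefWindow] = None,
    config: FilterConfig = FilterConfig(),
) -> DiscoveryResult:
    """Run the full cascade over a per-patient annotation mapping.

    Optional inputs switch on the corresponding stage: platform
    callsets enable the dual-platform intersection, relative callsets
    the cosegregation step, tested/confirmed/pool detections the
    confirmation and control-exclusion step, a catalog the overlap
    step.  Any stage failure aborts with the stage named.
    """
    if family_map is None:
        family_map = {pid: p.family_id for pid, p in patients.items()}
    trace = FilterTrace()

    # --- stage 1: quality ---------------------------------------------------
    try:
        passed_quality: dict[str, list[AnnotatedVariant]] = {}
        n_in = n_fail_metrics = n_fail_platform = n_fail_homopolymer = 0
        for pid, variants in annotations.items():
            n_in += len(variants)
            survivors, decisions = quality_stage(variants, config)
            for d in decisions:
                trace.record("quality", d.key, d.verdict, d.failed_criteria)
            n_fail_metrics += len(variants) - len(survivors)

            if platform_callsets and pid in platform_callsets:
                both = intersect_platforms(platform_callsets[pid])
                kept = [v for v in survivors if v.key in both]
                n_fail_platform += len(survivors) - len(kept)
                survivors = kept

            patient = patients.get(pid)
            single_platform = patient is not None and len(patient.platforms) == 1
            if reference is not None and (
                config.homopolymer_all_patients or single_platform
            ):
                kept = []
                for v in survivors:
                    if flag_homopolymer(v, reference, config):
                        n_fail_homopolymer += 1
                        trace.record("quality", v.key, "fail", ["homopolymer"])
                    else:
                        kept.append(v)
                survivors = kept
            passed_quality[pid] = survivors
        n_q = sum(len(v) for v in passed_quality.values())
        trace.add_stage(
            "quality", n_in,
            {"metrics": n_fail_metrics, "platform": n_fail_platform,
             "homopolymer": n_fail_homopolymer},
            n_q,
        )
    except Exception as e:  # pragma: no cover - defensive
        raise StageError(f"quality stage failed: {e}") from e

    # --- stage 2: frequency -------------------------------------------------
    try:
        callsets = {pid: {v.key for v in vs} for pid, vs in passed_quality.items()}
        surviving_recurrence = recurrence_filter(callsets, family_map, config)
        recurrent = set().union(*callsets.values()) - surviving_recurrence \
            if callsets else set()
        internal_union: set[VariantKey] = set()
        for cs in internal_callsets:
            internal_union |= cs
        passed_frequency: dict[str, list[AnnotatedVariant]] = {}
        excluded = {"population_maf": 0, "internal_panel": 0, "recurrence": 0}
        for pid, variants in passed_quality.items():
            survivors, decisions = frequency_stage(
                variants, config, internal_union, recurrent
            )
            for d in decisions:
                trace.record("frequency", d.key, d.verdict, d.failed_criteria)
                if d.failed_criteria:
                    excluded[d.failed_criteria[0]] += 1
            passed_frequency[pid] = survivors
        n_f = sum(len(v) for v in passed_frequency.values())
        trace.add_stage("frequency", n_q, excluded, n_f)
    except StageError:
        raise
    except Exception as e:
        raise StageError(f"frequency stage failed: {e}") from e

    # --- stage 3: functional prioritization ---------------------------------
    try:
        sibling_ids = [pid for pid, fam in family_map.items() if fam]
        families: dict[str, list[str]] = {}
        for pid in sibling_ids:
            families.setdefault(family_map[pid], []).append(pid)

        candidates: list[tuple[str, CandidateVariant]] = []
        shared_keys: set[VariantKey] = set()
        for fam, members in sorted(families.items()):
            member_sets = [
                {v.key for v in passed_frequency.get(pid, [])} for pid in members
            ]
            if len(member_sets) >= 2:
                shared_keys |= shared_variants(member_sets)

        for pid in sorted(passed_frequency):
            variants = passed_frequency[pid]
            if family_map.get(pid):
                mine = [v for v in variants if v.key in shared_keys]
                selected = select_functional_candidates(
                    mine, panel832, SelectionMode.sibling_shared, config
                )
            else:
                selected = select_functional_candidates(
                    variants, panel832, SelectionMode.unrelated, config
                )
            for c in selected:
                candidates.append((pid, c))
                trace.record("functional", c.key, "pass", [c.selection_reason.value])
        trace.add_stage(
            "functional", n_f,
            {"not_selected": n_f - len(candidates)}, len(candidates),
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError(f"functional stage failed: {e}") from e

    # --- stage 4: family cosegregation ---------------------------------------
    cosegregating: set[VariantKey] = set()
    novel_genes: set[str] = set()
    if relative_callsets:
        try:
            candidate_shared = {
                c.key for pid, c in candidates if family_map.get(pid)
            }
            gene_of = {c.key: c.variant.gene for _, c in candidates}
            for fam, rel_set in relative_callsets.items():
                results = cosegregation_filter(candidate_shared, rel_set)
                cosegregating |= cosegregating_keys(results)
            novel_genes = novel_segregating_genes(
                [(k, gene_of[k]) for k in cosegregating if k in gene_of],
                known_panel,
            )
            trace.add_stage(
                "cosegregation", len(candidate_shared),
                {"not_in_relative": len(candidate_shared) - len(cosegregating)},
                len(cosegregating),
            )
        except StageError:
            raise
        except Exception as e:
            raise StageError(f"cosegregation stage failed: {e}") from e

    # --- stage 5: confirmation + control exclusion --------------------------
    funnel_result: Optional[FunnelResult] = None
    candidate_keys = {c.key for _, c in candidates}
    surviving_keys = set(candidate_keys)
    if pool_detections is not None or tested is not None:
        try:
            funnel_result = apply_confirmation_and_controls(
                candidate_keys,
                tested if tested is not None else set(),
                confirmed if confirmed is not None else set(),
                pool_detections if pool_detections is not None else set(),
            )
            surviving_keys = funnel_result.surviving
            candidates = [(pid, c) for pid, c in candidates
                          if c.key in surviving_keys]
            trace.add_stage(
                "confirmation_controls", funnel_result.n_input,
                {"confirmation_failed": funnel_result.n_confirmation_failed,
                 "control_positive": funnel_result.n_input
                     - funnel_result.n_confirmation_failed
                     - funnel_result.n_surviving},
                funnel_result.n_surviving,
            )
        except StageError:
            raise
        except Exception as e:
            raise StageError(f"control stage failed: {e}") from e

    # --- stage 6: cross-study overlap ----------------------------------------
    overlap: list[OverlapRecord] = []
    if catalog is not None:
        try:
            triples = [
                (c.variant.gene, c.variant.hgvs_c, c.variant.is_lof)
                for _, c in candidates
            ]
            overlap = cross_study_overlap(triples, catalog)
        except Exception as e:
            raise StageError(f"overlap stage failed: {e}") from e

    # --- stage 7: candidate panel assembly -----------------------------------
    panel: Optional[CandidatePanel] = None
    components: dict[str, list[str]] = {}
    if novel_genes:
        components["segregating"] = sorted(novel_genes)
    if lof_cancer_genes:
        components["lof_cancer"] = list(lof_cancer_genes)
    if overlap:
        components["overlap"] = [r.gene for r in overlap]
    if components:
        panel = assemble_candidate_panel(components)

    return DiscoveryResult(
        candidates=candidates,
        trace=trace,
        shared_keys=shared_keys,
        cosegregating=cosegregating,
        novel_segregating=novel_genes,
        funnel=funnel_result,
        overlap=overlap,
        panel=panel,
    )


def run_validation_screen(
    cohort: Iterable[tuple[str, AnnotatedVariant]],
    panel: frozenset[str] | set[str],
    config: FilterConfig = FilterConfig(),
):
    """Independent-cohort screen over the candidate panel (thin wrapper
    kept for symmetry with the discovery driver)."""
    from .validation import screen_independent_cohort

    return screen_independent_cohort(cohort, panel, config)
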