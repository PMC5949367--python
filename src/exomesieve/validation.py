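"""Stages 4-6 — control screening, cross-study overlap, panel assembly,
and the independent-cohort screen.

The pooled-control screen sequences equimolar pools of five control
genomes: one heterozygous carrier in a pool contributes an expected
allele fraction of 1/(2*5) = 10%, comfortably above the 2% detection
threshold at ~1000x pool depth.  A candidate detected in any control
pool is treated as a population polymorphism and excluded, together
with candidates that failed the technical confirmation assay.

Surviving genes are compared against candidate catalogs of prior WES
studies of hereditary breast cancer, the components are merged into the
final candidate gene panel, and an independent patient cohort is
screened over that panel with the relaxed consensus rule (LOF or >= 3
of 6 damaging, MAF <= 1%).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .frequency import passes_population_frequency
from .model import (
    AnnotatedVariant,
    DataError,
    FilterConfig,
    VariantKey,
)
from .prioritize import ConsensusVote, consensus_damaging_count

# ---------------------------------------------------------------------------
# Pooled-control screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolObservation:
    """Read support for one variant in one control pool."""

    pool_id: str
    key: VariantKey
    pool_vaf: float
    pool_depth: int
    n_members: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.pool_vaf <= 1.0):
            raise DataError(f"pool VAF {self.pool_vaf} outside [0, 1]")
        if self.pool_depth < 0:
            raise DataError("pool depth must be >= 0")


def detect_in_pools(obs: PoolObservation, config: FilterConfig) -> bool:
    """Detected iff pool VAF > ``pool_vaf_min`` (strict) and pool depth
    >= ``pool_depth_min`` (inclusive)."""
    return obs.pool_vaf > config.pool_vaf_min and obs.pool_depth >= config.pool_depth_min


def detected_keys(
    observations: Iterable[PoolObservation], config: FilterConfig
) -> set[VariantKey]:
    return {o.key for o in observations if detect_in_pools(o, config)}


def exclude_control_positives(
    candidates: set[VariantKey],
    pool_detections: set[VariantKey],
) -> set[VariantKey]:
    """candidates minus variants detected in >= 1 control pool."""
    return set(candidates) - set(pool_detections)


@dataclass
class FunnelResult:
    """Bookkeeping of the confirmation + control-exclusion step."""

    surviving: set[VariantKey]
    n_input: int
    n_tested: int
    n_confirmed: int
    n_confirmation_failed: int
    n_control_positive: int
    n_surviving_validated: int
    n_surviving_untested: int

    @property
    def n_surviving(self) -> int:
        return len(self.surviving)


def apply_confirmation_and_controls(
    candidates: set[VariantKey],
    tested: set[VariantKey],
    confirmed: set[VariantKey],
    control_positive: set[VariantKey],
) -> FunnelResult:
    """Remove confirmation failures and control positives.

    A candidate survives unless it was tested and not confirmed, or it
    was detected in a control pool.  Untested candidates survive with
    status "not evaluated".
    """
    if not confirmed <= tested:
        raise DataError("confirmed variants must be a subset of tested")
    if not tested <= candidates:
        raise DataError("tested variants must be a subset of candidates")
    failed = tested - confirmed
    surviving = candidates - failed - control_positive
    return FunnelResult(
        surviving=surviving,
        n_input=len(candidates),
        n_tested=len(tested),
        n_confirmed=len(confirmed),
        n_confirmation_failed=len(failed),
        n_control_positive=len(control_positive & (candidates - failed)),
        n_surviving_validated=len((confirmed - control_positive) & surviving),
        n_surviving_untested=len(surviving - tested),
    )


# ---------------------------------------------------------------------------
# Cross-study overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    gene: str
    study: str
    hgvs_c: str
    variant_type: str  # free text; parsed with the consequence vocabulary


@dataclass
class PriorStudyCatalog:
    entries: list[CatalogEntry] = field(default_factory=list)

    def genes(self) -> set[str]:
        return {e.gene for e in self.entries}

    def by_gene(self, gene: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.gene == gene]


@dataclass
class OverlapRecord:
    gene: str
    this_study_variants: list[str]      # hgvs_c
    prior_study_variants: list[str]     # hgvs_c
    studies: list[str]
    identical_variant: bool
    lof_in_any_study: bool


def cross_study_overlap(
    candidates: Iterable[tuple[str, str, bool]],
    catalog: PriorStudyCatalog,
    prior_is_lof: Optional[Mapping[tuple[str, str], bool]] = None,
) -> list[OverlapRecord]:
    """One record per gene present in both this study and the catalog.

    ``candidates`` yields (gene, hgvs_c, is_lof) for this study's
    surviving variants.  ``prior_is_lof`` optionally overrides the LOF
    call for catalog entries keyed by (gene, hgvs_c); by default the
    catalog's free-text variant type is parsed.
    """
    from .model import LOF_CLASSES, parse_consequence_term

    ours: dict[str, list[tuple[str, bool]]] = {}
    for gene, hgvs, lof in candidates:
        ours.setdefault(gene, []).append((hgvs, lof))

    records: list[OverlapRecord] = []
    for gene in sorted(set(ours) & catalog.genes()):
        mine = ours[gene]
        theirs = catalog.by_gene(gene)
        their_lof = []
        for e in theirs:
            if prior_is_lof is not None and (gene, e.hgvs_c) in prior_is_lof:
                their_lof.append(prior_is_lof[(gene, e.hgvs_c)])
            else:
                their_lof.append(
                    parse_consequence_term(e.variant_type, e.hgvs_c) in LOF_CLASSES
                )
        mine_hgvs = [h for h, _ in mine]
        their_hgvs = [e.hgvs_c for e in theirs]
        records.append(
            OverlapRecord(
                gene=gene,
                this_study_variants=mine_hgvs,
                prior_study_variants=their_hgvs,
                studies=sorted({e.study for e in theirs}),
                identical_variant=bool(set(mine_hgvs) & set(their_hgvs)),
                lof_in_any_study=any(l for _, l in mine) or any(their_lof),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Candidate panel assembly
# ---------------------------------------------------------------------------


@dataclass
class CandidatePanel:
    """Deduplicated union of component gene lists with provenance."""

    genes: frozenset[str]
    provenance: dict[str, list[str]]  # gene -> component names

    def __len__(self) -> int:
        return len(self.genes)


def assemble_candidate_panel(
    components: Mapping[str, Iterable[str]],
) -> CandidatePanel:
    """Union the named component lists (e.g. segregating genes, LOF
    cancer genes, cross-study overlap genes); a gene may carry more
    than one source."""
    provenance: dict[str, list[str]] = {}
    for name, genes in components.items():
        for g in genes:
            provenance.setdefault(g, [])
            if name not in provenance[g]:
                provenance[g].append(name)
    return CandidatePanel(genes=frozenset(provenance), provenance=provenance)


# ---------------------------------------------------------------------------
# Independent-cohort screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenHit:
    patient_id: str
    variant: AnnotatedVariant
    vote: ConsensusVote
    reason: str  # "lof" | "consensus"


def screen_independent_cohort(
    cohort: Iterable[tuple[str, AnnotatedVariant]],
    panel: frozenset[str] | set[str],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[ScreenHit], Counter]:
    """Select rare, possibly pathogenic variants over the candidate panel.

    Keeps variants with gene in ``panel``, overall MAF within the rarity
    bound in every database, and either loss of function or damaging in
    at least ``consensus_validation_min`` (default 3) of the six
    predictors.  Returns the hits and a per-gene tally.
    """
    hits: list[ScreenHit] = []
    for patient_id, v in cohort:
        if v.gene not in panel:
            continue
        if not passes_population_frequency(v, config):
            continue
        vote = consensus_damaging_count(v.predictor_calls, config, key=v.key)
        if v.is_lof:
            reason = "lof"
        elif vote.passes_validation:
            reason = "consensus"
        else:
            continue
        hits.append(ScreenHit(patient_id, v, vote, reason))
    tally = Counter(h.variant.gene for h in hits)
    return hits, tally
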