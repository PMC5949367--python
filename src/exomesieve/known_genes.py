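"""Screen of established/emerging HBC predisposition genes and a
simplified classification tier.

Before searching for novel genes, each patient's rare variants are
screened against the 27-gene panel of well-established and emerging
hereditary breast cancer genes.  Hits are assigned one of four tiers by
an ordered rule table (first match wins):

1. ClinVar-pathogenic loss-of-function            -> pathogenic
2. Novel loss-of-function (no rsID, no frequency) -> probably_pathogenic
3. Rare missense, >= 4/6 predictors damaging      -> vus
4. otherwise                                      -> not_reportable

This is deliberately NOT the full ACMG/AMP evidence-combining
framework: it is a transparent four-rule simplification whose
``rationale`` field records exactly which rules fired, making the
shortcut auditable.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .frequency import passes_population_frequency
from .model import AnnotatedVariant, ClinvarStatus, Consequence, FilterConfig, VariantKey
from .prioritize import ConsensusVote, consensus_damaging_count


class Tier(str, enum.Enum):
    pathogenic = "pathogenic"
    probably_pathogenic = "probably_pathogenic"
    vus = "vus"
    not_reportable = "not_reportable"


#: total order, most severe first
TIER_ORDER = (
    Tier.pathogenic,
    Tier.probably_pathogenic,
    Tier.vus,
    Tier.not_reportable,
)


@dataclass
class ClassificationResult:
    key: VariantKey
    patient_id: str
    gene: str
    tier: Tier
    rationale: list[str] = field(default_factory=list)
    vote: Optional[ConsensusVote] = None

    def __post_init__(self) -> None:
        assert self.rationale or self.tier == Tier.not_reportable


def is_novel(variant: AnnotatedVariant) -> bool:
    """Novel = no rsID and absent from every frequency database."""
    no_rsid = not variant.dbsnp_id
    no_freq = all(f is None for f in variant.freqs.values()) or not variant.freqs
    return no_rsid and no_freq


def classify_variant(
    variant: AnnotatedVariant,
    patient_id: str = "",
    config: FilterConfig = FilterConfig(),
) -> ClassificationResult:
    """Apply the ordered four-rule table (first matching rule wins)."""
    vote = consensus_damaging_count(variant.predictor_calls, config, key=variant.key)
    rationale: list[str] = []
    tier = Tier.not_reportable

    if variant.is_lof and variant.clinvar == ClinvarStatus.pathogenic:
        tier = Tier.pathogenic
        rationale = ["clinvar_pathogenic", "lof"]
    elif variant.is_lof and is_novel(variant):
        tier = Tier.probably_pathogenic
        rationale = ["lof", "novel_truncating"]
    elif (
        variant.consequence == Consequence.missense
        and vote.damaging_count >= config.consensus_discovery_min
        and passes_population_frequency(variant, config)
    ):
        tier = Tier.vus
        rationale = [f"missense_damaging_{vote.damaging_count}_of_6", "rare"]

    return ClassificationResult(
        key=variant.key,
        patient_id=patient_id,
        gene=variant.gene,
        tier=tier,
        rationale=rationale,
        vote=vote,
    )


def screen_known_genes(
    variants_by_patient: Mapping[str, Iterable[AnnotatedVariant]],
    panel27: frozenset[str] | set[str],
    config: FilterConfig = FilterConfig(),
) -> dict[str, list[tuple[AnnotatedVariant, ConsensusVote]]]:
    """Rare variants whose gene is on the established-gene panel,
    per patient, each with its consensus vote.

    Quality and rarity filtering are assumed upstream; the rarity bound
    is re-checked here so a common panel variant can never surface.
    """
    hits: dict[str, list[tuple[AnnotatedVariant, ConsensusVote]]] = {}
    for patient_id, variants in variants_by_patient.items():
        mine = []
        for v in variants:
            if v.gene in panel27 and passes_population_frequency(v, config):
                mine.append(
                    (v, consensus_damaging_count(v.predictor_calls, config, key=v.key))
                )
        if mine:
            hits[patient_id] = mine
    return hits


@dataclass
class CohortSummary:
    highest_tier_by_patient: dict[str, Tier]
    counts_by_tier: dict[Tier, int]

    @property
    def n_lof_carrier_patients(self) -> int:
        """Patients whose best hit is a (probably) pathogenic LOF."""
        return self.counts_by_tier.get(Tier.pathogenic, 0) + self.counts_by_tier.get(
            Tier.probably_pathogenic, 0
        )

    @property
    def n_vus_patients(self) -> int:
        return self.counts_by_tier.get(Tier.vus, 0)


def tabulate_patient_outcomes(
    classifications: Iterable[ClassificationResult],
) -> CohortSummary:
    """Per-patient highest tier and cohort counts by tier.

    A patient with both a pathogenic and a VUS hit counts once, under
    pathogenic.  Siblings are separate patients.
    """
    severity = {t: i for i, t in enumerate(TIER_ORDER)}
    best: dict[str, Tier] = {}
    for c in classifications:
        cur = best.get(c.patient_id)
        if cur is None or severity[c.tier] < severity[cur]:
            best[c.patient_id] = c.tier
    counts = Counter(best.values())
    return CohortSummary(
        highest_tier_by_patient=best,
        counts_by_tier={t: counts.get(t, 0) for t in TIER_ORDER},
    )
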