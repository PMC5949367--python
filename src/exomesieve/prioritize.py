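"""Stage 3 — function-based candidate selection.

The cascade keeps:

* every loss-of-function variant (stop-gained, frameshift, canonical
  splice site) in ANY gene — hereditary cancer genes are enriched for
  truncating alleles;
* missense variants in the cancer/DNA-repair gene panel, provided at
  least ``consensus_discovery_min`` (default 4) of the six in-silico
  predictors call them damaging — or, for affected sibling pairs, any
  shared panel missense regardless of the vote;
* in-frame indels in the panel, in both modes without a vote (the six
  predictors do not score indels).

dbscSNV splice scores (ADA/RF > 0.6) annotate the selected variants but
never add or remove candidates.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .model import (
    AnnotatedVariant,
    Consequence,
    DataError,
    FilterConfig,
    PREDICTORS,
    PredictorCall,
    SchemaError,
    VariantKey,
)

logger = logging.getLogger(__name__)


class SelectionMode(str, enum.Enum):
    unrelated = "unrelated"
    sibling_shared = "sibling_shared"


class SelectionReason(str, enum.Enum):
    lof_any_gene = "lof_any_gene"
    missense_panel_consensus = "missense_panel_consensus"
    inframe_panel_consensus = "inframe_panel_consensus"
    sibling_shared_panel = "sibling_shared_panel"


@dataclass(frozen=True)
class ConsensusVote:
    """Damaging-vote tally over the six effect predictors."""

    key: Optional[VariantKey]
    damaging_count: int
    missing_count: int
    passes_discovery: bool
    passes_validation: bool

    def __post_init__(self) -> None:
        assert 0 <= self.damaging_count <= 6
        assert 0 <= self.missing_count <= 6
        assert self.damaging_count + self.missing_count <= 6


@dataclass
class CandidateVariant:
    variant: AnnotatedVariant
    selection_reason: SelectionReason
    splice_flag: bool = False
    vote: Optional[ConsensusVote] = None

    @property
    def key(self) -> VariantKey:
        return self.variant.key


def consensus_damaging_count(
    predictor_calls: Mapping[str, PredictorCall],
    config: FilterConfig = FilterConfig(),
    key: Optional[VariantKey] = None,
) -> ConsensusVote:
    """Count damaging calls among the six predictors.

    Missing calls never count as damaging; the denominator stays fixed
    at six, so an unscored predictor effectively votes against.
    """
    if set(predictor_calls) != set(PREDICTORS):
        raise SchemaError(
            f"expected exactly 6 predictor keys, got {sorted(predictor_calls)}"
        )
    damaging = sum(
        1 for c in predictor_calls.values() if c == PredictorCall.damaging
    )
    missing = sum(
        1 for c in predictor_calls.values() if c == PredictorCall.missing
    )
    vote = ConsensusVote(
        key=key,
        damaging_count=damaging,
        missing_count=missing,
        passes_discovery=damaging >= config.consensus_discovery_min,
        passes_validation=damaging >= config.consensus_validation_min,
    )
    if config.consensus_validation_min <= config.consensus_discovery_min:
        # threshold nesting: the discovery rule is the stricter one
        assert vote.passes_validation or not vote.passes_discovery
    return vote


def splice_effect(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """dbscSNV flag: ADA > 0.6 and/or RF > 0.6 (strict); missing scores
    are false.  Annotative only."""
    for score in (variant.splice_ada, variant.splice_rf):
        if score is not None:
            if not (0.0 <= score <= 1.0):
                raise DataError(f"dbscSNV score {score} outside [0, 1]")
            if score > config.splice_score_min:
                return True
    return False


def select_functional_candidates(
    variants: Iterable[AnnotatedVariant],
    panel832: frozenset[str] | set[str],
    mode: SelectionMode,
    config: FilterConfig = FilterConfig(),
) -> list[CandidateVariant]:
    """Apply the function-based selection rules to pre-filtered variants.

    ``mode=sibling_shared`` implements the relaxed rule for variants
    already known to be shared by the affected siblings.  Each candidate
    carries exactly one selection reason and its splice annotation.
    """
    if not panel832:
        logger.warning("empty gene panel: only LOF variants are selectable")
    aliases = config.gene_aliases
    out: list[CandidateVariant] = []
    for v in variants:
        gene = aliases.get(v.gene.strip(), v.gene.strip())
        in_panel = gene in panel832
        vote = consensus_damaging_count(v.predictor_calls, config, key=v.key)
        reason: Optional[SelectionReason] = None
        if v.is_lof:
            reason = SelectionReason.lof_any_gene
        elif v.consequence == Consequence.missense and in_panel:
            if mode == SelectionMode.sibling_shared:
                reason = SelectionReason.sibling_shared_panel
            elif vote.passes_discovery:
                reason = SelectionReason.missense_panel_consensus
        elif v.consequence == Consequence.inframe_indel and in_panel:
            # in-frame indels are not scored by the six predictors:
            # panel membership alone gates them in both modes
            reason = (
                SelectionReason.sibling_shared_panel
                if mode == SelectionMode.sibling_shared
                else SelectionReason.inframe_panel_consensus
            )
        if reason is not None:
            out.append(
                CandidateVariant(
                    variant=v,
                    selection_reason=reason,
                    splice_flag=splice_effect(v, config),
                    vote=vote,
                )
            )
    return out
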