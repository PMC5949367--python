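"""Stage 2 — population rarity and recurrence filters.

* :func:`passes_population_frequency` — exclude variants whose OVERALL
  minor allele frequency exceeds 1% in any reference database.  The
  maximum sub-population frequency is carried for reporting but never
  used for exclusion (the study retained variants whose ethnic-subgroup
  MAF exceeded 1% while the overall MAF did not).
* :func:`exclude_internal_panel` — drop variants seen in the in-house
  exomes of known pathogenic-variant carriers (presence-based).
* :func:`recurrence_filter` — drop variants carried by more than
  ``max_unrelated_recurrence`` unrelated probands, collapsing each
  family to a single carrier.

Missing frequencies pass: "not described" is evidence of rarity, never
coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import AnnotatedVariant, DataError, FilterConfig, VariantKey


@dataclass
class FrequencyDecision:
    key: VariantKey
    verdict: str  # "pass" | "fail"
    failed_criteria: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert (self.verdict == "fail") == bool(self.failed_criteria)


def passes_population_frequency(
    variant: AnnotatedVariant, config: FilterConfig
) -> bool:
    """True unless some database's overall MAF exceeds ``maf_max``."""
    for name, maf in variant.freqs.items():
        if maf is None:
            continue
        if not (0.0 <= maf <= 1.0):
            raise DataError(f"{name} MAF {maf} outside [0, 1]")
        if maf > config.maf_max:
            return False
    return True


def exclude_internal_panel(
    candidates: set[VariantKey],
    internal_callsets: Iterable[set[VariantKey]],
) -> set[VariantKey]:
    """Remove any candidate present in at least one internal carrier
    exome.  Pure set algebra: result = candidates \\ union(callsets)."""
    seen: set[VariantKey] = set()
    for callset in internal_callsets:
        seen |= callset
    return set(candidates) - seen


def unrelated_carrier_count(
    key: VariantKey,
    cohort_callsets: Mapping[str, set[VariantKey]],
    family_of: Mapping[str, Optional[str]],
    collapse_families: bool = True,
) -> int:
    """Number of carriers after collapsing each family to one.

    ``family_of`` maps patient id to family id (``None`` for
    singletons).  With ``collapse_families=False`` every carrier counts.
    """
    carriers = [pid for pid, cs in cohort_callsets.items() if key in cs]
    if not collapse_families:
        return len(carriers)
    units = {family_of.get(pid) or f"__singleton__{pid}" for pid in carriers}
    return len(units)


def recurrence_filter(
    cohort_callsets: Mapping[str, set[VariantKey]],
    family_of: Mapping[str, Optional[str]],
    config: FilterConfig,
) -> set[VariantKey]:
    """Keys carried by at most ``max_unrelated_recurrence`` unrelated
    patients (family-collapsed).  Returns the surviving set over the
    union of all callsets."""
    all_keys: set[VariantKey] = set()
    for cs in cohort_callsets.values():
        all_keys |= cs
    return {
        k for k in all_keys
        if unrelated_carrier_count(
            k, cohort_callsets, family_of, config.collapse_families
        ) <= config.max_unrelated_recurrence
    }


def frequency_stage(
    variants: Iterable[AnnotatedVariant],
    config: FilterConfig,
    internal_union: Optional[set[VariantKey]] = None,
    recurrent_keys: Optional[set[VariantKey]] = None,
) -> tuple[list[AnnotatedVariant], list[FrequencyDecision]]:
    """Combine the three frequency criteria for one patient's stream.

    ``internal_union`` is the union of internal-carrier callsets;
    ``recurrent_keys`` the set of keys failing the recurrence rule
    (computed cohort-wide beforehand).
    """
    survivors, decisions = [], []
    for v in variants:
        failed: list[str] = []
        if not passes_population_frequency(v, config):
            failed.append("population_maf")
        if internal_union and v.key in internal_union:
            failed.append("internal_panel")
        if recurrent_keys and v.key in recurrent_keys:
            failed.append("recurrence")
        decisions.append(
            FrequencyDecision(v.key, "fail" if failed else "pass", failed)
        )
        if not failed:
            survivors.append(v)
    return survivors, decisions
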