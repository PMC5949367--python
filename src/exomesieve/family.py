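"""Family analysis — sibling sharing and cosegregation.

For a family with two affected sisters and one additional affected
relative (an aunt with ovarian cancer, genotyped only at the candidate
loci), candidate support is strengthened in two steps:

1. :func:`shared_variants` — exact intersection of the siblings'
   candidate callsets;
2. :func:`cosegregation_filter` — membership of each shared variant in
   the relative's targeted callset.  Loci not assayed in the relative
   are ``untested`` (absence of data is not absence of the allele), and
   untested variants are never called cosegregating.

:func:`novel_segregating_genes` then reports the distinct genes of the
cosegregating variants outside the established-gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import DataError, VariantKey


@dataclass(frozen=True)
class CosegregationResult:
    key: VariantKey
    shared_by_siblings: bool
    present_in_relative: Optional[bool]  # None = untested
    cosegregating: bool

    def __post_init__(self) -> None:
        if self.cosegregating:
            assert self.shared_by_siblings and self.present_in_relative


def shared_variants(
    sibling_callsets: Sequence[set[VariantKey]],
) -> set[VariantKey]:
    """Exact intersection of >= 2 sibling callsets (normalized keys)."""
    if len(sibling_callsets) < 2:
        raise DataError("sharing requires at least two sibling callsets")
    out = set(sibling_callsets[0])
    for cs in sibling_callsets[1:]:
        out &= cs
    return out


def cosegregation_filter(
    shared: set[VariantKey],
    relative_callset: set[VariantKey],
    assayed_loci: Optional[set[VariantKey]] = None,
) -> dict[VariantKey, CosegregationResult]:
    """Per-variant cosegregation verdicts for the shared set.

    ``assayed_loci`` lists the keys actually genotyped in the relative
    (a targeted panel); ``None`` means every shared locus was assayed.
    """
    results: dict[VariantKey, CosegregationResult] = {}
    for key in shared:
        if assayed_loci is not None and key not in assayed_loci:
            present: Optional[bool] = None
        else:
            present = key in relative_callset
        results[key] = CosegregationResult(
            key=key,
            shared_by_siblings=True,
            present_in_relative=present,
            cosegregating=bool(present),
        )
    return results


def cosegregating_keys(
    results: dict[VariantKey, CosegregationResult]
) -> set[VariantKey]:
    return {k for k, r in results.items() if r.cosegregating}


def novel_segregating_genes(
    cosegregating: Iterable[tuple[VariantKey, str]],
    known_panel: frozenset[str] | set[str],
) -> set[str]:
    """Distinct genes of cosegregating variants minus established
    predisposition genes (set semantics: a gene counts once)."""
    return {gene for _, gene in cosegregating} - set(known_panel)
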