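"""Stage 1 — per-call quality filters.

Three independent, pure predicates:

* :func:`passes_quality` — the four caller-metric thresholds
  (QD > 2, FS < 6, depth >= 10x, VAF > 0.25 by default);
* :func:`intersect_platforms` — keep only variants called on both
  sequencing platforms for dual-platform patients;
* :func:`flag_homopolymer` — exclude indel-error-prone calls inside or
  immediately flanking reference homopolymer runs (> 4 identical
  bases), applied to patients sequenced only on the semiconductor
  platform arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import AnnotatedVariant, DataError, FilterConfig, RefWindow, VariantKey

import logging

logger = logging.getLogger(__name__)


@dataclass
class QualityDecision:
    key: VariantKey
    verdict: str  # "pass" | "fail"
    failed_criteria: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert (self.verdict == "fail") == bool(self.failed_criteria)


def passes_quality(variant: AnnotatedVariant, config: FilterConfig) -> QualityDecision:
    """Apply the four call-quality thresholds.

    Strictness mirrors the criteria exactly: QD and VAF strict ``>``,
    FS strict ``<``, depth inclusive ``>=``.  A missing metric fails
    conservatively with reason ``missing_metric``.
    """
    failed: list[str] = []
    metrics = {"qd": variant.qd, "fs": variant.fs,
               "depth": variant.depth, "vaf": variant.vaf}
    missing = [name for name, value in metrics.items() if value is None]
    if missing:
        failed.append("missing_metric")
        failed.extend(missing)
    else:
        if not variant.qd > config.qd_min:
            failed.append("qd")
        if not variant.fs < config.fs_max:
            failed.append("fs")
        if not variant.depth >= config.depth_min:
            failed.append("depth")
        if not variant.vaf > config.vaf_min:
            failed.append("vaf")
    verdict = "fail" if failed else "pass"
    return QualityDecision(variant.key, verdict, failed)


def intersect_platforms(
    callsets_by_platform: Mapping[str, set[VariantKey]],
) -> set[VariantKey]:
    """Exact set intersection of normalized keys across platforms.

    With a single platform the callset passes through unchanged (with a
    logged notice): the dual-platform requirement only applies where two
    callsets exist.
    """
    if not callsets_by_platform:
        return set()
    sets = list(callsets_by_platform.values())
    if len(sets) == 1:
        logger.info(
            "single platform (%s): passthrough of %d variants",
            next(iter(callsets_by_platform)), len(sets[0]),
        )
        return set(sets[0])
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def flag_homopolymer(
    variant: AnnotatedVariant | VariantKey,
    reference_context: RefWindow,
    config: FilterConfig,
) -> bool:
    """True iff a homopolymer run of >= ``homopolymer_min_run`` identical
    reference bases overlaps the variant's reference span or is
    immediately adjacent (+/-1 bp) to it.

    Adjacency counts because polymerase slippage artifacts attach to run
    boundaries.  The window must extend at least ``homopolymer_min_run``
    bases on each side of the span so no qualifying run can be cut off.
    """
    key = variant if isinstance(variant, VariantKey) else variant.key
    span_start, span_end = key.pos, key.pos + len(key.ref) - 1
    run = config.homopolymer_min_run
    if (reference_context.start > span_start - run
            or reference_context.end < span_end + run):
        raise DataError(
            "reference window too short: need "
            f">= {run} bases each side of {span_start}-{span_end}"
        )
    lo, hi = span_start - 1, span_end + 1  # padded span (adjacency)
    seq = reference_context.seq.upper()
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run_len = j - i
        if run_len >= run:
            run_start = reference_context.start + i
            run_end = reference_context.start + j - 1
            if run_start <= hi and run_end >= lo:
                return True
        i = j
    return False


def quality_stage(
    variants: Iterable[AnnotatedVariant], config: FilterConfig
) -> tuple[list[AnnotatedVariant], list[QualityDecision]]:
    """Apply :func:`passes_quality` to a stream; return survivors and
    the full decision list for the trace."""
    survivors, decisions = [], []
    for v in variants:
        d = passes_quality(v, config)
        decisions.append(d)
        if d.verdict == "pass":
            survivors.append(v)
    return survivors, decisions
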