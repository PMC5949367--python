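"""Core domain types for germline variant prioritization.

The cascade operates on annotated single-nucleotide variants and small
indels from whole-exome sequencing of hereditary breast cancer (HBC)
patients.  Every downstream stage (quality, frequency, functional
prioritization, family cosegregation, pooled-control screening,
independent-cohort validation) consumes the types defined here:

* :class:`AnnotatedVariant` — one variant call with its quality metrics
  (QD, FS, depth, VAF), functional annotation (consequence, HGVS), the
  six in-silico predictor verdicts, two dbscSNV splice scores, and
  per-database population allele frequencies.
* :class:`VariantKey` — normalized allele identity used to match calls
  across platforms, patients, and cohorts.
* :class:`FilterConfig` — every numeric threshold of the cascade, with
  the study defaults.

Coordinates are 1-based fully closed, matching VCF.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

#: Canonical order of the six in-silico effect predictors.
PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "PolyPhen2",
    "FATHMM",
    "FATHMM-MKL",
    "MutationAssessor",
    "MutationTaster",
)


class DataError(ValueError):
    """A value in an input record violates a domain invariant."""


class SchemaError(ValueError):
    """An input file or mapping does not match the expected schema."""


class StageError(RuntimeError):
    """A pipeline stage could not run; carries the stage name."""


class Consequence(str, enum.Enum):
    """Controlled consequence vocabulary."""

    stop_gained = "stop_gained"
    frameshift = "frameshift"
    splice_canonical = "splice_canonical"
    missense = "missense"
    inframe_indel = "inframe_indel"
    synonymous = "synonymous"
    other = "other"


#: Consequence classes counted as loss of function: truncating or
#: canonical splice-disrupting events.
LOF_CLASSES = frozenset(
    {Consequence.stop_gained, Consequence.frameshift, Consequence.splice_canonical}
)


class PredictorCall(str, enum.Enum):
    damaging = "damaging"
    tolerated = "tolerated"
    missing = "missing"


class ClinvarStatus(str, enum.Enum):
    pathogenic = "pathogenic"
    benign = "benign"
    vus = "vus"
    not_described = "not_described"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized allele identity: equal keys <=> same allele event."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise DataError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref}) is not a variant")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class RefWindow:
    """A slice of reference sequence anchored at a 1-based start."""

    chrom: str
    start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base(self, pos: int) -> str:
        if not (self.start <= pos <= self.end):
            raise DataError(
                f"position {pos} outside reference window "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        return self.seq[pos - self.start]

    def slice(self, start: int, end: int) -> str:
        if start < self.start or end > self.end:
            raise DataError("requested slice exceeds reference window")
        return self.seq[start - self.start : end - self.start + 1]


@dataclass(frozen=True)
class Patient:
    """A sequenced individual of the discovery cohort."""

    patient_id: str
    family_id: Optional[str] = None
    affected: bool = True
    cancer_diagnoses: tuple[str, ...] = ()
    platforms: frozenset[str] = frozenset({"A"})

    def __post_init__(self) -> None:
        if not self.platforms:
            raise DataError(f"patient {self.patient_id} has no platform")
        if not self.platforms <= {"A", "B"}:
            raise DataError(f"unknown platform in {sorted(self.platforms)}")


@dataclass
class AnnotatedVariant:
    """One annotated variant call for one sample.

    ``freqs`` maps population-database name to overall minor allele
    frequency; a missing entry (or ``None``) means the variant is not
    described in that database and must be treated as rare, never as
    frequency zero.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.other
    qd: Optional[float] = None
    fs: Optional[float] = None
    depth: Optional[int] = None
    vaf: Optional[float] = None
    predictor_calls: Mapping[str, PredictorCall] = field(
        default_factory=lambda: {p: PredictorCall.missing for p in PREDICTORS}
    )
    splice_ada: Optional[float] = None
    splice_rf: Optional[float] = None
    freqs: Mapping[str, Optional[float]] = field(default_factory=dict)
    subpop_max_freq: Optional[float] = None
    dbsnp_id: Optional[str] = None
    clinvar: ClinvarStatus = ClinvarStatus.not_described

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise DataError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise DataError("ref == alt is not a variant")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise DataError(f"VAF {self.vaf} outside [0, 1]")
        for name, maf in self.freqs.items():
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise DataError(f"{name} MAF {maf} outside [0, 1]")
        for score, label in ((self.splice_ada, "ADA"), (self.splice_rf, "RF")):
            if score is not None and not (0.0 <= score <= 1.0):
                raise DataError(f"dbscSNV {label} score {score} outside [0, 1]")
        if set(self.predictor_calls) != set(PREDICTORS):
            raise SchemaError(
                "predictor_calls must have exactly the six predictor keys; got "
                f"{sorted(self.predictor_calls)}"
            )

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CLASSES


@dataclass(frozen=True)
class FilterConfig:
    """All numeric thresholds of the cascade (study defaults).

    Strictness follows the operators of the source criteria: QD, VAF,
    MAF, splice and pool-VAF thresholds are strict (``>``); FS is a
    strict upper bound (``<``); depth bounds are inclusive (``>=``).
    """

    qd_min: float = 2.0
    fs_max: float = 6.0
    depth_min: int = 10
    vaf_min: float = 0.25
    maf_max: float = 0.01
    max_unrelated_recurrence: int = 3
    homopolymer_min_run: int = 5
    consensus_discovery_min: int = 4
    consensus_validation_min: int = 3
    splice_score_min: float = 0.6
    pool_vaf_min: float = 0.02
    pool_depth_min: int = 10
    pool_size: int = 5
    #: collapse family members to one carrier in the recurrence count
    collapse_families: bool = True
    #: apply the homopolymer exclusion to every patient, not only the
    #: single-platform arm
    homopolymer_all_patients: bool = False
    #: optional gene-symbol alias map (e.g. FAM175A -> ABRAXAS1)
    gene_aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        numeric = (
            self.qd_min, self.fs_max, self.depth_min, self.vaf_min,
            self.maf_max, self.max_unrelated_recurrence,
            self.homopolymer_min_run, self.consensus_discovery_min,
            self.consensus_validation_min, self.splice_score_min,
            self.pool_vaf_min, self.pool_depth_min,
        )
        if any(x < 0 for x in numeric):
            raise DataError("all thresholds must be nonnegative")
        if self.pool_size < 1:
            raise DataError("pool_size must be >= 1")

    def with_overrides(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if f.name != "gene_aliases"]


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference_context: Optional[RefWindow] = None,
) -> VariantKey:
    """Left-align and trim a variant to its minimal representation.

    Indels have many equivalent VCF spellings inside repeat runs; calls
    from the two sequencing platforms can only be intersected after both
    are reduced to one canonical spelling.  The procedure is the usual
    one: repeatedly trim a shared trailing base (extending left from the
    reference when an allele would become empty), then trim shared
    leading bases while both alleles remain nonempty.  Idempotent.

    Without ``reference_context`` the variant passes through with only
    the context-free trimming steps (a notice is logged when trailing
    trimming would have required left extension).
    """
    if not ref or not alt:
        raise DataError("ref and alt must be nonempty")
    if ref == alt:
        raise DataError("ref == alt is not a variant")
    if reference_context is not None:
        if reference_context.chrom != chrom:
            raise DataError("reference context is for a different chromosome")
        observed = reference_context.slice(pos, pos + len(ref) - 1)
        if observed.upper() != ref.upper():
            raise DataError(
                f"ref allele {ref!r} at {chrom}:{pos} does not match "
                f"reference context {observed!r}"
            )
    ref, alt = ref.upper(), alt.upper()

    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            # one allele is a single base; trimming needs a left extension
            if reference_context is None:
                logger.info(
                    "no reference context at %s:%s; indel left without "
                    "full left-alignment", chrom, pos,
                )
                break
            if pos - 1 < reference_context.start:
                break  # cannot extend past the supplied window
            base = reference_context.base(pos - 1).upper()
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
            continue
        break

    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return VariantKey(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

_TERM_MAP = {
    "stop_gained": Consequence.stop_gained,
    "stop gained": Consequence.stop_gained,
    "stopgain": Consequence.stop_gained,
    "nonsense": Consequence.stop_gained,
    "missense": Consequence.missense,
    "missense_variant": Consequence.missense,
    "synonymous": Consequence.synonymous,
    "synonymous_variant": Consequence.synonymous,
    "other": Consequence.other,
}

_INTRONIC_OFFSET = re.compile(r"\d+([+-])(\d+)")


def _splice_class(hgvs_c: str) -> Consequence:
    """Canonical (+/-1 or +/-2 intronic) splice sites are LOF; anything
    deeper is a splice-region change classified as ``other``."""
    m = _INTRONIC_OFFSET.search(hgvs_c or "")
    if m is None:
        # annotation says splice but gives no offset: trust it as canonical
        return Consequence.splice_canonical
    return (
        Consequence.splice_canonical
        if int(m.group(2)) <= 2
        else Consequence.other
    )


def parse_consequence_term(term: str, hgvs_c: str = "") -> Consequence:
    """Map a free-text consequence term to the controlled vocabulary.

    Accepts both controlled terms and the loose spellings found in
    annotation exports ("Stop gained", "frameshift del", "in frame del",
    "Splice acceptor", "splice site", ...).  Unrecognized terms map to
    ``other`` with a logged warning.
    """
    t = (term or "").strip().lower().replace("-", " ").replace("_", " ")
    squeezed = t.replace(" ", "_")
    if squeezed in _TERM_MAP:
        return _TERM_MAP[squeezed]
    if t in _TERM_MAP:
        return _TERM_MAP[t]
    if "frameshift" in t:
        return Consequence.frameshift
    if "in frame" in t or "inframe" in t:
        return Consequence.inframe_indel
    if "splice" in t:
        return _splice_class(hgvs_c)
    if "stop" in t and "gain" in t:
        return Consequence.stop_gained
    logger.warning("unrecognized consequence term %r -> other", term)
    return Consequence.other


def classify_consequence(variant: AnnotatedVariant) -> tuple[Consequence, bool]:
    """Return the consequence class and the loss-of-function flag.

    LOF is true exactly for stop-gained, frameshift, and canonical
    (+/-1/2) splice-site variants — the classes treated as overtly
    deleterious regardless of gene.  Pure function of the input.
    """
    cls = variant.consequence
    if cls == Consequence.splice_canonical:
        # re-check the intronic offset when HGVS is available
        cls = _splice_class(variant.hgvs_c) if variant.hgvs_c else cls
    return cls, cls in LOF_CLASSES


def make_predictor_calls(
    damaging_count: Optional[int],
    order: Sequence[str] = PREDICTORS,
) -> dict[str, PredictorCall]:
    """Expand an aggregate "N of 6" damaging count into a 6-key mapping.

    ``None`` (unscored, e.g. truncating variants the predictors do not
    evaluate) yields all-missing.  Otherwise the first N predictors in
    ``order`` are marked damaging and the rest tolerated; only the count
    is meaningful downstream.
    """
    if damaging_count is None:
        return {p: PredictorCall.missing for p in order}
    if not (0 <= damaging_count <= len(order)):
        raise DataError(f"damaging count {damaging_count} outside 0..{len(order)}")
    return {
        p: (PredictorCall.damaging if i < damaging_count else PredictorCall.tolerated)
        for i, p in enumerate(order)
    }
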