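"""Readers and writers for every external artifact.

The primary interchange format is a tab-delimited annotation table with
one record per (patient, variant) — the post-calling, post-annotation
export a variant-annotation suite produces.  VCF ingestion is a
convenience front-end yielding variant skeletons that must be joined to
annotations by normalized key.

Conventions:

* "ND", ".", "-", "–" and empty cells in frequency, score and rsID
  columns parse to missing, never to zero — a variant not described in
  a database must pass the rarity filter, whereas a true 0 would mask
  data-quality problems.
* Coordinates are 1-based fully closed (VCF convention).
* Writing then reading an annotation table reproduces the records
  exactly; report writing is byte-deterministic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    AnnotatedVariant,
    ClinvarStatus,
    DataError,
    FilterConfig,
    PREDICTORS,
    PredictorCall,
    RefWindow,
    SchemaError,
    parse_consequence_term,
)
from .validation import CatalogEntry, PoolObservation, PriorStudyCatalog
from .model import VariantKey

MISSING_TOKENS = {"", "nd", ".", "-", "–", "na", "n/a"}

#: Required columns of the annotation-table interchange format.
ANNOTATION_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "transcript",
    "hgvs_c", "hgvs_p", "consequence", "qd", "fs", "depth", "vaf",
    "sift", "polyphen2", "fathmm", "fathmm_mkl", "mutation_assessor",
    "mutation_taster", "splice_ada", "splice_rf",
    "maf_1000g", "maf_esp6500", "maf_exac", "maf_abraom",
    "subpop_max_freq", "dbsnp_id", "clinvar",
]

_PREDICTOR_COLUMNS = dict(zip(
    ["sift", "polyphen2", "fathmm", "fathmm_mkl",
     "mutation_assessor", "mutation_taster"],
    PREDICTORS,
))

_FREQ_COLUMNS = {
    "maf_1000g": "1000Genomes",
    "maf_esp6500": "ESP6500",
    "maf_exac": "ExAC",
    "maf_abraom": "Abraom",
}


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


def parse_optional_float(cell: str) -> Optional[float]:
    if _is_missing(cell):
        return None
    try:
        return float(cell)
    except ValueError as e:
        raise DataError(f"cannot parse number from {cell!r}") from e


def parse_optional_int(cell: str) -> Optional[int]:
    v = parse_optional_float(cell)
    return None if v is None else int(round(v))


def parse_predictor_cell(cell: str) -> PredictorCall:
    c = cell.strip().lower()
    if _is_missing(c):
        return PredictorCall.missing
    if c in {"damaging", "d", "deleterious"}:
        return PredictorCall.damaging
    if c in {"tolerated", "t", "benign", "neutral"}:
        return PredictorCall.tolerated
    raise DataError(f"unrecognized predictor call {cell!r}")


def parse_clinvar_cell(cell: str) -> ClinvarStatus:
    c = cell.strip().lower()
    if _is_missing(c) or c == "not_described":
        return ClinvarStatus.not_described
    if "pathogenic" in c and "non" not in c:
        return ClinvarStatus.pathogenic
    if "benign" in c:
        return ClinvarStatus.benign
    if "uncertain" in c or c == "vus":
        return ClinvarStatus.vus
    raise DataError(f"unrecognized ClinVar status {cell!r}")


_MAF_CELL = re.compile(
    r"^\s*(?P<overall>[0-9.eE+-]+|ND)?\s*"
    r"(?:\((?P<pop>[A-Za-z]{0,3})\s*(?P<sub>[0-9.eE+-]+)\))?\s*$"
)


def parse_maf_pair(cell: str) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Parse a printed "ExAC/Abraom" frequency cell.

    Handles the verbatim table forms, e.g. ``ND/ND``, ``0.007/0.005``,
    ``0.002 (AF0.02627)/0.0008``, ``0.001 (AF 0.0166)/ 0.003`` — the
    parenthesized value is the maximum sub-population frequency, which
    is reported but never used for exclusion.  Returns
    (overall_exac, subpop_max, abraom).
    """
    left, sep, right = cell.partition("/")
    if not sep:
        raise DataError(f"frequency cell {cell!r} lacks the '/' separator")
    m = _MAF_CELL.match(left)
    if not m:
        raise DataError(f"cannot parse frequency cell {cell!r}")
    overall = None if (m.group("overall") is None or _is_missing(m.group("overall"))) \
        else float(m.group("overall"))
    subpop = None if m.group("sub") is None else float(m.group("sub"))
    abraom = parse_optional_float(right)
    return overall, subpop, abraom


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Ordered variant-sample records with all cells kept as strings.

    ``to_variants`` materializes typed :class:`AnnotatedVariant`
    objects; unknown columns are preserved as opaque extras and survive
    a write/read round-trip byte-identically.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"annotation table missing required columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[dict]:
        return self.frame.to_dict(orient="records")

    def to_variants(self) -> list[tuple[str, AnnotatedVariant]]:
        out = []
        for rec in self.frame.itertuples(index=False):
            row = rec._asdict()
            freqs = {
                db: parse_optional_float(row[col])
                for col, db in _FREQ_COLUMNS.items()
            }
            calls = {
                _PREDICTOR_COLUMNS[col]: parse_predictor_cell(row[col])
                for col in _PREDICTOR_COLUMNS
            }
            v = AnnotatedVariant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]).strip(),
                transcript=str(row["transcript"]),
                hgvs_c=str(row["hgvs_c"]),
                hgvs_p=str(row["hgvs_p"]),
                consequence=parse_consequence_term(row["consequence"], row["hgvs_c"]),
                qd=parse_optional_float(row["qd"]),
                fs=parse_optional_float(row["fs"]),
                depth=parse_optional_int(row["depth"]),
                vaf=parse_optional_float(row["vaf"]),
                predictor_calls=calls,
                splice_ada=parse_optional_float(row["splice_ada"]),
                splice_rf=parse_optional_float(row["splice_rf"]),
                freqs=freqs,
                subpop_max_freq=parse_optional_float(row["subpop_max_freq"]),
                dbsnp_id=None if _is_missing(row["dbsnp_id"]) else row["dbsnp_id"].strip(),
                clinvar=parse_clinvar_cell(row["clinvar"]),
            )
            out.append((str(row["patient_id"]), v))
        return out


def read_annotation_table(path: str | Path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                        comment=None)
    return AnnotationTable(frame)


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def variants_to_table(records: Iterable[tuple[str, AnnotatedVariant]]) -> AnnotationTable:
    """Serialize typed records into the interchange string format."""
    def fmt(x) -> str:
        return "ND" if x is None else (f"{x:g}" if isinstance(x, float) else str(x))

    rows = []
    for patient_id, v in records:
        row = {
            "patient_id": patient_id, "chrom": v.chrom, "pos": str(v.pos),
            "ref": v.ref, "alt": v.alt, "gene": v.gene,
            "transcript": v.transcript, "hgvs_c": v.hgvs_c, "hgvs_p": v.hgvs_p,
            "consequence": v.consequence.value,
            "qd": fmt(v.qd), "fs": fmt(v.fs), "depth": fmt(v.depth),
            "vaf": fmt(v.vaf),
        }
        for col, pred in _PREDICTOR_COLUMNS.items():
            call = v.predictor_calls[pred]
            row[col] = "" if call == PredictorCall.missing else call.value
        row["splice_ada"] = fmt(v.splice_ada)
        row["splice_rf"] = fmt(v.splice_rf)
        for col, db in _FREQ_COLUMNS.items():
            row[col] = fmt(v.freqs.get(db))
        row["subpop_max_freq"] = fmt(v.subpop_max_freq)
        row["dbsnp_id"] = v.dbsnp_id or "ND"
        row["clinvar"] = v.clinvar.value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS, dtype=str)
    if not rows:
        frame = pd.DataFrame(columns=ANNOTATION_COLUMNS, dtype=str)
    return AnnotationTable(frame)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> list[tuple[str, AnnotatedVariant]]:
    """Per-sample variant skeletons from a VCF 4.x file.

    QD and FS are taken from INFO; depth from FORMAT AD (or DP) and VAF
    as alt-depth / total-depth when not explicit.  One skeleton per ALT
    allele per carrying sample.  Records missing required fields are
    skipped with a logged reason.
    """
    import logging
    from cyvcf2 import VCF

    logger = logging.getLogger(__name__)
    out: list[tuple[str, AnnotatedVariant]] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    n_skipped = 0
    for rec in vcf:
        qd = rec.INFO.get("QD")
        fs = rec.INFO.get("FS")
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            n_skipped += 1
            logger.warning("skipping %s:%s: no AD field", rec.CHROM, rec.POS)
            continue
        for alt_index, alt in enumerate(rec.ALT):
            for si, sample in enumerate(samples):
                depths = [int(d) for d in ad[si] if int(d) >= 0]
                total = sum(depths)
                alt_depth = int(ad[si][alt_index + 1]) if len(ad[si]) > alt_index + 1 else 0
                if alt_depth <= 0:
                    continue
                vaf = alt_depth / total if total > 0 else None
                out.append((sample, AnnotatedVariant(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                    qd=float(qd) if qd is not None else None,
                    fs=float(fs) if fs is not None else None,
                    depth=total if total > 0 else None,
                    vaf=vaf,
                )))
    if n_skipped:
        logger.warning("%d VCF records skipped for missing fields", n_skipped)
    return out


def read_reference_window(
    path: str | Path, chrom: str, start: int, end: int
) -> RefWindow:
    """1-based inclusive reference slice from a FASTA file (indexed on
    first access), for normalization and homopolymer scanning."""
    from pyfaidx import Fasta

    if start < 1 or end < start:
        raise DataError(f"invalid window {chrom}:{start}-{end}")
    fasta = Fasta(str(path))
    if chrom not in fasta:
        raise DataError(f"chromosome {chrom} not in {path}")
    seq = str(fasta[chrom][start - 1:end]).upper()
    return RefWindow(chrom, start, seq)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedMember:
    family_id: str
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: int
    affected: bool


@dataclass
class Pedigree:
    members: dict[str, PedMember]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for m in self.members.values():
            fams.setdefault(m.family_id, []).append(m.individual_id)
        return fams

    def family_of(self, individual_id: str) -> Optional[str]:
        m = self.members.get(individual_id)
        return m.family_id if m else None

    def family_map(self) -> dict[str, Optional[str]]:
        """patient -> family id, with singleton families mapped to None
        so that every singleton is its own relatedness unit."""
        sizes = {f: len(ms) for f, ms in self.families().items()}
        return {
            pid: (m.family_id if sizes[m.family_id] > 1 else None)
            for pid, m in self.members.items()
        }

    def affected(self) -> list[str]:
        return [pid for pid, m in self.members.items() if m.affected]


def read_pedigree(path: str | Path) -> Pedigree:
    """PED-like file: family, individual, father, mother, sex, phenotype
    (2 = affected).  '0' means unknown parent.  Unknown parent
    references and cyclic parentage are hard errors."""
    members: dict[str, PedMember] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise SchemaError(f"pedigree line has {len(parts)} fields, need 6: {line!r}")
        fam, iid, father, mother, sex, pheno = parts[:6]
        if iid in members:
            raise SchemaError(f"duplicate individual {iid}")
        members[iid] = PedMember(
            family_id=fam, individual_id=iid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=int(sex), affected=(pheno == "2"),
        )
    for m in members.values():
        for parent in (m.father_id, m.mother_id):
            if parent is not None and parent not in members:
                raise SchemaError(
                    f"{m.individual_id} references unknown parent {parent}"
                )
    _check_acyclic(members)
    return Pedigree(members)


def _check_acyclic(members: Mapping[str, PedMember]) -> None:
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(pid: str, stack: tuple[str, ...]) -> None:
        if pid in stack:
            raise SchemaError(f"cyclic parentage involving {pid}")
        if state.get(pid) == 1:
            return
        m = members[pid]
        for parent in (m.father_id, m.mother_id):
            if parent is not None:
                visit(parent, stack + (pid,))
        state[pid] = 1

    for pid in members:
        visit(pid, ())


# ---------------------------------------------------------------------------
# Gene panels, catalogs, pool calls, config
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def read_gene_panel(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """Newline-delimited gene symbols; '#' comments; deduplicated."""
    import logging
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line)
    if not symbols:
        raise SchemaError(f"gene panel {path} is empty")
    panel = GenePanel(name or Path(path).stem, frozenset(symbols))
    logging.getLogger(__name__).info("panel %s: %d genes", panel.name, len(panel))
    return panel


def read_prior_catalog(path: str | Path) -> PriorStudyCatalog:
    """Delimited catalog of prior-study candidates:
    columns gene, study, hgvs_c, variant_type."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene", "study", "hgvs_c", "variant_type"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"catalog missing columns: {missing}")
    entries = []
    for row in frame.itertuples(index=False):
        if not row.gene.strip() or not row.study.strip():
            raise DataError("catalog entries need nonempty gene and study")
        entries.append(CatalogEntry(
            gene=row.gene.strip(), study=row.study.strip(),
            hgvs_c=row.hgvs_c.strip(), variant_type=row.variant_type.strip(),
        ))
    return PriorStudyCatalog(entries)


def read_pool_calls(path: str | Path) -> list[PoolObservation]:
    """Delimited pool-screen calls:
    pool_id, chrom, pos, ref, alt, pool_vaf, pool_depth[, n_members]."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["pool_id", "chrom", "pos", "ref", "alt", "pool_vaf", "pool_depth"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"pool table missing columns: {missing}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(PoolObservation(
            pool_id=row.pool_id,
            key=VariantKey(row.chrom, int(row.pos), row.ref, row.alt),
            pool_vaf=float(row.pool_vaf),
            pool_depth=int(row.pool_depth),
            n_members=int(getattr(row, "n_members", 5) or 5),
        ))
    return out


def read_config(path: str | Path) -> FilterConfig:
    """Flat key=value file mirroring FilterConfig fields."""
    overrides = {}
    valid = set(FilterConfig.field_names())
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"config line without '=': {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise SchemaError(f"unknown config key {key!r}")
        default = getattr(FilterConfig(), key)
        if isinstance(default, bool):
            overrides[key] = value.lower() in {"1", "true", "yes"}
        elif isinstance(default, int):
            overrides[key] = int(value)
        else:
            overrides[key] = float(value)
    return FilterConfig(**overrides)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "hgvs_c", "hgvs_p",
    "consequence", "selection_reason", "damaging_count", "splice_flag",
]


def write_report(
    candidates: Iterable[tuple[str, "object"]],
    trace: Optional[object],
    tsv_path: str | Path,
    json_path: Optional[str | Path] = None,
) -> None:
    """TSV candidate table plus JSON provenance trace.

    Candidates are (patient_id, CandidateVariant).  Output is sorted and
    serialized deterministically: identical inputs give identical bytes.
    HGVS strings are written verbatim from input.
    """
    rows = []
    for patient_id, c in candidates:
        v = c.variant
        rows.append({
            "patient_id": patient_id, "chrom": v.chrom, "pos": str(v.pos),
            "ref": v.ref, "alt": v.alt, "gene": v.gene,
            "hgvs_c": v.hgvs_c, "hgvs_p": v.hgvs_p,
            "consequence": v.consequence.value,
            "selection_reason": c.selection_reason.value,
            "damaging_count": str(c.vote.damaging_count) if c.vote else "",
            "splice_flag": str(c.splice_flag),
        })
    rows.sort(key=lambda r: (r["patient_id"], r["chrom"], int(r["pos"]),
                             r["ref"], r["alt"]))
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS, dtype=str)
    frame.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if json_path is not None and trace is not None:
        payload = trace.to_dict() if hasattr(trace, "to_dict") else trace
        Path(json_path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
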