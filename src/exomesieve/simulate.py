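"""Synthetic annotated cohorts, families, and control pools.

The generator emulates the statistical structure the cascade assumes in
a post-calling, post-annotation cohort — it does not simulate reads:

* a discovery cohort of unrelated probands plus affected sibling pairs
  (each with one additional typed relative), default 15 + 1 pair;
* per-variant call metrics (QD, FS, depth, VAF) spanning both sides of
  every quality threshold;
* a population-frequency spectrum mixing a point mass at "not
  described" with log-uniform frequencies, with an explicit mass above
  the 1% rarity bound;
* six predictor calls drawn conditionally on a latent "truly damaging"
  label with tunable concordance (the study gives no predictor error
  model, so sensitivity/specificity of the 4-of-6 and 3-of-6 rules is a
  config knob);
* planted causal variants constructed to pass every stage, with ground
  truth recorded for end-to-end recovery tests;
* equimolar control pools where a variant with c carrier alleles in a
  pool of k individuals yields a binomial read fraction around c/(2k).

Everything is reproducible: a seed is mandatory and all draws flow from
one ``numpy.random.Generator``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    AnnotatedVariant,
    Consequence,
    DataError,
    PREDICTORS,
    Patient,
    PredictorCall,
    RefWindow,
    VariantKey,
)
from .validation import PoolObservation

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedVariant:
    gene: str
    consequence: Consequence
    family_transmission: bool = False  # plant in a sibling pair (+relative)


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 17 patients (15 unrelated + 1 affected
    sibling pair with a typed relative), desk-scale variant counts."""

    n_patients: int = 17
    n_families: int = 1
    variants_per_patient: int = 400
    fraction_lof: float = 0.05
    fraction_in_panel: float = 0.30
    #: probability a frequency is "not described" in every database
    maf_missing_mass: float = 0.30
    #: probability a described variant is common (overall MAF > 1%)
    maf_common_mass: float = 0.30
    #: probability a latent damaging/benign label propagates to each predictor
    predictor_concordance: float = 0.85
    predictor_missing_rate: float = 0.05
    fraction_truly_damaging: float = 0.10
    planted_causal: tuple[PlantedVariant, ...] = ()
    pool_depth: int = 1000
    pool_size: int = 5
    n_control_pools: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        fractions = (
            self.fraction_lof, self.fraction_in_panel, self.maf_missing_mass,
            self.maf_common_mass, self.predictor_concordance,
            self.predictor_missing_rate, self.fraction_truly_damaging,
        )
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise DataError("all fractions must be in [0, 1]")
        if self.maf_missing_mass + self.maf_common_mass > 1.0:
            raise DataError("maf spectrum masses exceed 1")
        if self.n_families * 2 > self.n_patients:
            raise DataError("families (sibling pairs) exceed patients / 2")
        if self.seed is None:
            raise DataError("a seed is mandatory for any stochastic run")


@dataclass
class SimulatedCohort:
    patients: list[Patient]
    pedigree_rows: list[tuple[str, str, str, str, int, int]]  # PED fields
    annotations: list[tuple[str, AnnotatedVariant]]
    callsets: dict[str, set[VariantKey]]
    relative_callsets: dict[str, set[VariantKey]]  # family -> typed relative
    planted_truth: dict[VariantKey, PlantedVariant]
    reference: RefWindow

    def family_map(self) -> dict[str, Optional[str]]:
        return {p.patient_id: p.family_id for p in self.patients}


def _random_gene(rng: np.random.Generator) -> str:
    return "GEN" + "".join(rng.choice(list(string.ascii_uppercase), 4))


def _draw_maf(rng: np.random.Generator, config: SimulationConfig) -> Optional[float]:
    u = rng.random()
    if u < config.maf_missing_mass:
        return None
    if u < config.maf_missing_mass + config.maf_common_mass:
        return float(np.exp(rng.uniform(np.log(0.01), np.log(0.2))))
    return float(np.exp(rng.uniform(np.log(1e-6), np.log(0.01))))


def _draw_predictors(
    rng: np.random.Generator, truly_damaging: bool, config: SimulationConfig
) -> dict[str, PredictorCall]:
    calls = {}
    for p in PREDICTORS:
        if rng.random() < config.predictor_missing_rate:
            calls[p] = PredictorCall.missing
        elif rng.random() < config.predictor_concordance:
            calls[p] = (
                PredictorCall.damaging if truly_damaging else PredictorCall.tolerated
            )
        else:
            calls[p] = (
                PredictorCall.tolerated if truly_damaging else PredictorCall.damaging
            )
    return calls


def _draw_quality(rng: np.random.Generator) -> dict:
    """Call metrics straddling every threshold: ~60% of draws pass all
    four by construction of the component distributions."""
    return {
        "qd": float(rng.uniform(0.0, 12.0)),        # threshold 2
        "fs": float(rng.exponential(3.0)),           # threshold 6
        "depth": int(rng.poisson(40) + 1),           # threshold 10
        "vaf": float(np.clip(rng.normal(0.45, 0.18), 0.0, 1.0)),  # 0.25
    }


def make_reference(rng: np.random.Generator, length: int = 200_000,
                   chrom: str = "sim1") -> RefWindow:
    seq = "".join(rng.choice(list(_BASES), length))
    return RefWindow(chrom, 1, seq)


def _background_variant(
    rng: np.random.Generator,
    config: SimulationConfig,
    reference: RefWindow,
    panel_genes: Sequence[str],
) -> AnnotatedVariant:
    pos = int(rng.integers(100, len(reference.seq) - 100))
    ref = reference.base(pos)
    alt = rng.choice([b for b in _BASES if b != ref])
    u = rng.random()
    if u < config.fraction_lof:
        lof_classes = (Consequence.stop_gained, Consequence.frameshift,
                       Consequence.splice_canonical)
        consequence = lof_classes[int(rng.integers(len(lof_classes)))]
    elif u < config.fraction_lof + 0.75:
        consequence = Consequence.missense
    elif u < config.fraction_lof + 0.85:
        consequence = Consequence.inframe_indel
    else:
        consequence = Consequence.synonymous
    gene = (
        str(rng.choice(list(panel_genes)))
        if panel_genes and rng.random() < config.fraction_in_panel
        else _random_gene(rng)
    )
    maf = _draw_maf(rng, config)
    truly_damaging = rng.random() < config.fraction_truly_damaging
    q = _draw_quality(rng)
    return AnnotatedVariant(
        chrom=reference.chrom, pos=pos, ref=ref, alt=str(alt), gene=gene,
        consequence=Consequence(consequence),
        predictor_calls=_draw_predictors(rng, truly_damaging, config),
        freqs={"ExAC": maf, "Abraom": maf},
        **q,
    )


def _planted_annotated(
    plant: PlantedVariant, pos: int, reference: RefWindow
) -> AnnotatedVariant:
    ref = reference.base(pos)
    alt = "G" if ref != "G" else "T"
    return AnnotatedVariant(
        chrom=reference.chrom, pos=pos, ref=ref, alt=alt, gene=plant.gene,
        consequence=plant.consequence,
        qd=15.0, fs=0.5, depth=120, vaf=0.48,      # guaranteed stage-1 pass
        predictor_calls={p: PredictorCall.damaging for p in PREDICTORS},
        freqs={"ExAC": None, "Abraom": None},       # novel -> rare
    )


def simulate_cohort(
    config: SimulationConfig,
    panel_genes: Sequence[str] = (),
) -> SimulatedCohort:
    """Generate an annotated discovery cohort with pedigree and ground
    truth.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    reference = make_reference(rng)

    patients: list[Patient] = []
    ped_rows = []
    n_family_members = 2 * config.n_families
    for i in range(config.n_families):
        fam = f"FAM{i + 1:02d}"
        for j in (1, 2):
            pid = f"{fam}_S{j}"
            patients.append(Patient(pid, family_id=fam, affected=True,
                                    platforms=frozenset({"A", "B"})))
            ped_rows.append((fam, pid, "0", "0", 2, 2))
    for i in range(config.n_patients - n_family_members):
        pid = f"P{i + 1:03d}"
        platforms = frozenset({"A", "B"}) if i % 3 else frozenset({"B"})
        patients.append(Patient(pid, family_id=None, affected=True,
                                platforms=platforms))
        ped_rows.append((pid, pid, "0", "0", 2, 2))

    annotations: list[tuple[str, AnnotatedVariant]] = []
    callsets: dict[str, set[VariantKey]] = {p.patient_id: set() for p in patients}
    for p in patients:
        for _ in range(config.variants_per_patient):
            v = _background_variant(rng, config, reference, panel_genes)
            annotations.append((p.patient_id, v))
            callsets[p.patient_id].add(v.key)

    planted_truth: dict[VariantKey, PlantedVariant] = {}
    relative_callsets: dict[str, set[VariantKey]] = {
        f"FAM{i + 1:02d}": set() for i in range(config.n_families)
    }
    next_pos = 50
    sibling_ids = [p.patient_id for p in patients if p.family_id]
    unrelated_ids = [p.patient_id for p in patients if not p.family_id]
    for plant in config.planted_causal:
        v = _planted_annotated(plant, next_pos, reference)
        next_pos += 7
        planted_truth[v.key] = plant
        if plant.family_transmission and sibling_ids:
            fam = patients[0].family_id or "FAM01"
            for pid in sibling_ids[:2]:
                annotations.append((pid, v))
                callsets[pid].add(v.key)
            relative_callsets[fam].add(v.key)
        else:
            carrier = unrelated_ids[len(planted_truth) % len(unrelated_ids)] \
                if unrelated_ids else sibling_ids[0]
            annotations.append((carrier, v))
            callsets[carrier].add(v.key)

    return SimulatedCohort(
        patients=patients,
        pedigree_rows=ped_rows,
        annotations=annotations,
        callsets=callsets,
        relative_callsets=relative_callsets,
        planted_truth=planted_truth,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFamily:
    sibling_callsets: list[set[VariantKey]]
    relative_callset: set[VariantKey]
    truth_shared: set[VariantKey]
    truth_cosegregating: set[VariantKey]


def simulate_family(
    rng: np.random.Generator,
    n_background: int = 50,
    n_shared: int = 10,
    transmission_rate: float = 0.5,
    chrom: str = "simfam",
) -> SimulatedFamily:
    """Two sibling callsets with planted shared variants, a fraction of
    which are transmitted to the typed relative; ground truth recorded."""
    def key(i: int) -> VariantKey:
        return VariantKey(chrom, 1 + i, "A", "G")

    n_total = 2 * n_background + n_shared
    keys = [key(i) for i in range(n_total)]
    private1 = set(keys[:n_background])
    private2 = set(keys[n_background:2 * n_background])
    shared = set(keys[2 * n_background:])
    transmitted = {k for k in shared if rng.random() < transmission_rate}
    return SimulatedFamily(
        sibling_callsets=[private1 | shared, private2 | shared],
        relative_callset=transmitted,
        truth_shared=shared,
        truth_cosegregating=transmitted,
    )


# ---------------------------------------------------------------------------
# Control pools
# ---------------------------------------------------------------------------


def simulate_control_pools(
    variant_keys: Sequence[VariantKey],
    carrier_alleles: Mapping[VariantKey, Mapping[str, int]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[PoolObservation]:
    """Binomial pool read-sampling.

    ``carrier_alleles[key][pool_id]`` is the number of alternate alleles
    the pool's members carry (1 per heterozygote, 2 per homozygote).
    Pool VAF is Binomial(pool_depth, alleles / (2 * pool_size)) /
    pool_depth, capped at probability 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool_ids = [f"POOL{i + 1}" for i in range(config.n_control_pools)]
    out = []
    for key in variant_keys:
        for pool_id in pool_ids:
            alleles = carrier_alleles.get(key, {}).get(pool_id, 0)
            p = min(alleles / (2 * config.pool_size), 1.0)
            reads = int(rng.binomial(config.pool_depth, p)) if p > 0 else 0
            out.append(PoolObservation(
                pool_id=pool_id, key=key,
                pool_vaf=reads / config.pool_depth if config.pool_depth else 0.0,
                pool_depth=config.pool_depth,
                n_members=config.pool_size,
            ))
    return out
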