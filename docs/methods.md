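# Methods

## The problem

In families with hereditary breast cancer (HBC), pathogenic variants in
the established predisposition genes (BRCA1/2, TP53, CHEK2, ATM, PALB2,
…) explain a minority of cases. Whole-exome sequencing of affected
probands who are negative for those genes yields hundreds of thousands
of germline variants per cohort, of which at most a handful can be
causal. `exomesieve` implements the full prioritization cascade such a
study applies after variant calling and annotation, so that each rule —
and the cascade as a whole — is a tested, replayable computation rather
than a spreadsheet step.

The package operates strictly downstream of calling and annotation: the
consequence term, the six in-silico predictor verdicts, the dbscSNV
splice scores, and the per-database allele frequencies are input
columns. No alignment, calling, re-annotation, or live database query
is performed.

## The cascade

Stages run in a fixed order; every stage records input, per-criterion
exclusions, and survivors in a trace whose conservation
(input = excluded + surviving) is asserted at run time.

1. **Call quality.** A variant call passes iff QD > 2 (call confidence
   per supporting read depth), FS < 6 (Phred-scaled strand bias),
   depth ≥ 10×, and VAF > 0.25. Strictness follows the defining
   operators exactly: QD/VAF strict, depth inclusive. Missing metrics
   fail conservatively — the cascade's purpose is specificity. For
   patients sequenced on two platforms, only variants called on both
   are kept (set intersection of normalized keys). For patients with
   data only from the semiconductor platform, variants overlapping or
   immediately flanking a reference homopolymer run of ≥ 5 identical
   bases are excluded (slippage-prone context; the ±1 bp adjacency is
   included because slippage artifacts attach to run boundaries).
2. **Frequency.** A variant is excluded if its *overall* minor allele
   frequency exceeds 1% in any reference database (1000 Genomes,
   ESP6500, ExAC, Abraom columns by default; the set is whatever the
   freqs mapping carries). The maximum sub-population frequency is
   reported but never used for exclusion — the source tables retain
   variants whose ethnic-subgroup frequency exceeds 1% while the
   overall frequency does not, which pins down the overall-MAF
   semantics. "Not described" is a first-class missing value that
   passes the filter; it is never coerced to 0. Variants present in any
   of the in-house carrier exomes (five known BRCA1-mutation carriers)
   are excluded, as are variants carried by more than three unrelated
   probands, with each family collapsed to one carrier
   (configurable via `collapse_families`).
3. **Function.** Loss-of-function variants — stop-gained, frameshift,
   canonical (±1/±2 intronic) splice site — are selected in any gene.
   Missense variants are selected only within the cancer/DNA-repair
   gene panel and only when at least 4 of the 6 predictors (SIFT,
   PolyPhen-2, FATHMM, FATHMM-MKL, MutationAssessor, MutationTaster)
   call them damaging; a missing predictor call never counts as
   damaging and the denominator stays 6. For the affected sibling pair,
   any shared panel missense is kept regardless of the vote. In-frame
   indels bypass the vote in both modes (the six tools do not score
   indels; the source tables carry no vote for them) and are gated by
   panel membership alone. dbscSNV ADA/RF > 0.6 (either score) sets an
   annotation-only splice flag on the selected variants.
4. **Family.** The siblings' candidate sets are intersected; each
   shared variant is then tested for presence in one additional
   affected relative genotyped at the candidate loci. Loci not assayed
   in the relative are `untested`, never "absent". Distinct genes of
   the cosegregating variants, minus the established-gene panel, form
   the novel segregating-gene list.
5. **Confirmation and controls.** Candidates that failed technical
   re-sequencing, and candidates detected in any pool of the 25-woman
   control group, are removed. A pool call is a detection iff pool
   VAF > 2% and pool coverage ≥ 10×. One heterozygote in an equimolar
   5-person pool contributes an expected allele fraction of
   1/(2·5) = 10%, so at ~1000× pool depth the binomial detection
   probability exceeds 0.99 (verified by simulation).
6. **Overlap and panel assembly.** Surviving genes are matched against
   a catalog of candidates from prior HBC exome studies (gene-level
   match; exact hgvs.c match and LOF-in-either-study are recorded
   per gene). The final candidate panel is the deduplicated union of
   the segregating genes, the cancer-related genes with LOF candidates,
   and the overlap genes, with per-gene provenance.
7. **Independent-cohort screen.** Over the assembled panel, the
   validation cohort keeps variants that are rare (overall MAF within
   the 1% bound in every database) and either LOF or damaging by at
   least 3 of 6 predictors — the relaxed consensus rule.

## Known-gene screen and classification

Before the novel-gene cascade, each patient's rare variants are
screened against 27 established/emerging HBC genes. Hits are assigned
a tier by an ordered four-rule table (first match wins): ClinVar-
pathogenic LOF → pathogenic; novel LOF (no rsID, absent from every
frequency database) → probably pathogenic; rare missense with ≥ 4/6
damaging votes → VUS; otherwise not reportable. This is deliberately
not the ACMG/AMP evidence-combining framework — it is a transparent
simplification sufficient to reproduce the published tiers, and the
`rationale` field lists the fired rules so the shortcut is auditable.
Patients are tabulated by their highest tier; siblings count
separately.

## Variant identity

Indels admit many equivalent VCF spellings inside repeat runs, and the
two sequencing platforms disagree on anchoring, so cross-platform and
cross-patient matching uses a normalized key: shared trailing bases are
trimmed (extending left from the reference when an allele would empty),
then shared leading bases, yielding the left-aligned minimal
representation. The procedure is idempotent (property-tested).
Without reference context, variants pass through with context-free
trimming only, and a notice is logged. Coordinates are 1-based closed;
gene symbols compare case-sensitively after trimming, with an optional
alias map (empty by default).

## Thresholds

All thresholds live in `FilterConfig`:

| field | default | meaning |
|---|---|---|
| `qd_min` | 2 (strict >) | call confidence per depth |
| `fs_max` | 6 (strict <) | Phred strand bias |
| `depth_min` | 10 (≥) | site coverage |
| `vaf_min` | 0.25 (strict >) | variant allele fraction |
| `maf_max` | 0.01 | overall population frequency bound |
| `max_unrelated_recurrence` | 3 | max unrelated carriers |
| `homopolymer_min_run` | 5 | run length ("> 4 bases") |
| `consensus_discovery_min` | 4 | damaging votes, discovery |
| `consensus_validation_min` | 3 | damaging votes, validation |
| `splice_score_min` | 0.6 (strict >) | dbscSNV ADA/RF cutoff |
| `pool_vaf_min` | 0.02 (strict >) | pool detection VAF |
| `pool_depth_min` | 10 (≥) | pool detection coverage |
| `pool_size` | 5 | members per control pool |

## Synthetic cohorts

The generator (`exomesieve.simulate`) emulates an annotated
post-calling cohort, not reads: 17 affected patients by default (15
unrelated plus one affected sibling pair with one typed relative,
mirroring the study design), per-call metrics drawn to straddle every
quality threshold, a frequency spectrum mixing a point mass at
"not described" (0.30) with log-uniform frequencies and an explicit
mass above the 1% bound (0.30), and predictor calls drawn conditionally
on a latent "truly damaging" label with per-predictor concordance 0.85.
The study reports no predictor error model, so concordance is an
explicit knob rather than a hidden constant. Planted causal variants
are constructed to pass every stage (QD 15, FS 0.5, depth 120,
VAF 0.48, absent from every database) and their ground truth is
recorded, so end-to-end recovery is checkable exactly. Background
variant counts are desk-scale (hundreds per patient, versus ~10⁴–10⁵
in a real exome); genome-scale funnel counts are therefore not
emulated, and nothing in the tests depends on them. The generator also
omits haplotype structure, linkage disequilibrium, and read-level
error, so passing tests demonstrate the correctness of the filtering
logic on cohorts with the assumed statistical structure — not
robustness to upstream calling artifacts.

Control pools are simulated binomially: a variant with c alternate
alleles among a pool's members yields
VAF ~ Binomial(depth, c/(2·pool_size))/depth at pool depth 1000
(the study's mean pool coverage is ~1100×). All randomness flows from
one `numpy.random.Generator`; a seed is mandatory and equal seeds give
byte-identical outputs.

## Packaged table fixtures

The four published result tables ship as tab-separated fixtures with
frozen SHA-256 checksums, cells verbatim including "ND" and
parenthesized sub-population frequencies — so the missing-vs-zero and
overall-vs-subpopulation decisions are themselves under test. Tables
printing no genomic coordinates get deterministic placeholder loci
(chromosome `fx1`); identity there is (gene, hgvs.c), which is also
what the study matches on. Aggregate "N of 6" votes are expanded to a
six-key call mapping with N damaging calls; only the count is
meaningful downstream. The 832-gene cancer/DNA-repair panel is shipped
as a smaller placeholder reconstruction (established cancer and
DNA-repair genes, including every gene the result tables imply was on
the panel) and is fully replaceable; no test depends on its contents.

## Design choices made where the design was open

* **Canonical splice site** = intronic ±1/±2 of an exon boundary,
  parsed from hgvs.c when available; splice annotations without an
  offset are trusted as canonical; offsets ≥ 3 are splice-region and
  not LOF.
* **Recurrence counting** collapses each family to one carrier (the
  sisters contribute at most 1); a config switch restores per-carrier
  counting.
* **Homopolymer exclusion** applies only to the single-platform arm by
  default, with a config switch to widen it to all patients, and uses
  a reference-context scan (the alternative — caller flags — is not
  available in the interchange format).
* **Control-positive and confirmation-failure exclusions** are applied
  together in stage 5; the arithmetic 208 − 7 − 8 = 193 requires both.
* **Distinct genes, not a forced count:** how the published "186
  genes" derives from the 193 surviving variants is not fully
  specified (gene collapsing across patients and the family's variants
  is ambiguous), so the pipeline reports the distinct genes of the
  surviving variants and does not force a particular total.
* **Rarity in the validation screen** uses the same overall-MAF ≤ 1%
  semantics as discovery; no fixture value sits at the bound, so
  strictness there is moot.

## Numerical and degenerate-input behavior

Frequencies, VAFs, and dbscSNV scores outside [0, 1] are data errors,
not clamped. Empty gene panels leave only LOF selectable (warned).
Fewer than two sibling callsets is an error for sharing. An empty
annotation table produces an empty report with a complete trace. Report
writing sorts candidates by (patient, locus) and serializes JSON with
sorted keys, so identical inputs give identical bytes.

## Problem sizes

Tests and the analysis drivers run the cascade on seeded cohorts of
~1,200–6,800 variant records (6–17 patients × 200–400 variants), pool
simulations of 1,000 replicates at depth 1,000, and 500-locus
homopolymer sweeps; these sizes keep the whole suite in seconds while
leaving every statistical check with comfortable power (binomial
standard errors ≲ 0.5% where 3-SE bands are asserted).

## Known limitations

No likelihood-based cosegregation (Bayes factors), phasing, or
identity-by-descent inference — presence/absence only, as in the
source analysis. No burden testing or case–control association. The
simplified classification table encodes observed tier outcomes, not
the ACMG guideline. VCF ingestion trusts INFO/FORMAT fields and does
not recalibrate. Transcript-aware re-annotation from raw HGVS is out
of scope; the consequence column is trusted.
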