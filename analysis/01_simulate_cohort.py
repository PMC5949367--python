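#!/usr/bin/env python
"""Generate the synthetic discovery cohort used by the cascade demo.

Emulates the study design: 17 affected patients (15 unrelated + one
affected sibling pair with a typed relative), desk-scale background
variation, and four planted causal variants that satisfy every stage of
the cascade.  Writes the annotation table and pedigree to results/.
"""

from pathlib import Path

from exomesieve import fixtures
from exomesieve.io import variants_to_table, write_annotation_table
from exomesieve.model import Consequence
from exomesieve.simulate import PlantedVariant, SimulationConfig, simulate_cohort

# the full cohort table is bulky regenerable output -> scratch/
OUT = Path(__file__).resolve().parents[1] / "scratch"
SEED = 2018

PLANTED = (
    PlantedVariant("NOVELGENE1", Consequence.stop_gained),
    PlantedVariant("ERCC1", Consequence.missense),
    PlantedVariant("NIN", Consequence.inframe_indel),
    PlantedVariant("ERBB2", Consequence.missense, family_transmission=True),
)


def build_cohort():
    cfg = SimulationConfig(seed=SEED, planted_causal=PLANTED)
    panel = sorted(fixtures.load_panel_cancer_repair().genes)
    return cfg, simulate_cohort(cfg, panel_genes=panel)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg, cohort = build_cohort()
    write_annotation_table(
        variants_to_table(cohort.annotations), OUT / "simulated_cohort.tsv"
    )
    ped_lines = ["\t".join(str(x) for x in row) for row in cohort.pedigree_rows]
    (OUT / "simulated_cohort.ped").write_text("\n".join(ped_lines) + "\n")
    print(f"seed {cfg.seed}: {len(cohort.patients)} patients, "
          f"{len(cohort.annotations)} variant records, "
          f"{len(cohort.planted_truth)} planted causal variants")
    print(f"wrote {OUT / 'simulated_cohort.tsv'}")


if __name__ == "__main__":
    main()
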