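#!/usr/bin/env python
"""Independent-cohort screen over the 23-gene candidate panel.

Applies the validation criteria (rare, and loss of function or damaging
in at least 3 of 6 predictors) to the validation-cohort records: 16
variants in 12 of the 23 candidate genes, including the recurrent ERCC1
nonsense already seen in the discovery cohort.  Writes the hit table to
results/.
"""

import csv
from pathlib import Path

from exomesieve import fixtures, screen_independent_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = fixtures.load_panel_candidate23()
    hits, tally = screen_independent_cohort(
        fixtures.table4_validation_cohort(), panel.genes
    )
    with open(OUT / "independent_screen.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene", "hgvs_c", "consequence", "damaging_of_6",
                         "reason"])
        for h in sorted(hits, key=lambda h: (h.variant.gene, h.variant.hgvs_c)):
            writer.writerow([
                h.variant.gene, h.variant.hgvs_c, h.variant.consequence.value,
                h.vote.damaging_count, h.reason,
            ])
    print(f"selected variants: {len(hits)} in {len(tally)} of "
          f"{len(panel)} panel genes")
    for gene in sorted(tally):
        print(f"  {gene}\t{tally[gene]}")
    ercc1 = [h for h in hits if h.variant.gene == "ERCC1"]
    discovery = {v.hgvs_c for _, v in fixtures.table4_discovery_variants()
                 if v.gene == "ERCC1"}
    if ercc1 and ercc1[0].variant.hgvs_c in discovery:
        print(f"recurrent LOF shared with discovery: ERCC1 "
              f"{ercc1[0].variant.hgvs_c}")


if __name__ == "__main__":
    main()
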