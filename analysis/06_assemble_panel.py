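#!/usr/bin/env python
"""Assemble the candidate gene panel from its three components.

Union of the 7 family-segregating genes, the 5 cancer-related genes
with LOF candidates, and the 12 cross-study overlap genes; ROS1 sits in
two components, so the deduplicated panel has 23 genes.  Writes the
panel with provenance to results/.
"""

from pathlib import Path

from exomesieve import assemble_candidate_panel, cross_study_overlap, fixtures
from exomesieve.family import (
    cosegregating_keys,
    cosegregation_filter,
    novel_segregating_genes,
    shared_variants,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    s1, s2, aunt = fixtures.table2_callsets()
    coseg = cosegregating_keys(
        cosegregation_filter(shared_variants([s1, s2]), aunt)
    )
    genes = fixtures.table2_genes()
    segregating = novel_segregating_genes(
        [(k, genes[k]) for k in coseg], fixtures.load_panel_hbc27().genes
    )
    overlap = cross_study_overlap(
        fixtures.table3_current_candidates(), fixtures.table3_catalog()
    )
    panel = assemble_candidate_panel({
        "segregating": sorted(segregating),
        "lof_cancer": list(fixtures.LOF_CANCER_GENES),
        "overlap": [r.gene for r in overlap],
    })

    lines = [f"{g}\t{','.join(panel.provenance[g])}" for g in sorted(panel.genes)]
    (OUT / "candidate_panel.tsv").write_text(
        "gene\tsources\n" + "\n".join(lines) + "\n")
    print(f"components: segregating={len(segregating)}, "
          f"lof_cancer={len(fixtures.LOF_CANCER_GENES)}, overlap={len(overlap)}")
    multi = [g for g, s in panel.provenance.items() if len(s) > 1]
    print(f"panel size after deduplication: {len(panel)} "
          f"(multi-source: {', '.join(multi)})")


if __name__ == "__main__":
    main()
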