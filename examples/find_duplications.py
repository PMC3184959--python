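"""Detect tandem and segmental duplicates in a synthetic genome layout.

Plants two tandem clusters and one collinear block pair, then recovers them
with the ordinal-gap rule (<= 5 intervening genes) and the block-offset
rule (<= 500 kb between collinear gene offsets).
"""

from phytocyanin import (
    duplication_report,
    find_segmental_pairs,
    find_tandem_groups,
    gen_genome_layout,
)

loci, family_ids, blocks, truth = gen_genome_layout()

groups = find_tandem_groups(loci, family_ids)
pairs = find_segmental_pairs(loci, blocks, family_ids)
report = duplication_report(groups, pairs)

for g in groups:
    print(f"tandem group on {g.chrom}: {', '.join(g.gene_ids)}")
for p in pairs:
    print(f"segmental pair {p.gene_a} <-> {p.gene_b} "
          f"(offset difference {p.offset_diff/1e3:.0f} kb)")
print(f"{report.n_duplicated_genes} of {len(family_ids)} family genes arose "
      "by duplication — tandem genes sit within 5 gene slots of each other;")
print("segmental pairs lie at matching offsets inside duplicated chromosome blocks.")
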