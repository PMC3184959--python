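"""Digital expression analysis: EST specificity, MPSS tiers, microarray
normalisation/clustering and stress differential calls on synthetic data."""

from phytocyanin import (
    call_stress_de,
    cluster_genes,
    est_specific_tissue,
    gen_expression_data,
    mpss_tier,
    normalize_microarray,
)
from phytocyanin.simulate import ExprSpec

matrix, est, mpss, plate, truth = gen_expression_data(ExprSpec(seed=7))

specific = {g: est_specific_tissue(est.loc[g].to_dict()) for g in est.index}
specific = {g: t for g, t in specific.items() if t}
print(f"EST: {len(specific)} tissue-specific genes (one tissue holds >1/2 "
      f"of the counts): {specific}")

tiers = mpss.assign(tier=[mpss_tier(v) for v in mpss["tpm"]])
print("MPSS tier counts (<50 / 50-500 / >500 tpm):",
      tiers["tier"].value_counts().to_dict())

norm = normalize_microarray(matrix)
linkage, leaf_order = cluster_genes(norm)
print("hierarchical clustering leaf order (first 8 genes):", leaf_order[:8])

calls = call_stress_de(matrix, "drought")
up = [c.gene_id for c in calls if c.call == "UP"]
down = [c.gene_id for c in calls if c.call == "DOWN"]
print(f"drought stress: {len(up)} up-regulated (fold>2, p<0.05): {up}")
print(f"               {len(down)} down-regulated (fold<0.5, p<0.05): {down}")
print("planted truth:", sorted(truth.up), sorted(truth.down))
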