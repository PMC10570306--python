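"""Associate proteins with clinical factors and run preranked enrichment.

Per-protein ANOVA against disease cohort, preranked GSEA (weighted KS with a
gene-label permutation null) on the signed significance ranking, and assembly
of the factor/protein/pathway association network with high-confidence
interaction edges.
"""

from pharmotype import association as assoc
from pharmotype.synth import (
    GROUPS,
    SimulationConfig,
    default_blocks,
    simulate_all,
)

config = SimulationConfig(
    n_patients_per_group={g: 12 for g in GROUPS},
    n_proteins=500,
    blocks=default_blocks(),
    detection_quantile=0.0,
    mcar_rate=0.0,
)
result = simulate_all(config, seed=9)
matrix = result["proteomes"]["granulocyte"]
clinical = result["clinical"].set_index("patient_id")

anova = assoc.protein_factor_anova(matrix,
                                   clinical["cohort"].reindex(matrix.columns))
print("top disease-associated proteins (per-protein ANOVA):")
print(anova.nsmallest(5, "p_value")
      [["protein", "statistic", "p_value", "p_adj"]].to_string(index=False))

ranking = anova.set_index("protein")["signed_sig"]
enrich = assoc.gsea_preranked(ranking, result["genesets"], n_perm=500, seed=9)
print("\npreranked GSEA on the signed ANOVA ranking:")
print(enrich.nsmallest(4, "p_value")
      [["set_name", "es", "nes", "p_value", "p_adj"]].round(3)
      .to_string(index=False))

nodes, edges = assoc.build_network({"disease": anova}, {"disease": enrich},
                                   result["edges"], alpha_adj=0.001)
print(f"\nassociation network: {len(nodes)} nodes "
      f"({(nodes['node_type'] == 'protein').sum()} proteins), "
      f"{len(edges)} edges "
      f"({(edges['edge_type'] == 'protein-protein').sum()} interactions)")
# Planted discriminative and VAF-scaled proteins top the ANOVA ranking and
# drive the top enrichments; interaction edges appear whenever the included
# proteins belong to a planted co-regulated block.
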