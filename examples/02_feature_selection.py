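"""Rank genes with the cost-weighted DKM split criterion and compare against
the KS and t-test screens.

Run: python examples/02_feature_selection.py
"""

from avadx import (CohortConfig, build_gene_score_matrix, dkm_rank,
                   filter_training_variants, gene_set_overlap,
                   generate_cohort, prune_genes, screen_by_test)

cohort = generate_cohort(CohortConfig(seed=23))
panel = filter_training_variants(cohort.to_panel())
matrix = prune_genes(build_gene_score_matrix(panel))
labels = panel.individuals["status"]

# DKM: every gene gets a merit (decrease of 2*sqrt(p(1-p)) impurity at its
# best threshold split); take the top 125
ranking = dkm_rank(matrix, labels, top_k=125)
top_genes = {g for g, _ in ranking.entries}
print("top 5 genes by DKM merit:")
for g, merit in ranking.entries[:5]:
    print(f"  {g}: {merit:.4f}")

planted = set(cohort.causal_genes) & set(matrix.genes)
print(f"\nplanted causal genes recovered in top-125: "
      f"{len(planted & top_genes)}/{len(planted)}")

# distribution screens at p < 0.05 (uncorrected, as in the pipeline)
ks = set(screen_by_test(matrix, labels, test="KS").genes)
tt = set(screen_by_test(matrix, labels, test="TT").genes)
print(f"KS5 selects {len(ks)} genes, TT5 selects {len(tt)} genes")

# significance of the agreement between two selections (hypergeometric)
overlap, p = gene_set_overlap(frozenset(top_genes), frozenset(ks),
                              set(matrix.genes))
print(f"DKM125 vs KS5 overlap: {overlap} genes, p = {p:.3g}")
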