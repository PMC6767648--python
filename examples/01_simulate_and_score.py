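"""Generate a synthetic case/control cohort and build gene functional-deficit
scores from it.

Run: python examples/01_simulate_and_score.py
"""

from avadx import (CohortConfig, build_gene_score_matrix,
                   filter_training_variants, generate_cohort, prune_genes)

# 60 Crohn's-like cases (CD), 60 healthy controls (HC), 2000 genes of which
# 10 carry planted case-enriched deleterious variants
cohort = generate_cohort(CohortConfig(seed=11))
print(f"cohort: {len(cohort.individuals)} individuals, "
      f"{len(cohort.variants)} variants, "
      f"causal genes: {[str(g) for g in cohort.causal_genes[:4]]}...")

# keep autosomal PASS variants with complete genotypes, as training requires
panel = filter_training_variants(cohort.to_panel())
print(f"after filtering: {len(panel.variants)} variants")

# per-individual, per-gene scores: zygosity-weighted sums of variant scores
matrix = prune_genes(build_gene_score_matrix(panel))
print(f"score matrix: {matrix.scores.shape[0]} individuals x "
      f"{matrix.scores.shape[1]} genes after pruning")

causal = [g for g in cohort.causal_genes if g in matrix.genes]
print("\nmean gene score, cases vs controls, first two causal genes:")
status = panel.individuals["status"]
for g in causal[:2]:
    col = matrix.scores[g]
    print(f"  {g}: CD {col[status == 'CD'].mean():.3f}  "
          f"HC {col[status == 'HC'].mean():.3f}")
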