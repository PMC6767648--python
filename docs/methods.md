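# Methods

This document specifies exactly what `avadx` computes, the constants it uses,
and where its defaults deliberately scale the original analysis protocol down
for desk-scale runtimes.

## 1. Variant and gene scoring

Only autosomal, `FILTER=PASS` variants with complete genotypes across the
panel enter training (`filter_training_variants`). Multiallelic records are
split into per-alternate-allele rows; a genotype is the count of that
alternate allele (0/1/2), with missing genotypes propagated as missing.

Each annotated variant gets a functional-deficit value `v_score` in [0, 1]:

| class | v_score |
|---|---|
| indel | 1.0 |
| synonymous | 0.05 |
| non-synonymous, effect score s ≤ 0 (neutral) | 0.055 |
| non-synonymous without an effect score | 0.055 |
| non-synonymous, effect score s > 0 | 0.06 + 0.94·s/100 |

Effect scores live on [−100, 100]; s = 0 is treated as the boundary of the
effect branch (0.06 + 0.94·0 = 0.06 > 0.055, so a zero-score variant counts as
a minimal effect variant). A gene's score for one individual is

    gene_score = Σ_i z_i · v_score_i,   z_i = 0.25 (het) or 1.0 (hom alt)

over the gene's variants carried by that individual. Variants annotated to
multiple genes contribute to each. Genes that are all-zero, constant across
all carriers with a single shared value, or carried by a single individual are
pruned before modelling (`prune_genes`).

## 2. Feature selection (always inside the fold)

Four schemes, re-run on every training fold so that held-out individuals
never influence gene choice:

- **DIS / DISO** — genes whose non-zero carrier pattern is (near-)exclusive
  to cases: at least 3 case carriers and 0 control carriers (DIS), or the
  analogous one-sided pattern (DISO).
- **KS5 / TT5** — two-sample Kolmogorov–Smirnov or Welch t-test per gene,
  selecting p < 0.05, uncorrected. These return a *set*; cross-validation
  repeats draw a random subset of the requested size from it.
- **DKMcost** (default) — each gene is scored by the maximal decrease of the
  impurity 2·√(p(1−p)) over all threshold splits of its score column, with
  class weights compensating case/control imbalance; the top-k genes by merit
  (ties broken lexicographically by gene name) are used. The implementation
  is vectorised over genes and verified against an exhaustive split search.

Agreement between two gene sets is quantified with a one-sided
hypergeometric tail test (`gene_set_overlap`); per-variant case/control
carrier counts can also be screened with Fisher's exact test and
Benjamini–Hochberg correction (`variant_fisher_screen`).

## 3. Cross-validation and the model

Cross-validation is leave-one-out with the constraint that all members of a
family are held out together (a panel of 111 individuals containing two
related pairs yields 109 folds). Within each training fold the classes are
balanced by resampling: either *match-major* (keep everyone, resample the
minor class up to the major class size) or an integer target (resample both
classes to e.g. 500/500).

The learner is an RBF support-vector machine used in regression mode against
targets +100 (case) / −100 (control), with library-default hyperparameters
(C = 1, ε = 0.1, γ = "scale"). Regression targets are standardised before
fitting and predictions back-transformed — the default behaviour of the
reference SVM front end (e1071/libsvm). This matters: with targets of
magnitude 100 and C = 1, an unstandardised fit saturates every dual
coefficient and collapses onto its intercept, which tracks the training-fold
majority class and *anti-predicts* the held-out individual. A
classification-mode SVC with decision-function scores is available via
`ModelConfig(mode="svc")`.

Significance is assessed by a permutation test: training-fold labels are
shuffled within each fold, feature selection is redone, and the empirical p
is the fraction of permuted runs whose pooled held-out AUC exceeds the
observed one.

## 4. Prediction of unseen individuals

A fixed gene set (top-k DKM on the full, unadjusted training panel) defines
the feature space. For each test individual, one at a time:

1. test variants are restricted to training loci (zero overlap is an error;
   overlap below a configurable fraction, default 0.58, warns of degraded
   accuracy);
2. the individual's gene-score vector is batch-adjusted against the training
   panel with mean-only empirical-Bayes ComBat (a singleton test "batch"
   forces mean-only: there is no within-batch variance to moderate);
3. the training panel is resampled to 500/500 and a fresh model is trained to
   score the individual. One model per test individual, always.

Scores are called at three cutoffs: loose 0, default 14.3, strict 45. The
default cutoff can be re-derived as the mode (one-decimal grid, smallest on
ties) of per-round cross-validated score midpoints between the class means
(`select_default_cutoff`).

The ComBat implementation standardises genes against a batch-design linear
model, moderates batch location (and, outside mean-only mode, scale) with the
standard empirical-Bayes iteration, and is verified to 1e-9 (mean-only) /
1e-4 (full EB, bounded by the reference's iteration tolerance) against a
stored reference computed once with R `sva::ComBat`
(`tests/data/combat_sva_reference.tsv`).

## 5. Evaluation

`evaluate_scores` reports ROC AUC (verified equal to the Mann–Whitney U
statistic normalised by n₁·n₂), PR AUC with its class-fraction baseline, and,
at each cutoff: TP/FN/TN/FP, precision, recall, F1, MCC, and *balanced
precision* = TPR/(TPR + FPR), i.e. precision standardised to equal class
sizes. Undefined ratios (0/0) are reported as null, except MCC which follows
the convention of 0.0. Ties at a cutoff are called as cases (score ≥ cutoff).

## 6. Synthetic cohorts

`generate_cohort` produces a deterministic cohort: Hardy–Weinberg genotypes
at per-variant allele frequencies, optional related pairs sharing half their
genotypes, chromosome-X / non-PASS / missing-genotype records to exercise the
filters, and `n_causal` causal genes in which every non-synonymous SNV is a
planted effect variant (effect score uniform on [40, 100]) whose carriers are
enriched in cases (`case_enrichment` is the probability that a non-carrier
case is forced to carry).

Two design choices matter for calibration:

- **Dense background, rare causal variants.** Background variants are common
  (allele frequency 0.05–0.40, ~12 variants per gene) while causal variants
  are rare (0.005–0.05). With a *sparse* heavy-tailed background, leave-one-out
  with in-fold selection is systematically pessimistic: the noise genes a fold
  selects are exactly those in which the held-out individual is a discordant
  carrier, and a saturated SVM amplifies that tilt into anti-prediction. The
  dense background removes this artifact so that null cohorts cross-validate
  at AUC ≈ 0.5, as they must.
- **Batch shifts inflate genotypes at existing loci**
  (`plant_batch_shift`), never invent loci, so a planted shift survives the
  restriction of test variants to training loci and genuinely stresses the
  per-individual adjustment.

## 7. Scale reductions

The default synthetic scale is 60/60 individuals × 2000 genes with 10 causal
genes. `scripts/acceptance.py` (a few minutes end to end) uses: 2
cross-validation repeats (not 100), 19–20 permutations/cutoff rounds (not
1000), 20 seeds for recovery, 10 seeds for the null-AUC mean, and a 40-person
test panel for the batch experiment. The test suite further shrinks some
cohorts (e.g. the permutation-uniformity check runs on a 30/30 × 400-gene
null cohort). These reductions lower the precision of the reported estimates
but change no method constants: thresholds, score tables, resampling targets
and cutoffs are everywhere the full-scale defaults.

Known limitations: no covariates in the batch model (design matrix is batch
only), no X-chromosome dosage model (chr X is filtered out), and the
synthetic generator plants additive burden only — epistasis, linkage and
population structure are out of scope.
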