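"""Synthetic cohort generator: determinism, structure, carrier frequencies."""

import numpy as np
import pandas as pd
import pytest

from avadx import CohortConfig, generate_cohort, plant_batch_shift
from avadx.cohort import HET, HOM_ALT, MISSING


def test_generation_is_byte_identical_under_seed(tmp_path):
    cfg = CohortConfig(seed=3, n_cases=10, n_controls=10, n_genes=50, n_causal=2,
                       n_families=1)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert np.array_equal(a.genotypes, b.genotypes)
    pd.testing.assert_frame_equal(a.variants, b.variants)
    files_a = a.write(tmp_path / "a")
    files_b = b.write(tmp_path / "b")
    assert files_a.vcf.read_bytes() == files_b.vcf.read_bytes()
    assert files_a.annotations.read_bytes() == files_b.annotations.read_bytes()
    c = generate_cohort(CohortConfig(seed=4, n_cases=10, n_controls=10,
                                     n_genes=50, n_causal=2, n_families=1))
    assert not np.array_equal(a.genotypes, c.genotypes)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_causal=10, n_genes=5)
    with pytest.raises(ValueError):
        CohortConfig(case_enrichment=1.5)
    with pytest.raises(ValueError):
        CohortConfig(allele_freq=(0.0, 0.3))
    with pytest.raises(ValueError):
        CohortConfig(n_cases=3, n_families=2)


def test_cohort_structure(small_cohort):
    cfg = small_cohort.config
    ind = small_cohort.individuals
    assert (ind["status"] == "CD").sum() == cfg.n_cases
    assert (ind["status"] == "HC").sum() == cfg.n_controls
    fam_sizes = ind["family_id"].value_counts()
    assert (fam_sizes == 2).sum() == cfg.n_families
    assert len(small_cohort.causal_genes) == cfg.n_causal
    v = small_cohort.variants
    assert set(v.loc[v["consequence"] == "nonsynonymous", "gene"]) >= set(
        small_cohort.causal_genes
    )
    # some filter-exercising noise present
    assert (v["filter_status"] != "PASS").any()
    assert (v["chrom"] == "X").any()
    assert (small_cohort.genotypes == MISSING).any()


def test_family_pairs_share_genotypes(small_cohort):
    ind = small_cohort.individuals
    fam = ind["family_id"].value_counts()
    pair = ind.index[ind["family_id"] == fam[fam == 2].index[0]]
    cols = [list(ind.index).index(i) for i in pair]
    share = (small_cohort.genotypes[:, cols[0]]
             == small_cohort.genotypes[:, cols[1]]).mean()
    assert share > 0.5  # half forced plus chance agreement


def test_carrier_frequencies_match_hardy_weinberg():
    cfg = CohortConfig(seed=5, n_cases=500, n_controls=500, n_genes=40,
                       n_causal=0, variants_per_gene=4.0,
                       allele_freq=(0.2, 0.2), n_families=0,
                       frac_nonpass=0.0, frac_chrx=0.0, frac_missing=0.0)
    cohort = generate_cohort(cfg)
    carrier = ((cohort.genotypes == HET) | (cohort.genotypes == HOM_ALT))
    rate = carrier.mean()
    expected = 1 - (1 - 0.2) ** 2  # 0.36
    # n = 1000 individuals x ~160 variants: binomial error is tiny
    assert rate == pytest.approx(expected, abs=0.01)
    hom_rate = (cohort.genotypes == HOM_ALT).mean()
    assert hom_rate == pytest.approx(0.04, abs=0.005)


def test_case_enrichment_raises_case_carrier_rate():
    cfg = CohortConfig(seed=6, n_cases=300, n_controls=300, n_genes=60,
                       n_causal=20, case_enrichment=0.5, n_families=0,
                       frac_nonpass=0.0, frac_chrx=0.0, frac_missing=0.0)
    cohort = generate_cohort(cfg)
    v = cohort.variants
    causal_rows = np.flatnonzero(
        v["gene"].isin(cohort.causal_genes).to_numpy()
        & (v["consequence"] == "nonsynonymous").to_numpy()
    )
    is_case = (cohort.individuals["status"] == "CD").to_numpy()
    carrier = (cohort.genotypes[causal_rows] != 0)
    rate_cd = carrier[:, is_case].mean()
    rate_hc = carrier[:, ~is_case].mean()
    # forced carriers: rate_cd ~ p + 0.5 (1 - p)
    assert rate_cd == pytest.approx(rate_hc + 0.5 * (1 - rate_hc), abs=0.02)


def test_effect_score_distributions():
    cohort = generate_cohort(CohortConfig(seed=7, n_cases=20, n_controls=20,
                                          n_genes=300, n_causal=10, n_families=0))
    v = cohort.variants
    causal = v["gene"].isin(cohort.causal_genes) & (v["consequence"] == "nonsynonymous")
    background = ~v["gene"].isin(cohort.causal_genes) & (v["consequence"] == "nonsynonymous")
    assert (v.loc[causal, "effect_score"] >= 40).all()
    assert (v.loc[causal, "effect_score"] <= 100).all()
    assert v.loc[background, "effect_score"].mean() < 0
    assert v.loc[background, "effect_score"].between(-100, 100).all()


def test_split_keeps_families_in_training():
    cohort = generate_cohort(CohortConfig(seed=8, n_cases=20, n_controls=20,
                                          n_genes=50, n_causal=2, n_families=2))
    train, test = cohort.split(5, 5)
    assert len(test.individuals) == 10
    assert len(train.individuals) == 30
    fam_sizes = train.individuals["family_id"].value_counts()
    assert (fam_sizes == 2).sum() == 2  # both pairs intact in training
    assert not set(test.individuals.index) & set(train.individuals.index)
    with pytest.raises(ValueError):
        cohort.split(50, 5)


def test_batch_shift_displaces_scores_at_existing_loci(small_cohort):
    from avadx import build_gene_score_matrix, filter_training_variants

    shifted = plant_batch_shift(small_cohort, shift=1.0, seed=42)
    assert shifted.variants.equals(small_cohort.variants)  # loci unchanged
    assert (shifted.individuals["batch_id"] != small_cohort.individuals["batch_id"]).all()
    base = build_gene_score_matrix(filter_training_variants(small_cohort.to_panel()))
    moved = build_gene_score_matrix(filter_training_variants(shifted.to_panel()))
    common = [g for g in base.genes if g in moved.genes]
    delta = (moved.scores[common] - base.scores[common]).mean()
    assert (delta >= -1e-12).all()          # inflation only
    assert delta.max() > 0.2                # some genes visibly displaced
    # zero shift only relabels
    relabelled = plant_batch_shift(small_cohort, shift=0.0)
    assert np.array_equal(relabelled.genotypes, small_cohort.genotypes)
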