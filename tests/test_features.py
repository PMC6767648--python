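"""Feature selection: DIS, KS/TT screens, DKM ranking, overlap, Fisher."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from avadx import (dkm_merit, dkm_rank, gene_set_overlap, screen_by_test,
                   select_dis, variant_fisher_screen)
from avadx.features import _dkm_merits_matrix
from conftest import matrix_from_array

LABELS_6 = pd.Series(["CD", "CD", "CD", "HC", "HC", "HC"],
                     index=[f"ind{i}" for i in range(6)])


def test_select_dis_requires_case_exclusive_pattern():
    m = matrix_from_array([
        # g0: 3 cases, no control -> selected
        # g1: 2 cases only -> too few
        # g2: 3 cases + 1 control -> excluded
        [0.1, 0.1, 0.1],
        [0.2, 0.2, 0.1],
        [0.3, 0.0, 0.2],
        [0.0, 0.0, 0.4],
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0],
    ])
    gs = select_dis(m, LABELS_6, min_cases=3)
    assert gs.genes == frozenset({"g0"})
    # monotone in min_cases: raising the bar never adds genes
    gs2 = select_dis(m, LABELS_6, min_cases=2)
    assert gs.genes <= gs2.genes


def test_ks_exact_small_sample_p_value():
    # CD = {1,1,1,1,1}, HC = {0,0,0,0,0}: D = 1, exact p = 2/C(10,5) = 2/252
    m = matrix_from_array([[1.0]] * 5 + [[0.0]] * 5)
    labels = pd.Series(["CD"] * 5 + ["HC"] * 5, index=m.scores.index)
    from scipy import stats

    p = stats.ks_2samp(np.ones(5), np.zeros(5), method="auto").pvalue
    assert p == pytest.approx(2 / 252)
    assert "g0" in screen_by_test(m, labels, test="KS").genes


def test_screens_never_select_identical_constant_genes():
    m = matrix_from_array([[0.3, 0.0]] * 6)
    assert screen_by_test(m, LABELS_6, test="KS").genes == frozenset()
    assert screen_by_test(m, LABELS_6, test="TT").genes == frozenset()


def _brute_force_dkm(values, is_case, cw=1.0, hw=1.0):
    """Exhaustive DKM merit over every threshold split."""
    def impurity(sub_case):
        w = np.where(sub_case, cw, hw)
        p = w[sub_case].sum() / w.sum()
        return 2 * math.sqrt(max(p * (1 - p), 0.0))

    values = np.asarray(values, dtype=float)
    root = impurity(is_case)
    w_all = np.where(is_case, cw, hw).sum()
    merit = 0.0
    for t in np.unique(values)[:-1]:
        left = values <= t
        wl = np.where(is_case[left], cw, hw).sum()
        wr = w_all - wl
        children = (wl / w_all) * impurity(is_case[left]) + (
            wr / w_all
        ) * impurity(is_case[~left])
        merit = max(merit, root - children)
    return merit


def test_dkm_merit_brute_force_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(4, 9))
        values = rng.choice([0.0, 0.05, 0.1, 0.53, 1.0], size=n)
        is_case = rng.random(n) < 0.5
        if is_case.all() or not is_case.any():
            continue
        cw, hw = rng.uniform(0.5, 2.0, size=2)
        assert dkm_merit(values, is_case, cw, hw) == pytest.approx(
            _brute_force_dkm(values, is_case, cw, hw)
        )


def test_dkm_vectorised_matches_single_gene():
    rng = np.random.default_rng(2)
    x = rng.choice([0.0, 0.0125, 0.05, 0.25, 1.0], size=(15, 30))
    is_case = rng.random(15) < 0.5
    vec = _dkm_merits_matrix(x, is_case, 1.3, 0.7)
    ref = [dkm_merit(x[:, j], is_case, 1.3, 0.7) for j in range(30)]
    assert np.allclose(vec, ref)


def test_dkm_perfect_separation_and_constant():
    is_case = np.array([True] * 3 + [False] * 3)
    perfect = np.array([1.0, 0.9, 0.8, 0.1, 0.2, 0.3])
    assert dkm_merit(perfect, is_case) == pytest.approx(2 * math.sqrt(0.25))
    assert dkm_merit(np.full(6, 0.4), is_case) == 0.0


def test_dkm_rank_monotone_transform_invariance():
    rng = np.random.default_rng(3)
    x = rng.random((12, 8))
    m1 = matrix_from_array(x)
    m2 = matrix_from_array(np.exp(3 * x) + 1)  # strictly monotone transform
    labels = pd.Series(["CD"] * 6 + ["HC"] * 6, index=m1.scores.index)
    r1 = dkm_rank(m1, labels)
    r2 = dkm_rank(m2, labels)
    assert [g for g, _ in r1.entries] == [g for g, _ in r2.entries]
    assert np.allclose([v for _, v in r1.entries], [v for _, v in r2.entries])


def test_dkm_rank_ties_break_lexicographically_and_top_k_warns(caplog):
    m = matrix_from_array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
    labels = pd.Series(["CD", "CD", "HC", "HC"], index=m.scores.index)
    r = dkm_rank(m, labels)
    assert [g for g, _ in r.entries] == ["g0", "g1"]
    top = dkm_rank(m, labels, top_k=5)
    assert len(top.entries) == 2


def test_gene_set_overlap_exact_enumeration():
    # |a| = |b| = 5 in a background of 20, full overlap:
    # P(X >= 5) = 1/C(20,5) = 1/15504
    background = {f"G{i}" for i in range(20)}
    a = frozenset(f"G{i}" for i in range(5))
    overlap, p = gene_set_overlap(a, a, background)
    assert overlap == 5
    assert p == pytest.approx(1 / 15504)
    # brute-force check of P(X >= 2) for |a| = 4, |b| = 3, N = 30
    background30 = {f"G{i}" for i in range(30)}
    b = frozenset(["G0", "G1", "G2"])
    a4 = frozenset(["G0", "G1", "G10", "G11"])
    overlap, p = gene_set_overlap(a4, b, background30)
    assert overlap == 2
    hits = sum(
        1 for comb in itertools.combinations(range(30), 4)
        if len(set(comb) & {0, 1, 2}) >= 2
    )
    assert p == pytest.approx(hits / math.comb(30, 4))


def test_gene_set_overlap_validation():
    with pytest.raises(ValueError):
        gene_set_overlap(frozenset("a"), frozenset("b"), set())
    with pytest.raises(ValueError):
        gene_set_overlap(frozenset({"z"}), frozenset(), {"a"})
    assert gene_set_overlap(frozenset(), frozenset({"a"}), {"a"})[1] == 1.0


def test_variant_fisher_screen(small_cohort):
    from avadx import filter_training_variants
    from scipy import stats

    panel = filter_training_variants(small_cohort.to_panel())
    out = variant_fisher_screen(panel)
    assert len(out) == panel.n_variants
    assert ((out["q"] >= out["p"] - 1e-12)).all()
    # identical carrier counts in both (equal-size) classes -> p = 1
    equal = out[out["carriers_cd"] == out["carriers_hc"]]
    assert len(equal) > 0 and (equal["p"] == 1.0).all()
    # spot-check one variant against scipy directly
    i = int(out["p"].idxmin())
    is_case = (panel.statuses == "CD").to_numpy()
    carrier = (panel.genotypes[i] == 1) | (panel.genotypes[i] == 2)
    table = [[carrier[is_case].sum(), (~carrier[is_case]).sum()],
             [carrier[~is_case].sum(), (~carrier[~is_case]).sum()]]
    assert out["p"].iloc[i] == pytest.approx(
        stats.fisher_exact(table, alternative="two-sided")[1]
    )
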