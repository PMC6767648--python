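"""Feature selection: disease-informative genes from a gene-score matrix.

Four selection schemes operate on the individuals x genes matrix with
case/control labels:

* ``DIS`` — genes non-zero in at least ``min_cases`` cases and in no control;
* ``KS5`` / ``TT5`` — genes whose case and control score distributions differ
  at p < 0.05 under a two-sample Kolmogorov-Smirnov or Welch t test
  (no multiple-testing correction; the sets feed a classifier, not a claim
  of per-gene significance);
* ``DKMcost`` — genes ranked by the best achievable decrease of the
  Dietterich-Kearns-Mansour split impurity 2*sqrt(p(1-p)) over binary
  threshold splits of the gene's scores, with optional misclassification-cost
  weighting of the class probabilities.

All selections are meant to be run per cross-validation fold on the
training individuals only (in-fold discipline lives in :mod:`avadx.model`).
A hypergeometric overlap test and a per-variant Fisher screen with
Benjamini-Hochberg correction complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HET, HOM_ALT, Panel, STATUS_CASE, STATUS_CONTROL
from .scoring import GeneScoreMatrix

logger = logging.getLogger(__name__)

FS_METHODS = ("DIS", "DISO", "KS5", "TT5", "DKMcost")


@dataclass(frozen=True)
class GeneSet:
    genes: frozenset[str]
    method: str
    fold_id: str = "full-panel"

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class FeatureRanking:
    """Genes ordered by merit (descending; ties broken by gene ID)."""

    entries: tuple[tuple[str, float], ...]
    method: str = "DKMcost"
    fold_id: str = "full-panel"

    def top(self, k: int) -> list[str]:
        if k > len(self.entries):
            logger.warning(
                "requested top %d of %d ranked genes; returning all", k, len(self.entries)
            )
        return [g for g, _ in self.entries[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "merit"]).assign(
            method=self.method, fold=self.fold_id
        )


def _aligned_labels(matrix: GeneScoreMatrix, labels) -> np.ndarray:
    """Boolean case indicator aligned to matrix rows."""
    if isinstance(labels, (pd.Series, dict)):
        labels = pd.Series(labels).reindex(matrix.scores.index)
        if labels.isna().any():
            raise ValueError("labels missing for some matrix individuals")
        values = labels.to_numpy()
    else:
        values = np.asarray(labels)
        if len(values) != len(matrix.scores):
            raise ValueError("labels length does not match matrix")
    if values.dtype == bool:
        return values
    return values == STATUS_CASE


def select_dis(
    matrix: GeneScoreMatrix, labels, min_cases: int = 3, fold_id: str = "full-panel"
) -> GeneSet:
    """Genes non-zero in >= ``min_cases`` cases and zero in every control."""
    is_case = _aligned_labels(matrix, labels)
    if int(is_case.sum()) < min_cases:
        raise ValueError(f"fewer than {min_cases} cases in matrix")
    x = matrix.scores.to_numpy()
    nz = x != 0
    case_hits = nz[is_case].sum(axis=0)
    control_hits = nz[~is_case].sum(axis=0)
    keep = (case_hits >= min_cases) & (control_hits == 0)
    genes = frozenset(np.asarray(matrix.genes)[keep])
    return GeneSet(genes=genes, method="DIS", fold_id=fold_id)


def screen_by_test(
    matrix: GeneScoreMatrix,
    labels,
    test: str = "KS",
    alpha: float = 0.05,
    fold_id: str = "full-panel",
) -> GeneSet:
    """Genes whose case vs control score distributions differ at p < alpha.

    ``test`` is ``"KS"`` (two-sample Kolmogorov-Smirnov, exact null for
    small samples) or ``"TT"`` (Welch two-sample t test).  Genes constant
    in both classes are never selected.
    """
    is_case = _aligned_labels(matrix, labels)
    if int(is_case.sum()) < 2 or int((~is_case).sum()) < 2:
        raise ValueError("need at least two individuals per class")
    x = matrix.scores.to_numpy()
    cases, controls = x[is_case], x[~is_case]
    if test.upper() == "TT":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(cases, controls, axis=0, equal_var=False)
        pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        method = "TT5"
    elif test.upper() == "KS":
        pvals = np.ones(x.shape[1])
        for j in range(x.shape[1]):
            a, b = cases[:, j], controls[:, j]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                continue  # identical constants: p = 1
            pvals[j] = stats.ks_2samp(a, b, method="auto").pvalue
        method = "KS5"
    else:
        raise ValueError(f"unknown test {test!r}")
    keep = pvals < alpha
    genes = frozenset(np.asarray(matrix.genes)[keep])
    return GeneSet(genes=genes, method=method, fold_id=fold_id)


def _dkm_impurity(p: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * np.sqrt(np.clip(p * (1.0 - p), 0.0, None))


def dkm_merit(values: np.ndarray, is_case: np.ndarray,
              case_weight: float = 1.0, control_weight: float = 1.0) -> float:
    """Best DKM impurity decrease over binary threshold splits of one gene.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values; node class probabilities and node sizes use
    cost-derived class weights (uniform weights give the plain criterion).
    A constant gene has no split and merit 0.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = np.where(is_case[order], case_weight, control_weight)
    wc = np.where(is_case[order], case_weight, 0.0)
    total_w = w.sum()
    total_case = wc.sum()
    p_root = total_case / total_w
    root = _dkm_impurity(p_root)

    # split after position i (left = v[:i+1]); valid where value changes
    cut = np.nonzero(v[:-1] < v[1:])[0]
    if len(cut) == 0:
        return 0.0
    cw = np.cumsum(w)[cut]
    cc = np.cumsum(wc)[cut]
    p_left = cc / cw
    p_right = (total_case - cc) / (total_w - cw)
    children = (cw / total_w) * _dkm_impurity(p_left) + (
        (total_w - cw) / total_w
    ) * _dkm_impurity(p_right)
    return float(root - children.min())


def _dkm_merits_matrix(x: np.ndarray, is_case: np.ndarray,
                       case_weight: float, control_weight: float) -> np.ndarray:
    """Vectorised :func:`dkm_merit` over the columns of ``x``."""
    n, m = x.shape
    if n < 2:
        return np.zeros(m)
    order = np.argsort(x, axis=0, kind="stable")
    v = np.take_along_axis(x, order, axis=0)
    w_row = np.where(is_case, case_weight, control_weight)
    wc_row = np.where(is_case, case_weight, 0.0)
    w = w_row[order]
    wc = wc_row[order]
    total_w = w_row.sum()
    total_case = wc_row.sum()
    root = _dkm_impurity(total_case / total_w)

    cw = np.cumsum(w, axis=0)[:-1]
    cc = np.cumsum(wc, axis=0)[:-1]
    valid = v[:-1] < v[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_left = cc / cw
        p_right = (total_case - cc) / (total_w - cw)
        children = (cw * _dkm_impurity(p_left)
                    + (total_w - cw) * _dkm_impurity(p_right)) / total_w
    children = np.where(valid, children, np.inf)
    best = children.min(axis=0)
    merits = np.where(np.isfinite(best), root - best, 0.0)
    return merits


def dkm_rank(
    matrix: GeneScoreMatrix,
    labels,
    cost_matrix: Sequence[Sequence[float]] | None = None,
    top_k: int | None = None,
    fold_id: str = "full-panel",
) -> FeatureRanking:
    """Rank genes by DKM merit (cost-weighted when a cost matrix is given).

    ``cost_matrix[i][j]`` is the cost of predicting class j for true class i
    (classes ordered case, control; the diagonal is ignored).  Class weights
    are the off-diagonal misclassification costs, so the uniform default
    reduces to the unweighted criterion.
    """
    is_case = _aligned_labels(matrix, labels)
    if matrix.scores.shape[1] == 0:
        raise ValueError("matrix has no genes to rank")
    if cost_matrix is None:
        case_weight = control_weight = 1.0
    else:
        case_weight = float(cost_matrix[0][1])
        control_weight = float(cost_matrix[1][0])
    x = matrix.scores.to_numpy()
    merits = _dkm_merits_matrix(x, is_case, case_weight, control_weight)
    genes = np.asarray(matrix.genes)
    order = np.lexsort((genes, -merits))  # merit desc, gene ID asc on ties
    entries = tuple((str(genes[j]), float(merits[j])) for j in order)
    if top_k is not None:
        if top_k > len(entries):
            logger.warning("top_k=%d exceeds %d available genes", top_k, len(entries))
        entries = entries[:top_k]
    return FeatureRanking(entries=entries, method="DKMcost", fold_id=fold_id)


def gene_set_overlap(a: GeneSet | frozenset, b: GeneSet | frozenset,
                     background: set) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p for two gene sets.

    Drawing |a| genes from the background in which |b| are marked, the
    p-value is P(X >= |a & b|); an empty overlap therefore gives p = 1.
    """
    genes_a = a.genes if isinstance(a, GeneSet) else frozenset(a)
    genes_b = b.genes if isinstance(b, GeneSet) else frozenset(b)
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    if not genes_a <= background or not genes_b <= background:
        raise ValueError("gene sets must be subsets of the background")
    overlap = len(genes_a & genes_b)
    p = float(stats.hypergeom.sf(overlap - 1, len(background), len(genes_b), len(genes_a)))
    return overlap, p


def variant_fisher_screen(panel: Panel) -> pd.DataFrame:
    """Per-variant carrier-based Fisher exact screen with BH correction.

    For each variant the 2x2 table of carrier (het or hom-alt) counts in
    cases vs controls is tested (two-sided); q-values are
    Benjamini-Hochberg adjusted.  Returns a DataFrame with one row per
    variant (chrom, pos, ref, alt, carriers_cd, carriers_hc, p, q).
    """
    from statsmodels.stats.multitest import multipletests

    is_case = (panel.statuses == STATUS_CASE).to_numpy()
    n_cd, n_hc = int(is_case.sum()), int((~is_case).sum())
    carrier = (panel.genotypes == HET) | (panel.genotypes == HOM_ALT)
    carr_cd = carrier[:, is_case].sum(axis=1)
    carr_hc = carrier[:, ~is_case].sum(axis=1)
    pvals = np.empty(panel.n_variants)
    for i in range(panel.n_variants):
        table = [[carr_cd[i], n_cd - carr_cd[i]], [carr_hc[i], n_hc - carr_hc[i]]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    if len(pvals):
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = pvals
    out = panel.variants[["chrom", "pos", "ref", "alt"]].copy()
    out["carriers_cd"] = carr_cd
    out["carriers_hc"] = carr_hc
    out["p"] = pvals
    out["q"] = qvals
    return out
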