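"""Empirical-Bayes batch-effect adjustment of gene-score matrices (ComBat).

Gene scores computed from separately sequenced panels carry systematic
inter-panel ("batch") differences — different capture kits and calling
settings shift per-gene score levels regardless of disease status.  This
module implements the parametric empirical-Bayes location/scale adjustment
of Johnson, Li & Rabinovic (ComBat): per-gene standardisation against the
batch-size-weighted grand mean and pooled variance, per-batch per-gene
location (and optionally scale) estimates shrunk across genes under a
normal (and inverse-gamma) prior, then subtraction and back-transformation.

The intended use here is asymmetric: one training panel versus a single
test individual.  With a one-sample batch only location can be estimated,
so the adjustment is mean-only — the training panel's variances are left
untouched up to the back-transform — and disease labels are never consulted.
Adjusted scores may become negative; they are deliberately not clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import GeneScoreMatrix

logger = logging.getLogger(__name__)

TRAIN_BATCH = "train"
TEST_BATCH = "test"


@dataclass
class AdjustmentModel:
    """Fitted standardisation and shrinkage parameters of one adjustment."""

    genes: tuple[str, ...]
    grand_mean: np.ndarray           # per gene
    pooled_sd: np.ndarray            # per gene
    batch_levels: tuple[str, ...]
    gamma_star: np.ndarray           # batches x genes, shrunken location shifts
    delta_star: np.ndarray           # batches x genes, scale multipliers
    mean_only: bool
    parametric: bool = True


def _as_frame(matrix) -> tuple[pd.DataFrame, GeneScoreMatrix | None]:
    if isinstance(matrix, GeneScoreMatrix):
        return matrix.scores, matrix
    return matrix, None


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=100):
    """Iterative joint posterior update of location and scale (per batch)."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs((g_new - g_old) / g_old).max(),
            np.abs((d_new - d_old) / d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    matrix,
    batch_labels,
    mean_only: bool = False,
    return_model: bool = False,
):
    """Remove batch effects from an individuals x genes score matrix.

    ``batch_labels`` assigns each row (individual) to a batch; at least two
    non-empty batches are required.  A batch with a single sample forces
    mean-only adjustment (scale cannot be estimated from one sample).
    Genes with zero variance within a multi-sample batch are left
    unadjusted; a gene constant across *all* samples is a hard error —
    such genes should have been pruned upstream.

    Returns the adjusted matrix (same type, shape, and ordering as the
    input); with ``return_model=True`` also the fitted
    :class:`AdjustmentModel`.
    """
    frame, gsm = _as_frame(matrix)
    batch = pd.Series(list(batch_labels), index=frame.index)
    levels = tuple(dict.fromkeys(batch))
    if len(levels) < 2:
        raise ValueError("combat_adjust requires at least two batches")
    batch_idx = [np.flatnonzero((batch == lv).to_numpy()) for lv in levels]
    n_batches = np.array([len(ix) for ix in batch_idx])
    if (n_batches == 0).any():
        raise ValueError("every batch must be non-empty")
    if (n_batches == 1).any() and not mean_only:
        logger.info("a batch has a single sample; forcing mean-only adjustment")
        mean_only = True

    X = frame.to_numpy(dtype=float).T  # genes x samples
    G, N = X.shape

    if np.ptp(X, axis=1).min() == 0:
        raise ValueError(
            "gene constant across all samples; prune constant genes before adjusting"
        )
    # genes constant within a multi-sample batch cannot be standardised there
    unadjustable = np.zeros(G, dtype=bool)
    for ix in batch_idx:
        if len(ix) > 1:
            unadjustable |= np.ptp(X[:, ix], axis=1) == 0
    adjustable = ~unadjustable
    if unadjustable.any():
        logger.warning(
            "%d genes constant within a batch are left unadjusted", int(unadjustable.sum())
        )

    Xa = X[adjustable]
    batch_means = np.stack([Xa[:, ix].mean(axis=1) for ix in batch_idx])  # b x g
    grand_mean = (n_batches / N) @ batch_means
    resid = Xa.copy()
    for bi, ix in enumerate(batch_idx):
        resid[:, ix] -= batch_means[bi][:, None]
    var_pooled = (resid**2).sum(axis=1) / N
    sd_pooled = np.sqrt(var_pooled)
    Z = (Xa - grand_mean[:, None]) / sd_pooled[:, None]

    gamma_hat = np.stack([Z[:, ix].mean(axis=1) for ix in batch_idx])
    if mean_only:
        delta_hat = np.ones_like(gamma_hat)
    else:
        delta_hat = np.stack([Z[:, ix].var(axis=1, ddof=1) for ix in batch_idx])
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.ones_like(gamma_hat)
    for bi, ix in enumerate(batch_idx):
        if mean_only:
            gamma_star[bi] = _postmean(gamma_hat[bi], gamma_bar[bi], 1.0, 1.0, t2[bi])
        else:
            a, b = _aprior(delta_hat[bi]), _bprior(delta_hat[bi])
            gamma_star[bi], delta_star[bi] = _it_sol(
                Z[:, ix], gamma_hat[bi], delta_hat[bi], gamma_bar[bi], t2[bi], a, b
            )

    Zadj = Z.copy()
    for bi, ix in enumerate(batch_idx):
        Zadj[:, ix] = (Z[:, ix] - gamma_star[bi][:, None]) / np.sqrt(
            delta_star[bi][:, None]
        )
    Xadj = X.copy()
    Xadj[adjustable] = Zadj * sd_pooled[:, None] + grand_mean[:, None]

    out = pd.DataFrame(Xadj.T, index=frame.index, columns=frame.columns)
    if gsm is not None:
        provenance = dict(gsm.provenance)
        provenance["adjusted"] = True
        result = GeneScoreMatrix(scores=out, provenance=provenance)
    else:
        result = out
    if not return_model:
        return result
    model = AdjustmentModel(
        genes=tuple(frame.columns[adjustable]),
        grand_mean=grand_mean,
        pooled_sd=sd_pooled,
        batch_levels=levels,
        gamma_star=gamma_star,
        delta_star=delta_star,
        mean_only=mean_only,
    )
    return result, model


def adjust_test_individual(
    train_matrix: GeneScoreMatrix, test_vector: pd.Series
) -> tuple[GeneScoreMatrix, pd.Series]:
    """Adjust the training panel and one test individual toward a common mean.

    The test vector (indexed by gene, restricted to the training gene list)
    forms a singleton batch against the whole training panel; adjustment is
    mean-only and never consults class labels.  Returns the adjusted
    training matrix and the adjusted test vector, orders unchanged.
    """
    genes = list(train_matrix.scores.columns)
    if list(test_vector.index) != genes:
        if set(test_vector.index) != set(genes):
            raise ValueError("test vector genes do not match the training matrix")
        test_vector = test_vector[genes]
    test_id = test_vector.name or "__test__"
    combined = pd.concat(
        [train_matrix.scores, test_vector.to_frame(test_id).T]
    )
    batches = [TRAIN_BATCH] * len(train_matrix.scores) + [TEST_BATCH]
    adjusted = combat_adjust(combined, batches, mean_only=True)
    train_adj = GeneScoreMatrix(
        scores=adjusted.iloc[:-1].copy(),
        provenance={**train_matrix.provenance, "adjusted": True},
    )
    test_adj = adjusted.iloc[-1].copy()
    test_adj.name = test_vector.name
    return train_adj, test_adj
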