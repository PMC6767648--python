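"""Model training and family-aware cross-validation.

The classifier is a support-vector machine trained on gene-score vectors
against numeric targets +100 (case) / -100 (control); its continuous output
is the prediction score later thresholded at the calibrated cutoffs.  The
default learner is epsilon-SVR with an RBF kernel and library-default
hyperparameters (no tuning is performed); C-classification with decision
values is available behind ``ModelConfig.mode = "svc"``.

Cross-validation is leave-one-out at the family level: members of the same
family are always held out together, so a panel of n individuals with f
multi-member families yields fewer than n folds.  Feature selection runs
inside each fold on the training individuals only, and class imbalance is
handled by bootstrap-resampling the minor class.  Significance of the
cross-validated AUCs is assessed with a permutation null that reshuffles
the labels of every training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR

from .cohort import STATUS_CASE, STATUS_CONTROL
from .features import dkm_rank, select_dis, screen_by_test
from .metrics import pr_auc, roc_auc
from .scoring import GeneScoreMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Family-grouped leave-one-out folds: held-out sets partition the panel."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


@dataclass(frozen=True)
class ModelConfig:
    label_cd: float = 100.0
    label_hc: float = -100.0
    balance: int | str = "match-major"
    mode: str = "svr"  # "svr" (regression on +-100) or "svc" (decision values)
    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"
    scale_features: bool = True
    scale_targets: bool = True

    def __post_init__(self) -> None:
        if not self.label_cd > self.label_hc:
            raise ValueError("label_cd must exceed label_hc")
        if self.mode not in ("svr", "svc"):
            raise ValueError(f"unknown model mode {self.mode!r}")


@dataclass
class TrainedModel:
    """A fitted predictor bound to the exact gene list it was trained on."""

    genes: tuple[str, ...]
    estimator: object
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    config: ModelConfig
    target_mean: float = 0.0
    target_scale: float = 1.0


@dataclass
class CVResult:
    """Cross-validation outcome over repeated minor-class resampling."""

    roc_aucs: np.ndarray          # one per repeat
    pr_aucs: np.ndarray
    pr_baseline: float
    scores: pd.DataFrame          # repeats x individuals, held-out scores
    fold_gene_counts: dict[str, int]
    permutation_p: dict | None = None

    @property
    def mean_scores(self) -> pd.Series:
        return self.scores.mean(axis=0)

    def summary(self) -> dict:
        out = {
            "roc_auc_mean": float(self.roc_aucs.mean()),
            "roc_auc_sd": float(self.roc_aucs.std(ddof=1)) if len(self.roc_aucs) > 1 else 0.0,
            "pr_auc_mean": float(self.pr_aucs.mean()),
            "pr_auc_sd": float(self.pr_aucs.std(ddof=1)) if len(self.pr_aucs) > 1 else 0.0,
            "pr_baseline": self.pr_baseline,
            "n_repeats": int(len(self.roc_aucs)),
        }
        if self.permutation_p is not None:
            out["permutation_p"] = self.permutation_p
        return out


def plan_loocv_folds(phenotypes: pd.DataFrame) -> FoldPlan:
    """One fold per family group; individuals without relatives form their own.

    ``phenotypes`` is indexed by individual ID with a ``family_id`` column.
    Held-out groups appear in panel order and partition the panel.
    """
    ids = list(phenotypes.index)
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for ind in ids:
        fam = phenotypes.loc[ind, "family_id"]
        key = str(fam) if pd.notna(fam) and str(fam) != "" else f"__solo__{ind}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(ind)
    folds = []
    id_set = set(ids)
    for key in order:
        held = tuple(groups[key])
        train = tuple(i for i in ids if i not in set(held))
        folds.append((train, held))
    assert sum(len(h) for _, h in folds) == len(id_set)
    return FoldPlan(folds=tuple(folds))


def bootstrap_balance(
    train_ids: Sequence[str],
    labels: pd.Series,
    target_per_class: int | str = "match-major",
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Bootstrap-resample training IDs into balanced classes.

    ``"match-major"`` keeps every individual and adds minor-class draws
    (with replacement) until the classes match; an integer target resamples
    both classes with replacement to exactly that size.
    """
    rng = rng or np.random.default_rng()
    train_ids = list(train_ids)
    lab = labels.loc[train_ids]
    cases = [i for i in train_ids if lab[i] == STATUS_CASE]
    controls = [i for i in train_ids if lab[i] == STATUS_CONTROL]
    if not cases or not controls:
        raise ValueError("both classes must be present for balancing")
    if target_per_class == "match-major":
        if len(cases) == len(controls):
            return train_ids
        minor, major = (cases, controls) if len(cases) < len(controls) else (controls, cases)
        extra = rng.choice(minor, size=len(major) - len(minor), replace=True)
        return train_ids + list(extra)
    target = int(target_per_class)
    return list(rng.choice(cases, size=target, replace=True)) + list(
        rng.choice(controls, size=target, replace=True)
    )


def _numeric_targets(labels: pd.Series, config: ModelConfig) -> np.ndarray:
    return np.where(labels.to_numpy() == STATUS_CASE, config.label_cd, config.label_hc)


def train_model(X: pd.DataFrame, labels: pd.Series, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit the SVM on a (possibly resampled) training matrix.

    Features are standardised with training mean/sd (constant features get
    unit scale); the gene list and its order are frozen into the model.
    """
    y = _numeric_targets(labels, config)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    Xv = X.to_numpy(dtype=float)
    if np.ptp(Xv) == 0:
        logger.warning("constant feature matrix: model scores will be ~constant")
    if config.scale_features:
        mean = Xv.mean(axis=0)
        scale = Xv.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(Xv.shape[1])
        scale = np.ones(Xv.shape[1])
    Z = (Xv - mean) / scale
    y_mean, y_scale = 0.0, 1.0
    if config.mode == "svr":
        if config.scale_targets:
            # Standardise the regression targets too (as libsvm front ends
            # do); with targets of magnitude ~100 and default C the fit
            # otherwise collapses onto its intercept.
            y_mean = float(y.mean())
            y_scale = float(y.std(ddof=1))
            if y_scale == 0:
                y_scale = 1.0
            y = (y - y_mean) / y_scale
        est = SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon,
                  gamma=config.gamma)
        est.fit(Z, y)
    else:
        est = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
        est.fit(Z, y > 0)
    return TrainedModel(
        genes=tuple(X.columns), estimator=est,
        feature_mean=mean, feature_scale=scale, config=config,
        target_mean=y_mean, target_scale=y_scale,
    )


def predict_scores(model: TrainedModel, X: pd.DataFrame) -> pd.Series:
    """Continuous prediction scores for rows of ``X`` (higher = more case-like)."""
    if list(X.columns) != list(model.genes):
        if set(X.columns) != set(model.genes) or len(X.columns) != len(model.genes):
            raise ValueError("prediction matrix gene list does not match the model")
        X = X[list(model.genes)]
    Z = (X.to_numpy(dtype=float) - model.feature_mean) / model.feature_scale
    if model.config.mode == "svr":
        raw = model.estimator.predict(Z) * model.target_scale + model.target_mean
    else:
        raw = model.estimator.decision_function(Z)
    return pd.Series(raw, index=X.index)


# ---------------------------------------------------------------------------
# cross-validation machinery

_FS_ALIASES = {
    "dis": "dis", "diso": "diso", "ks": "ks", "ks5": "ks", "tt": "tt",
    "tt5": "tt", "dkm": "dkm", "dkmcost": "dkm",
}


@dataclass
class _FoldSelection:
    genes: tuple[str, ...]      # ranked top-k (dkm) or sorted set (others)
    resample: bool              # True: draw gene_count genes per repeat


def _select_fold_genes(
    train_matrix: GeneScoreMatrix,
    train_labels: pd.Series,
    fs_method: str,
    gene_count: int | None,
    fold_id: str,
    min_cases: int = 3,
    alpha: float = 0.05,
    cost_matrix=None,
    full_panel_set: frozenset | None = None,
) -> _FoldSelection:
    method = _FS_ALIASES[fs_method.lower()]
    if method == "dkm":
        ranking = dkm_rank(train_matrix, train_labels, cost_matrix=cost_matrix,
                           fold_id=fold_id)
        genes = [g for g, _ in ranking.entries]
        if gene_count is not None:
            genes = genes[: min(gene_count, len(genes))]
        return _FoldSelection(genes=tuple(genes), resample=False)
    if method == "dis":
        gs = select_dis(train_matrix, train_labels, min_cases=min_cases, fold_id=fold_id)
        genes = sorted(gs.genes)
    elif method in ("ks", "tt"):
        gs = screen_by_test(train_matrix, train_labels, test=method.upper(),
                            alpha=alpha, fold_id=fold_id)
        genes = sorted(gs.genes)
    elif method == "diso":
        # deliberate overfit sanity check: set computed on the full panel
        if full_panel_set is None:
            raise ValueError("diso requires the full-panel gene set")
        genes = sorted(full_panel_set)
    else:  # pragma: no cover
        raise ValueError(f"unknown FS method {fs_method!r}")
    resample = gene_count is not None and len(genes) > gene_count
    if gene_count is not None and len(genes) <= gene_count:
        logger.info("fold %s: %s set has %d <= %s genes; using the entire set",
                    fold_id, method, len(genes), gene_count)
    return _FoldSelection(genes=tuple(genes), resample=resample)


def select_genes_per_fold(
    matrix: GeneScoreMatrix,
    phenotypes: pd.DataFrame,
    fs_method: str = "dkm",
    gene_count: int | None = 125,
    min_cases: int = 3,
    alpha: float = 0.05,
    cost_matrix=None,
) -> dict[int, _FoldSelection]:
    """In-fold feature selection for every cross-validation fold."""
    labels = phenotypes["status"]
    folds = plan_loocv_folds(phenotypes)
    full_panel_set = None
    if _FS_ALIASES[fs_method.lower()] == "diso":
        full_panel_set = select_dis(matrix, labels, min_cases=min_cases).genes
    selections: dict[int, _FoldSelection] = {}
    for fi, (train_ids, _) in enumerate(folds):
        sub = GeneScoreMatrix(scores=matrix.scores.loc[list(train_ids)],
                              provenance=matrix.provenance)
        selections[fi] = _select_fold_genes(
            sub, labels.loc[list(train_ids)], fs_method, gene_count,
            fold_id=f"fold{fi}", min_cases=min_cases, alpha=alpha,
            cost_matrix=cost_matrix, full_panel_set=full_panel_set,
        )
    return selections


def cross_validation_scores(
    matrix: GeneScoreMatrix,
    labels: pd.Series,
    folds: FoldPlan,
    fold_genes: dict[int, Sequence[str]],
    config: ModelConfig,
    balance_target: int | str | None = None,
    rng: np.random.Generator | None = None,
    fold_train_labels: dict[int, pd.Series] | None = None,
) -> pd.Series:
    """One cross-validation pass: held-out score for every individual.

    ``fold_genes`` maps fold index to the exact gene list used for that
    fold; ``fold_train_labels`` optionally overrides the training labels of
    a fold (used by the permutation null).  Held-out individuals are never
    part of the balanced training multiset (asserted).
    """
    rng = rng or np.random.default_rng()
    balance_target = balance_target if balance_target is not None else config.balance
    out = pd.Series(np.nan, index=matrix.scores.index, dtype=float)
    for fi, (train_ids, held_ids) in enumerate(folds):
        genes = list(fold_genes[fi])
        if not genes:
            # no informative gene survived selection in this fold
            logger.warning("fold %d selected no genes; held-out scores set to 0", fi)
            out.loc[list(held_ids)] = 0.0
            continue
        train_lab = (fold_train_labels[fi] if fold_train_labels is not None
                     else labels.loc[list(train_ids)])
        balanced = bootstrap_balance(train_ids, train_lab, balance_target, rng)
        assert not set(balanced) & set(held_ids), "held-out individual leaked into training"
        X_train = matrix.scores.loc[balanced, genes]
        model = train_model(X_train, train_lab.loc[balanced], config)
        X_held = matrix.scores.loc[list(held_ids), genes]
        out.loc[list(held_ids)] = predict_scores(model, X_held).to_numpy()
    return out


def run_crossvalidation(
    matrix: GeneScoreMatrix,
    phenotypes: pd.DataFrame,
    fs_method: str = "dkm",
    gene_count: int | None = 125,
    config: ModelConfig = ModelConfig(),
    n_repeats: int = 100,
    seed: int = 0,
    min_cases: int = 3,
    alpha: float = 0.05,
    cost_matrix=None,
) -> CVResult:
    """Family-aware LOOCV with in-fold feature selection.

    Per fold, features are selected on the training individuals only.  For
    ranking selection (``dkm``) the top ``gene_count`` genes are fixed per
    fold; for set selections (``dis``/``ks5``/``tt5``) ``gene_count`` genes
    are drawn with replacement from the fold's set on every repeat, or the
    entire set is used when it is not larger than ``gene_count``.  Each
    repeat redraws the minor-class bootstrap, so with a fixed gene set the
    spread of the per-repeat AUCs reflects resampling alone.
    """
    labels = phenotypes["status"]
    folds = plan_loocv_folds(phenotypes)
    selections = select_genes_per_fold(
        matrix, phenotypes, fs_method, gene_count,
        min_cases=min_cases, alpha=alpha, cost_matrix=cost_matrix,
    )

    ss = np.random.SeedSequence(seed)
    roc_list, pr_list, score_rows = [], [], []
    baseline = float((labels == STATUS_CASE).mean())
    for rep_ss in ss.spawn(n_repeats):
        rng = np.random.default_rng(rep_ss)
        fold_genes = {}
        for fi, sel in selections.items():
            if sel.resample:
                fold_genes[fi] = list(rng.choice(sel.genes, size=gene_count, replace=True))
            else:
                fold_genes[fi] = list(sel.genes)
        scores = cross_validation_scores(matrix, labels, folds, fold_genes, config,
                                         rng=rng)
        roc_list.append(roc_auc(scores, labels.loc[scores.index]))
        pr_list.append(pr_auc(scores, labels.loc[scores.index])[0])
        score_rows.append(scores)
    return CVResult(
        roc_aucs=np.asarray(roc_list),
        pr_aucs=np.asarray(pr_list),
        pr_baseline=baseline,
        scores=pd.DataFrame(score_rows).reset_index(drop=True),
        fold_gene_counts={f"fold{fi}": len(sel.genes) for fi, sel in selections.items()},
    )


def permutation_null(
    matrix: GeneScoreMatrix,
    phenotypes: pd.DataFrame,
    fs_method: str,
    gene_count: int | None,
    observed_roc: float,
    observed_pr: float,
    config: ModelConfig = ModelConfig(),
    n_perm: int = 1000,
    seed: int = 0,
    min_cases: int = 3,
    alpha: float = 0.05,
    cost_matrix=None,
) -> dict:
    """Permutation significance of cross-validated AUCs.

    Every permutation reshuffles the labels within each training fold
    independently (class counts preserved per fold), reruns feature
    selection and training with those labels, and scores the held-out
    individuals against their true labels.  The empirical p-value counts
    permuted AUCs strictly larger than the observed one, divided by the
    number of permutations.
    """
    labels = phenotypes["status"]
    folds = plan_loocv_folds(phenotypes)
    ss = np.random.SeedSequence(seed)
    null_roc, null_pr = [], []
    for perm_ss in ss.spawn(n_perm):
        rng = np.random.default_rng(perm_ss)
        fold_genes = {}
        fold_train_labels = {}
        for fi, (train_ids, _) in enumerate(folds):
            train_ids = list(train_ids)
            shuffled = labels.loc[train_ids].to_numpy().copy()
            rng.shuffle(shuffled)
            perm_lab = pd.Series(shuffled, index=train_ids)
            fold_train_labels[fi] = perm_lab
            sub = GeneScoreMatrix(scores=matrix.scores.loc[train_ids],
                                  provenance=matrix.provenance)
            sel = _select_fold_genes(sub, perm_lab, fs_method, gene_count,
                                     fold_id=f"perm-fold{fi}", min_cases=min_cases,
                                     alpha=alpha, cost_matrix=cost_matrix)
            if sel.resample:
                fold_genes[fi] = list(rng.choice(sel.genes, size=gene_count, replace=True))
            else:
                fold_genes[fi] = list(sel.genes)
        scores = cross_validation_scores(matrix, labels, folds, fold_genes, config,
                                         rng=rng, fold_train_labels=fold_train_labels)
        null_roc.append(roc_auc(scores, labels.loc[scores.index]))
        null_pr.append(pr_auc(scores, labels.loc[scores.index])[0])
    null_roc = np.asarray(null_roc)
    null_pr = np.asarray(null_pr)
    return {
        "p_roc": float((null_roc > observed_roc).sum() / n_perm),
        "p_pr": float((null_pr > observed_pr).sum() / n_perm),
        "null_roc": null_roc,
        "null_pr": null_pr,
    }
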