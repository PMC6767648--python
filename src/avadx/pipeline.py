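"""End-to-end workflows: train with cross-validation, predict new individuals.

Training (:func:`run_train`) chains ingestion, gene scoring, pruning,
family-aware cross-validation with in-fold feature selection, evaluation
and cutoff calibration, and freezes the full-panel top-k ranked genes as
the fixed feature set for prediction.

Prediction (:func:`run_predict_individual`) mirrors the clinical setting:
the previously unseen exome is restricted to training loci, its gene
scores are batch-adjusted against the entire training panel (one-sample
batch, mean-only, labels never consulted), the training panel is
bootstrap-resampled to ``resample_target`` individuals per class, and a
fresh model is trained to score that one individual — one model per test
individual, which never sees its own data in training.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cio
from .batch import adjust_test_individual
from .cohort import Panel
from .features import dkm_rank
from .metrics import CutoffSet, evaluate_scores, select_default_cutoff
from .model import (CVResult, ModelConfig, bootstrap_balance, permutation_null,
                    run_crossvalidation, select_genes_per_fold, train_model,
                    predict_scores)
from .scoring import (DEFAULT_VSCORE, GeneScoreMatrix, VScoreParams,
                      build_gene_score_matrix, prune_genes)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every constant of the pipeline in one place (YAML-serialisable)."""

    vscore: VScoreParams = DEFAULT_VSCORE
    model: ModelConfig = ModelConfig()
    cutoffs: CutoffSet = CutoffSet()
    fs_method: str = "dkm"
    n_genes: int = 125
    alpha: float = 0.05
    min_cases: int = 3
    cv_repeats: int = 100
    n_permutations: int = 1000
    cutoff_rounds: int = 1000
    resample_target: int = 500
    min_locus_overlap: float = 0.58
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("vscore", VScoreParams), ("model", ModelConfig),
                         ("cutoffs", CutoffSet)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def ingest_panel(
    vcf_path,
    phenotype_path,
    annotation_path,
    role: str = "train",
    train_loci: set | None = None,
) -> Panel:
    """Load, filter and annotate a panel.

    ``role="train"`` applies the full training filters (autosomes, PASS,
    no missing call anywhere); ``role="test"`` keeps PASS variants and
    restricts to the supplied training loci (missing calls in a test
    individual simply contribute no score).
    """
    panel = cio.load_panel(vcf_path, phenotype_path)
    if role == "train":
        panel = cio.filter_training_variants(panel)
    elif role == "test":
        if train_loci is None:
            raise ValueError("test ingestion requires the training loci")
        panel = panel.subset_variants(
            (panel.variants["filter_status"] == "PASS").to_numpy()
        )
        panel = cio.restrict_test_variants(panel, train_loci)
    else:
        raise ValueError(f"unknown role {role!r}")
    return cio.load_annotations(panel, annotation_path)


@dataclass
class TrainArtifacts:
    """Everything a prediction run needs from training."""

    config: PipelineConfig
    phenotypes: pd.DataFrame
    matrix: GeneScoreMatrix             # pruned training gene-score matrix
    train_loci: set
    fixed_genes: tuple[str, ...]        # full-panel top-k ranked genes
    fold_gene_sets: dict[int, list[str]]
    cv: CVResult
    evaluation: dict
    default_cutoff: float | None = None
    fisher_screen: pd.DataFrame | None = None


def run_train(
    panel: Panel,
    config: PipelineConfig = PipelineConfig(),
    compute_cutoff: bool = False,
    compute_permutation: bool = False,
    compute_fisher: bool = False,
) -> TrainArtifacts:
    """Train-with-cross-validation on an ingested (filtered, annotated) panel."""
    panel.require_training_classes()
    seeds = _child_seeds(config.seed, 4)
    matrix = prune_genes(build_gene_score_matrix(panel, config.vscore))
    logger.info("run_train: %d individuals x %d genes after pruning",
                *matrix.scores.shape)

    cv = run_crossvalidation(
        matrix, panel.individuals, fs_method=config.fs_method,
        gene_count=config.n_genes, config=config.model,
        n_repeats=config.cv_repeats, seed=seeds[0],
        min_cases=config.min_cases, alpha=config.alpha,
    )
    if compute_permutation:
        cv.permutation_p = permutation_null(
            matrix, panel.individuals, config.fs_method, config.n_genes,
            observed_roc=float(cv.roc_aucs.mean()),
            observed_pr=float(cv.pr_aucs.mean()),
            config=config.model, n_perm=config.n_permutations, seed=seeds[1],
            min_cases=config.min_cases, alpha=config.alpha,
        )

    labels = panel.individuals["status"]
    evaluation = evaluate_scores(cv.mean_scores, labels.loc[cv.mean_scores.index],
                                 config.cutoffs)

    # fixed feature set for prediction: full-panel ranking
    ranking = dkm_rank(matrix, labels, top_k=config.n_genes)
    fixed_genes = tuple(g for g, _ in ranking.entries)

    selections = select_genes_per_fold(
        matrix, panel.individuals, config.fs_method, config.n_genes,
        min_cases=config.min_cases, alpha=config.alpha,
    )
    fold_gene_sets = {fi: list(sel.genes) for fi, sel in selections.items()}

    default_cutoff = None
    if compute_cutoff:
        default_cutoff = select_default_cutoff(
            matrix, panel.individuals, fold_gene_sets, config.model,
            n_rounds=config.cutoff_rounds,
            resample_target=config.resample_target, seed=seeds[2],
        )

    fisher = None
    if compute_fisher:
        from .features import variant_fisher_screen
        fisher = variant_fisher_screen(panel)

    return TrainArtifacts(
        config=config,
        phenotypes=panel.individuals,
        matrix=matrix,
        train_loci=panel.loci(),
        fixed_genes=fixed_genes,
        fold_gene_sets=fold_gene_sets,
        cv=cv,
        evaluation=evaluation,
        default_cutoff=default_cutoff,
        fisher_screen=fisher,
    )


def test_gene_scores(artifacts: TrainArtifacts, test_panel: Panel) -> pd.DataFrame:
    """Gene-score rows for test individuals over the training gene list.

    The test panel must already be restricted to training loci; genes of
    the training matrix absent from a test exome score 0.
    """
    extra = test_panel.loci() - artifacts.train_loci
    if extra:
        raise ValueError("test panel contains non-training loci; restrict it first")
    frac = len(test_panel.loci()) / len(artifacts.train_loci)
    if frac < artifacts.config.min_locus_overlap:
        warnings.warn(
            f"test panel shares only {frac:.0%} of training loci "
            f"(< {artifacts.config.min_locus_overlap:.0%}); prediction accuracy degrades",
            stacklevel=2,
        )
    m = build_gene_score_matrix(test_panel, artifacts.config.vscore)
    return m.scores.reindex(columns=artifacts.matrix.scores.columns, fill_value=0.0)


def predict_one(
    artifacts: TrainArtifacts,
    test_vector: pd.Series,
    seed: int,
) -> dict:
    """Batch-adjust, retrain and score a single test individual."""
    config = artifacts.config
    train_adj, test_adj = adjust_test_individual(artifacts.matrix, test_vector)
    rng = np.random.default_rng(seed)
    labels = artifacts.phenotypes["status"]
    balanced = bootstrap_balance(
        list(train_adj.scores.index), labels, config.resample_target, rng
    )
    genes = list(artifacts.fixed_genes)
    model = train_model(train_adj.scores.loc[balanced, genes],
                        labels.loc[balanced], config.model)
    score = float(predict_scores(model, test_adj[genes].to_frame().T).iloc[0])
    calls = {name: ("CD" if score >= cut else "HC")
             for name, cut in config.cutoffs.as_dict().items()}
    return {"score": score, "calls": calls}


def run_predict_individual(
    artifacts: TrainArtifacts,
    test_panel: Panel,
    individual_id: str,
    seed: int | None = None,
) -> dict:
    """Predict one previously unseen individual from a restricted test panel."""
    scores = test_gene_scores(artifacts, test_panel)
    if individual_id not in scores.index:
        raise KeyError(f"{individual_id!r} not in test panel")
    seed = artifacts.config.seed if seed is None else seed
    # same per-individual seed derivation as run_predict_panel, so predicting
    # one individual agrees with their row in a whole-panel run
    child = _child_seeds(seed, len(scores))
    position = list(scores.index).index(individual_id)
    return predict_one(artifacts, scores.loc[individual_id], child[position])


def run_predict_panel(
    artifacts: TrainArtifacts,
    test_panel: Panel,
    seed: int | None = None,
) -> pd.DataFrame:
    """Predict every individual of a test panel, one fresh model each."""
    scores = test_gene_scores(artifacts, test_panel)
    seed = artifacts.config.seed if seed is None else seed
    child = _child_seeds(seed, len(scores))
    rows = []
    for s, (ind, vec) in zip(child, scores.iterrows()):
        res = predict_one(artifacts, vec, s)
        rows.append({"individual_id": ind, "score": res["score"], **res["calls"]})
    out = pd.DataFrame(rows).set_index("individual_id")
    assert len(out) == len(scores)  # one fresh model per test individual
    return out
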