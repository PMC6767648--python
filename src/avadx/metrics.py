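"""Evaluation metrics and score-cutoff calibration.

Prediction scores are continuous, with positive values pointing at disease;
an individual is called a case when its score is at or above the cutoff.
Three cutoffs of increasing stringency (loose 0, default 14.3, strict 45)
trade recall for precision.  Besides the usual confusion-matrix metrics
this module provides *balanced precision* — precision standardised to equal
class sizes, computed as TPR / (TPR + FPR) — which makes precision
comparable across panels with different case/control ratios.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .cohort import STATUS_CASE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutoffSet:
    loose: float = 0.0
    default: float = 14.3
    strict: float = 45.0

    def __post_init__(self) -> None:
        if not self.loose < self.default < self.strict:
            raise ValueError("cutoffs must satisfy loose < default < strict")

    def as_dict(self) -> dict[str, float]:
        return {"loose": self.loose, "default": self.default, "strict": self.strict}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def _case_indicator(labels) -> np.ndarray:
    values = np.asarray(pd.Series(labels))
    if values.dtype == bool:
        return values
    return values == STATUS_CASE


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionCounts:
    """Tally the confusion matrix calling CD when score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    is_case = _case_indicator(labels)
    if len(scores) != len(is_case):
        raise ValueError("scores and labels must be aligned")
    called = scores >= cutoff
    return ConfusionCounts(
        tp=int((called & is_case).sum()),
        fn=int((~called & is_case).sum()),
        tn=int((~called & ~is_case).sum()),
        fp=int((called & ~is_case).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Precision, recall, FPR, F1, MCC and balanced precision from counts.

    Undefined ratios (0/0) are reported as ``None``, except MCC, which is 0
    by convention whenever a factor of its denominator vanishes.
    """
    tp, fn, tn, fp = c.tp, c.fn, c.tn, c.fp
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    fpr = fp / (fp + tn) if fp + tn else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    if recall is not None and fpr is not None and recall + fpr > 0:
        balanced_precision = recall / (recall + fpr)
    else:
        balanced_precision = None
    return {
        "precision": precision,
        "recall": recall,
        "fpr": fpr,
        "f1": f1,
        "mcc": mcc,
        "balanced_precision": balanced_precision,
    }


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal over all thresholds)."""
    is_case = _case_indicator(labels)
    if is_case.all() or not is_case.any():
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(is_case, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> tuple[float, float]:
    """Precision-recall AUC (trapezoid over recall) and its baseline.

    The baseline is the case fraction, i.e. the precision of a random
    ranker at any recall.
    """
    is_case = _case_indicator(labels)
    if is_case.all() or not is_case.any():
        raise ValueError("PR AUC needs both classes present")
    precision, recall, _ = precision_recall_curve(is_case, np.asarray(scores, dtype=float))
    # integrate along the curve as returned (recall monotonically decreasing);
    # re-sorting would scramble tied-recall points and clip area
    auc = float(-np.trapezoid(precision, recall))
    baseline = float(is_case.mean())
    return auc, baseline


def evaluate_scores(scores, labels, cutoffs: CutoffSet = CutoffSet()) -> dict:
    """Full evaluation report: AUCs plus metrics at each cutoff."""
    roc = roc_auc(scores, labels)
    pr, baseline = pr_auc(scores, labels)
    per_cutoff = {}
    for name, cut in cutoffs.as_dict().items():
        c = confusion_at_cutoff(scores, labels, cut)
        per_cutoff[name] = {
            "cutoff": cut,
            "counts": {"tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp},
            **compute_metrics(c),
        }
    return {"roc_auc": roc, "pr_auc": pr, "pr_baseline": baseline, "cutoffs": per_cutoff}


def midpoint_cutoff(scores, labels) -> float:
    """Midpoint between the class mean scores: (mean_CD + mean_HC) / 2."""
    scores = np.asarray(scores, dtype=float)
    is_case = _case_indicator(labels)
    return float((scores[is_case].mean() + scores[~is_case].mean()) / 2.0)


def select_default_cutoff(
    matrix,
    phenotypes: pd.DataFrame,
    fold_gene_sets: dict,
    config=None,
    n_rounds: int = 1000,
    resample_target: int = 500,
    seed: int = 0,
) -> float:
    """Calibrate the default score cutoff on training cross-validation.

    Each round repeats the family-aware cross-validation with both classes
    resampled to ``resample_target`` individuals, pools the held-out scores
    and takes the midpoint between the case and control mean scores.  The
    returned cutoff is the most common per-round value after rounding to
    one decimal (smallest value on ties, for determinism).
    """
    from .model import ModelConfig, cross_validation_scores, plan_loocv_folds

    config = config or ModelConfig()
    folds = plan_loocv_folds(phenotypes)
    labels = phenotypes["status"]
    ss = np.random.SeedSequence(seed)
    cutoffs = []
    for round_ss in ss.spawn(n_rounds):
        scores = cross_validation_scores(
            matrix, labels, folds, fold_gene_sets, config,
            balance_target=resample_target, rng=np.random.default_rng(round_ss),
        )
        cutoffs.append(round(midpoint_cutoff(scores, labels.loc[scores.index]), 1))
    counts = Counter(cutoffs)
    best = max(counts.values())
    return float(min(v for v, n in counts.items() if n == best))
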