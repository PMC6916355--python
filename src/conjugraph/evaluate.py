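"""Scoring of edge rankings against a known graph: ROC and PR areas.

Scores are "higher = more evidence for an edge"; when scoring the Bayes
factor pipeline, pass the negated tail probabilities.  The PR area uses
step-wise integration over achieved recall levels (no interpolation
between recall points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)


def _check(scores, truth):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be 1-D arrays of equal length")
    if truth.all() or not truth.any():
        raise ValueError("truth vector must contain both edges and non-edges")
    return scores, truth


def auc_roc(scores, truth) -> float:
    """Area under the ROC curve of the ranking (ties averaged)."""
    scores, truth = _check(scores, truth)
    return float(roc_auc_score(truth, scores))


def auc_pr(scores, truth) -> float:
    """Area under the precision-recall step curve of the ranking."""
    scores, truth = _check(scores, truth)
    return float(average_precision_score(truth, scores))


@dataclass
class RankingEvaluation:
    auc_roc: float
    auc_pr: float
    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray


def evaluate_ranking(scores, truth) -> RankingEvaluation:
    """Both areas plus the ROC and PR curve points."""
    scores, truth = _check(scores, truth)
    fpr, tpr, _ = roc_curve(truth, scores)
    precision, recall, _ = precision_recall_curve(truth, scores)
    return RankingEvaluation(
        auc_roc=float(roc_auc_score(truth, scores)),
        auc_pr=float(average_precision_score(truth, scores)),
        fpr=fpr, tpr=tpr, recall=recall, precision=precision,
    )
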