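"""Multi-label evaluation: confusion counts, F/G measures, ranking metrics
and the weighted normalized Challenge score.

Per-class F-beta and G-beta follow the printed competition formulas

    F_beta = (1 + beta^2) TP / ((1 + beta^2) TP + FP + beta^2 FN)
    G_beta = TP / (TP + FP + beta FN)

with macro averages taken over classes that actually occur (a class absent
from both truth and prediction is excluded and logged).  The weighted score
uses the Challenge's modified multi-label confusion allocation: each
record's credit is row-normalised by the size of the union of its true and
predicted label sets, weighted by a class-by-class reward matrix, then
normalised between an "inactive" classifier that always outputs the normal
rhythm (score 0) and a perfect one (score 1).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import ClassVocabulary

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN over a multi-label prediction set."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    classes: list[str]

    @property
    def n_records(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0]) if len(self.classes) else 0

    def precision(self) -> np.ndarray:
        denom = self.tp + self.fp
        return np.where(denom > 0, self.tp / np.maximum(denom, 1), 0.0)

    def recall(self) -> np.ndarray:
        denom = self.tp + self.fn
        return np.where(denom > 0, self.tp / np.maximum(denom, 1), 0.0)


def _check_binary_pair(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 2:
        raise ValueError(f"label matrices must share a 2-D shape, "
                         f"got {y_true.shape} vs {y_pred.shape}")
    return y_true, y_pred


def confusion(y_true: np.ndarray, y_pred: np.ndarray,
              classes: list[str] | None = None) -> ConfusionCounts:
    """Column-wise confusion counts for aligned binary label matrices."""
    y_true, y_pred = _check_binary_pair(y_true, y_pred)
    tp = np.sum((y_true == 1) & (y_pred == 1), axis=0).astype(float)
    fp = np.sum((y_true == 0) & (y_pred == 1), axis=0).astype(float)
    fn = np.sum((y_true == 1) & (y_pred == 0), axis=0).astype(float)
    tn = np.sum((y_true == 0) & (y_pred == 0), axis=0).astype(float)
    if classes is None:
        classes = [f"class_{i}" for i in range(y_true.shape[1])]
    return ConfusionCounts(tp, fp, fn, tn, list(classes))


def f_measure(counts: ConfusionCounts, beta: float = 1.0) -> tuple[np.ndarray, float]:
    """Per-class and macro F-beta; classes with TP=FP=FN=0 are excluded (NaN)."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    b2 = beta ** 2
    denom = (1 + b2) * counts.tp + counts.fp + b2 * counts.fn
    per_class = np.full(len(counts.classes), np.nan)
    defined = denom > 0
    per_class[defined] = (1 + b2) * counts.tp[defined] / denom[defined]
    if not np.all(defined):
        logger.info("f_measure: %d empty class(es) excluded from macro",
                    int(np.sum(~defined)))
    macro = float(np.nanmean(per_class)) if np.any(defined) else float("nan")
    return per_class, macro


def g_measure(counts: ConfusionCounts, beta: float = 2.0) -> tuple[np.ndarray, float]:
    """Per-class and macro G-beta = TP / (TP + FP + beta FN)."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    denom = counts.tp + counts.fp + beta * counts.fn
    per_class = np.full(len(counts.classes), np.nan)
    defined = denom > 0
    per_class[defined] = counts.tp[defined] / denom[defined]
    macro = float(np.nanmean(per_class)) if np.any(defined) else float("nan")
    return per_class, macro


@dataclass
class RankMetrics:
    auroc: np.ndarray
    auprc: np.ndarray
    macro_auroc: float
    macro_auprc: float


def rank_metrics(y_true: np.ndarray, y_score: np.ndarray) -> RankMetrics:
    """Per-class AUROC (trapezoid, ties averaged) and AUPRC (step-wise).

    Columns without both a positive and a negative example are undefined
    (NaN) and excluded from the macro means.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape or y_true.ndim != 2:
        raise ValueError("y_true and y_score must share a 2-D shape")
    if not np.all(np.isfinite(y_score)):
        raise ValueError("scores must be finite")
    n_classes = y_true.shape[1]
    auroc = np.full(n_classes, np.nan)
    auprc = np.full(n_classes, np.nan)
    for j in range(n_classes):
        col = y_true[:, j]
        if 0 < col.sum() < col.size:
            auroc[j] = roc_auc_score(col, y_score[:, j])
            auprc[j] = average_precision_score(col, y_score[:, j])
        else:
            logger.info("rank_metrics: class %d single-valued, excluded", j)
    macro_auroc = float(np.nanmean(auroc)) if np.any(np.isfinite(auroc)) else float("nan")
    macro_auprc = float(np.nanmean(auprc)) if np.any(np.isfinite(auprc)) else float("nan")
    return RankMetrics(auroc, auprc, macro_auroc, macro_auprc)


@dataclass
class RewardMatrix:
    """Class-by-class credit weights for the Challenge score.

    Diagonal entries should be 1 (a correct label earns full credit); other
    entries encode how benign a particular confusion is.  The identity
    matrix — full credit only for exact labels — is the built-in default.
    """

    weights: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.classes)
        if self.weights.shape != (n, n):
            raise ValueError(f"weight matrix shape {self.weights.shape} "
                             f"does not match {n} classes")
        if not np.allclose(np.diag(self.weights), 1.0):
            logger.warning("reward matrix diagonal is not all ones")
        if np.any((self.weights < 0) | (self.weights > 1)):
            logger.warning("reward matrix has entries outside [0, 1]")

    @classmethod
    def identity(cls, vocab: ClassVocabulary) -> "RewardMatrix":
        return cls(np.eye(vocab.n_classes), vocab.abbreviations)

    @classmethod
    def from_csv(cls, path: str | Path, vocab: ClassVocabulary) -> "RewardMatrix":
        """CSV with class abbreviations as header row/column, reordered to the vocabulary."""
        with open(path, newline="", encoding="utf-8") as fh:
            rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
        header = [h.strip() for h in rows[0][1:]]
        data = {r[0].strip(): [float(v) for v in r[1:]] for r in rows[1:]}
        idx = {h: i for i, h in enumerate(header)}
        n = vocab.n_classes
        w = np.zeros((n, n))
        for i, a in enumerate(vocab.abbreviations):
            for j, b in enumerate(vocab.abbreviations):
                w[i, j] = data[a][idx[b]]
        return cls(w, vocab.abbreviations)


def _modified_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Multi-label confusion allocation: each record spreads unit credit
    across true x predicted label pairs, normalised by |union|."""
    n_classes = y_true.shape[1]
    a = np.zeros((n_classes, n_classes))
    for t_row, p_row in zip(y_true, y_pred):
        union = float(np.sum((t_row == 1) | (p_row == 1)))
        norm = max(union, 1.0)
        ti = np.flatnonzero(t_row)
        pi = np.flatnonzero(p_row)
        for i in ti:
            a[i, pi] += 1.0 / norm
    return a


@dataclass
class ChallengeScore:
    raw: float
    normalized: float
    perfect: float
    inactive: float


def challenge_score(y_true: np.ndarray, y_pred: np.ndarray, weights: RewardMatrix,
                    vocab: ClassVocabulary | None = None) -> ChallengeScore:
    """Weighted normalized Challenge score.

    ``normalized = (raw - inactive) / (perfect - inactive)`` where the
    perfect classifier reproduces the truth and the inactive one predicts
    only the normal-rhythm class for every record.
    """
    y_true, y_pred = _check_binary_pair(y_true, y_pred)
    vocab = vocab or ClassVocabulary.load()
    if y_true.shape[1] != vocab.n_classes:
        raise ValueError("label matrices not aligned to the vocabulary")
    normal_idx = vocab.index_of(vocab.normal_class)

    def score_of(pred: np.ndarray) -> float:
        return float(np.sum(weights.weights * _modified_confusion(y_true, pred)))

    raw = score_of(y_pred)
    perfect = score_of(y_true)
    inactive_pred = np.zeros_like(y_true)
    inactive_pred[:, normal_idx] = 1
    inactive = score_of(inactive_pred)
    if np.isclose(perfect, inactive):
        raise ValueError("degenerate normalization: the perfect and inactive "
                         "classifiers score identically on this truth set")
    return ChallengeScore(raw, (raw - inactive) / (perfect - inactive), perfect, inactive)
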