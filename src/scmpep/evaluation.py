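"""Binary-classification metrics and stratified cross-validation.

Implements the five standard measures used for peptide classifiers —
accuracy, sensitivity, specificity, Matthews correlation coefficient and the
area under the ROC curve — plus seeded stratified k-fold cross-validation
with pooled out-of-fold predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """ACC / Sn / Sp / MCC / AUC bundle.

    acc = (TP+TN)/N, sn = TP/(TP+FN), sp = TN/(TN+FP),
    mcc = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    auc = P(score+ > score-) + 0.5*P(tie).
    """

    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {"ACC": self.acc, "Sn": self.sn, "Sp": self.sp,
                "MCC": self.mcc, "AUC": self.auc}

    def to_tsv(self) -> str:
        d = self.as_dict()
        head = "\t".join(d)
        vals = "\t".join("NA" if v is None else f"{v:.4f}" for v in d.values())
        return f"{head}\n{vals}\n"


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """2x2 contingency of binary predictions against binary labels."""
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(labels)} labels"
        )
    if len(labels) == 0:
        raise ValueError("empty input")
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (y == 1))),
        tn=int(np.sum((p == 0) & (y == 0))),
        fp=int(np.sum((p == 1) & (y == 0))),
        fn=int(np.sum((p == 0) & (y == 1))),
    )


def _safe_div(num: float, den: float, default: float = 0.0) -> float:
    return num / den if den != 0 else default


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        logger.debug("MCC denominator zero (counts %s); returning 0 by convention", c)
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank statistic with midrank tie handling.

    Equals the probability that a random positive outscores a random
    negative, ties counted half — identical to the trapezoidal area under
    the ROC curve over all thresholds.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def metrics(counts: ConfusionCounts,
            scores: Sequence[float] | None = None,
            labels: Sequence[int] | None = None) -> MetricSet:
    """Full metric bundle from confusion counts, AUC if scores are supplied."""
    a = _safe_div(counts.tp + counts.tn, counts.total)
    sn = _safe_div(counts.tp, counts.tp + counts.fn)
    sp = _safe_div(counts.tn, counts.tn + counts.fp)
    m = mcc_from_counts(counts)
    a_uc = auc(scores, labels) if scores is not None and labels is not None else None
    return MetricSet(acc=a, sn=sn, sp=sp, mcc=m, auc=a_uc)


def evaluate_predictions(predictions: Sequence[int], labels: Sequence[int],
                         scores: Sequence[float] | None = None) -> MetricSet:
    return metrics(confusion(predictions, labels), scores, labels)


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment; returns fold index per sample.

    Within each class, samples are shuffled and dealt round-robin to the k
    folds, so fold class balance matches the dataset's within one sample.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (0, 1):
        if np.sum(y == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def cross_validate(train, card_builder: Callable, k: int = 10,
                   seed: int = 0) -> MetricSet:
    """Stratified k-fold CV of a card-building procedure.

    ``card_builder(fold_train: LabeledDataset) -> ScoreCard`` must return a
    card with its cutoff set. Out-of-fold predictions and scores are pooled
    into a single MetricSet.
    """
    from .scoring_card import classify_score, score_dataset

    y = np.asarray(train.labels, dtype=int)
    folds = stratified_folds(y, k, seed)
    oof_scores = np.empty(len(y))
    oof_preds = np.empty(len(y), dtype=int)
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        card = card_builder(train.subset(train_idx, name=f"{train.name}.fold{fold}"))
        if card.cutoff is None:
            raise ValueError("card_builder must return a card with a cutoff")
        s = score_dataset([train.peptides[i].seq for i in test_idx], card)
        oof_scores[test_idx] = s
        oof_preds[test_idx] = [classify_score(v, card.cutoff) for v in s]
    return evaluate_predictions(oof_preds, y, oof_scores)


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> list[tuple[float, float, float]]:
    """ROC curve as (fpr, tpr, threshold) triples over all distinct scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = np.sum(y == 1)
    n_neg = np.sum(y == 0)
    points = [(0.0, 0.0, np.inf)]
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tpr = np.sum(pred & (y == 1)) / n_pos
        fpr = np.sum(pred & (y == 0)) / n_neg
        points.append((float(fpr), float(tpr), float(t)))
    return points
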