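"""Operating-threshold selection, majority-vote ensembling, and metrics.

Each fine-tuned CNN gets its own operating threshold, chosen on that model's
validation fold as the point of maximum recall subject to a precision floor
(default 90%, clean = positive class). Three thresholded CNNs are combined by
majority vote into the final clean-vs-artifact classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .model import CNNClassifier


class CalibrationError(RuntimeError):
    """No threshold attains the required precision floor.

    Carries the maximum precision attainable on the validation data so the
    caller can decide whether to relax the floor.
    """

    def __init__(self, floor: float, max_precision: float):
        self.floor = floor
        self.max_precision = max_precision
        super().__init__(
            f"no threshold reaches precision >= {floor:.3f}; "
            f"maximum attainable is {max_precision:.3f}"
        )


def select_threshold(
    scores: np.ndarray, truths: np.ndarray, precision_floor: float = 0.90
) -> float:
    """Maximum-recall threshold subject to precision >= ``precision_floor``.

    Candidates are the distinct observed scores plus the sentinels 0 (accept
    everything) and just-above-max (reject everything); optimal operating
    points lie at score order statistics. Ties are broken toward higher
    precision, then lower threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths).astype(np.int64)
    if scores.shape != truths.shape or scores.ndim != 1:
        raise ValueError("scores and truths must be equal-length vectors")
    pos = truths.sum()
    if pos == 0 or pos == truths.size:
        raise ValueError("both classes must be present to calibrate")

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = truths[order]
    # suffix sums: predictions at threshold t are scores >= t
    suffix_tp = np.cumsum(t_sorted[::-1])[::-1]
    n = scores.size
    candidates = np.unique(np.concatenate([[0.0], s_sorted]))
    best = None  # (recall, precision, -threshold)
    max_prec = 0.0
    for t in candidates:
        i = np.searchsorted(s_sorted, t, side="left")
        n_pred = n - i
        if n_pred == 0:
            continue
        tp = suffix_tp[i] if i < n else 0
        precision = tp / n_pred
        recall = tp / pos
        max_prec = max(max_prec, precision)
        if precision >= precision_floor:
            key = (recall, precision, -t)
            if best is None or key > best[0]:
                best = (key, t)
    if best is None:
        raise CalibrationError(precision_floor, max_prec)
    return float(best[1])


def apply_threshold(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Label 1 (clean) iff score >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    return (np.asarray(scores, dtype=np.float64) >= threshold).astype(np.int64)


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Label held by at least 2 of exactly 3 members; permutation-invariant."""
    votes = np.asarray(votes, dtype=np.int64)
    if votes.ndim == 1:
        votes = votes[None, :]
    if votes.shape[1] != 3:
        raise ValueError(f"expected exactly 3 votes per segment, got {votes.shape[1]}")
    return (votes.sum(axis=1) >= 2).astype(np.int64)


@dataclass
class EvaluationReport:
    """Confusion counts (clean = positive) and the derived metrics.

    Ratios with a zero denominator are ``None`` (reported as missing), never
    silently zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "EvaluationReport":
        n = tp + fp + tn + fn
        if n == 0:
            raise ValueError("empty evaluation")

        def ratio(num: int, den: int, name: str) -> float | None:
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
                return None
            return num / den

        precision = ratio(tp, tp + fp, "precision")
        recall = ratio(tp, tp + fn, "recall")
        specificity = ratio(tn, tn + fp, "specificity")
        if precision is None or recall is None or (precision + recall) == 0:
            f1 = None
            if precision is not None and recall is not None:
                warnings.warn("f1 undefined (precision + recall = 0)", stacklevel=3)
        else:
            f1 = 2 * precision * recall / (precision + recall)
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            accuracy=(tp + tn) / n,
            precision=precision, recall=recall,
            specificity=specificity, f1=f1,
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity, "f1": self.f1,
        }


def evaluate_metrics(pred: np.ndarray, truth: np.ndarray) -> EvaluationReport:
    """Confusion counts and metrics with clean (1) as the positive class."""
    pred = np.asarray(pred).astype(np.int64)
    truth = np.asarray(truth).astype(np.int64)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if pred.size == 0:
        raise ValueError("empty evaluation")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return EvaluationReport.from_counts(tp, fp, tn, fn)


class MajorityVoteEnsemble(ClassifierMixin, BaseEstimator):
    """Three (CNN, threshold) pairs combined by majority vote.

    Built by :func:`calibrate_ensemble`; ``members`` is a list of exactly
    three ``(CNNClassifier, threshold)`` pairs, each threshold selected on
    that member's own validation fold.
    """

    def __init__(self, members: list[tuple[CNNClassifier, float]] | None = None):
        self.members = members

    def _check(self) -> list[tuple[CNNClassifier, float]]:
        if not self.members or len(self.members) != 3:
            raise ValueError("ensemble requires exactly 3 (model, threshold) members")
        return self.members

    @property
    def thresholds_(self) -> list[float]:
        return [t for _, t in self._check()]

    def member_scores(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict_scores(X) for m, _ in self._check()])

    def member_votes(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [apply_threshold(m.predict_scores(X), t) for m, t in self._check()]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return majority_vote(self.member_votes(X))


def calibrate_ensemble(
    models: Sequence[CNNClassifier],
    val_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    precision_floor: float = 0.90,
) -> MajorityVoteEnsemble:
    """Select each model's threshold on its own validation fold and ensemble.

    ``val_sets[i]`` is ``(X_val, y_binary)`` for model i.
    """
    if len(models) != 3 or len(val_sets) != 3:
        raise ValueError("majority voting requires exactly 3 models with val sets")
    members = []
    for model, (X_val, y_val) in zip(models, val_sets):
        scores = model.predict_scores(X_val)
        thr = select_threshold(scores, y_val, precision_floor)
        members.append((model, thr))
    return MajorityVoteEnsemble(members=members)
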