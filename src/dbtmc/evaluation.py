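"""Evaluation protocol for benign/malignant microcalcification classification.

Malignant is the positive class throughout: sensitivity is the malignant
detection rate, specificity the benign one, and a specificity deficit means
extra false positives (benign lesions sent to biopsy).

Two evaluation levels are supported.  At the *view* level each acquisition
(CC or MLO) of a lesion counts as an independent sample; at the *lesion*
level the malignancy scores of all views of a lesion are averaged into a
single score before thresholding or ranking.

``recover_confusion_counts`` inverts printed sensitivity/specificity
percentages back to the unique integer confusion matrix on a known test
composition, which lets published metric tables be checked end to end from
their own numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "PredictionRecord",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "roc_auc",
    "aggregate_lesion_level",
    "recover_confusion_counts",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-class confusion counts with malignant as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class MetricsReport:
    """Proportion metrics derived from a confusion matrix, plus optional AUC.

    Undefined ratios (zero denominator) are reported as ``math.nan`` rather
    than silently coerced to 0.
    """

    acc: float
    sen: float
    spec: float
    precision: float
    recall: float
    f1: float
    auc: float = math.nan
    level: str = "view"
    n_pos: int = 0
    n_neg: int = 0

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spec": self.spec,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "level": self.level,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass(frozen=True)
class PredictionRecord:
    """One model score for one view (or one lesion after aggregation)."""

    lesion_id: str
    view: str
    label: int  # 1 = malignant, 0 = benign
    p_malignant: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_malignant <= 1.0:
            raise ValueError(f"p_malignant out of [0,1]: {self.p_malignant}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def confusion_from_predictions(
    preds: Sequence[PredictionRecord], threshold: float = 0.5
) -> ConfusionMatrix:
    """Threshold scores into a confusion matrix.

    A score exactly at the threshold counts as a positive (malignant) call;
    this tie convention is fixed and documented rather than configurable.
    """
    if len(preds) == 0:
        raise ValueError("no predictions given")
    tp = fn = fp = tn = 0
    for r in preds:
        called_pos = r.p_malignant >= threshold
        if r.label == 1:
            tp += called_pos
            fn += not called_pos
        else:
            fp += called_pos
            tn += not called_pos
    return ConfusionMatrix(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_confusion(cm: ConfusionMatrix, level: str = "view") -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, recall and F1.

    ACC = (TP+TN)/(TP+FP+TN+FN); SEN = Recall = TP/(TP+FN);
    SPEC = TN/(TN+FP); Precision = TP/(TP+FP);
    F1 = 2*Precision*Recall/(Precision+Recall).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is all zeros")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        acc=(cm.tp + cm.tn) / cm.total,
        sen=recall,
        spec=_ratio(cm.tn, cm.tn + cm.fp),
        precision=precision,
        recall=recall,
        f1=f1,
        level=level,
        n_pos=cm.n_pos,
        n_neg=cm.n_neg,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve as the normalized rank statistic.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, with ties counted half — identically the
    trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aggregate_lesion_level(
    preds: Sequence[PredictionRecord],
) -> list[PredictionRecord]:
    """Collapse view-level scores to lesion level by unweighted averaging.

    All views of a lesion must carry the same label; the averaged record
    keeps insertion order of first appearance and view ``"*"``.
    """
    by_lesion: dict[str, list[PredictionRecord]] = {}
    for r in preds:
        by_lesion.setdefault(r.lesion_id, []).append(r)
    out = []
    for lesion_id, records in by_lesion.items():
        labels = {r.label for r in records}
        if len(labels) != 1:
            raise ValueError(f"conflicting labels within lesion {lesion_id}")
        p = float(np.mean([r.p_malignant for r in records]))
        out.append(
            PredictionRecord(
                lesion_id=lesion_id, view="*", label=records[0].label, p_malignant=p
            )
        )
    return out


def _round_half_up_2(x: Fraction) -> Fraction:
    """Round a percentage (as an exact Fraction) half-up to 2 decimals."""
    return Fraction(math.floor(x * 100 + Fraction(1, 2)), 100)


def recover_confusion_counts(
    sen_pct: float, spec_pct: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Invert printed SEN/SPEC percentages to integer confusion counts.

    Exhaustively searches TP in [0, n_pos] and TN in [0, n_neg] for counts
    whose percentages round (half-up, two decimals) to the printed values.
    Raises if no solution exists (a transcription problem) or if several do
    (the printed precision does not pin the counts down).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    sen_target = Fraction(str(sen_pct))
    spec_target = Fraction(str(spec_pct))
    tps = [
        tp
        for tp in range(n_pos + 1)
        if _round_half_up_2(Fraction(100 * tp, n_pos)) == sen_target
    ]
    tns = [
        tn
        for tn in range(n_neg + 1)
        if _round_half_up_2(Fraction(100 * tn, n_neg)) == spec_target
    ]
    if not tps or not tns:
        raise ValueError(
            f"no integer counts reproduce SEN={sen_pct}%, SPEC={spec_pct}% "
            f"on {n_pos}+{n_neg} samples"
        )
    if len(tps) > 1 or len(tns) > 1:
        raise ValueError(
            f"ambiguous recovery: TP candidates {tps}, TN candidates {tns}"
        )
    tp, tn = tps[0], tns[0]
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)


def evaluate_predictions(
    preds: Sequence[PredictionRecord],
    level: str = "view",
    threshold: float = 0.5,
) -> MetricsReport:
    """Full metric report (including AUC) at view or lesion level."""
    if level not in ("view", "lesion"):
        raise ValueError(f"unknown level {level!r}")
    if level == "lesion":
        preds = aggregate_lesion_level(preds)
    cm = confusion_from_predictions(preds, threshold=threshold)
    auc = roc_auc([r.p_malignant for r in preds], [r.label for r in preds])
    base = metrics_from_confusion(cm, level=level)
    return MetricsReport(**{**base.as_dict(), "auc": auc})
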