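"""Window-level metric suite and the resampling significance procedure.

Metrics: ROC AUC, area under the precision-recall curve (AUPRC, whose
uninformative baseline equals the positive prevalence), class-proportion-
weighted F1, positive-class precision/recall, and weighted accuracy

    WAcc = (w * TP + TN) / (w * (TP + FN) + (TN + FP)),   w = #neg / #pos,

which rebalances accuracy so each class contributes equally regardless of
imbalance. AUC/AUPRC/F1 are computed with scikit-learn; the weighted
accuracy formula is implemented directly.

Model comparison uses a paired resampling test: repeatedly draw 1500
positive windows and 1500*R negatives (R the negative:positive ratio, so
the original imbalance is preserved), score both models on the same draw,
and report the fraction of repeats in which model ``a`` fails to beat
model ``b`` (ties count half, so identical models give p = 0.5).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "ScoredSet",
    "MetricReport",
    "compute_metrics",
    "weighted_accuracy",
    "significance_compare",
]


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_scores(scores: np.ndarray, labels: np.ndarray, threshold: float) -> "ConfusionCounts":
        pred = np.asarray(scores) > threshold
        labels = np.asarray(labels).astype(bool)
        return ConfusionCounts(
            tp=int((pred & labels).sum()),
            fp=int((pred & ~labels).sum()),
            tn=int((~pred & ~labels).sum()),
            fn=int((~pred & labels).sum()),
        )


@dataclasses.dataclass
class ScoredSet:
    """Scores in [0,1] with binary labels; the unit the metrics act on."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = self.labels.astype(np.int64)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean()) if len(self.labels) else float("nan")

    def class_weights(self) -> tuple[float, float]:
        """(w_neg, w_pos): class proportions of the set."""
        p = self.prevalence
        return (1.0 - p, p)


def weighted_accuracy(c: ConfusionCounts) -> float | None:
    """Dong-style rebalanced accuracy; None when a class is absent."""
    n_pos = c.tp + c.fn
    n_neg = c.tn + c.fp
    if n_pos == 0 or n_neg == 0:
        return None
    w = n_neg / n_pos
    return (w * c.tp + c.tn) / (w * n_pos + n_neg)


@dataclasses.dataclass
class MetricReport:
    auc: float | None
    auprc: float | None
    auprc_baseline: float
    weighted_f1: float
    precision: float
    recall: float
    weighted_accuracy: float | None
    confusion: ConfusionCounts
    threshold: float
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auprc": self.auprc,
            "auprc_baseline": self.auprc_baseline,
            "weighted_f1": self.weighted_f1,
            "precision": self.precision,
            "recall": self.recall,
            "weighted_accuracy": self.weighted_accuracy,
            "threshold": self.threshold,
            "confusion": dataclasses.asdict(self.confusion),
        }


def compute_metrics(s: ScoredSet, threshold: float = 0.5) -> MetricReport:
    """Full metric report at the given decision threshold.

    With single-class labels the ranking metrics (AUC/AUPRC) are undefined
    and reported as None with a warning; the confusion-based metrics are
    still returned.
    """
    notes: list[str] = []
    both = len(np.unique(s.labels)) == 2
    if both:
        auc = float(roc_auc_score(s.labels, s.scores))
        auprc = float(average_precision_score(s.labels, s.scores))
    else:
        auc = auprc = None
        notes.append("AUC/AUPRC undefined: labels contain a single class")
    conf = ConfusionCounts.from_scores(s.scores, s.labels, threshold)
    pred = (s.scores > threshold).astype(int)
    wf1 = float(f1_score(s.labels, pred, average="weighted", zero_division=0))
    precision = conf.tp / (conf.tp + conf.fp) if conf.tp + conf.fp else 0.0
    recall = conf.tp / (conf.tp + conf.fn) if conf.tp + conf.fn else 0.0
    return MetricReport(
        auc=auc,
        auprc=auprc,
        auprc_baseline=s.prevalence,
        weighted_f1=wf1,
        precision=precision,
        recall=recall,
        weighted_accuracy=weighted_accuracy(conf),
        confusion=conf,
        threshold=threshold,
        warnings=notes,
    )


_METRIC_FUNCS = {
    "auc": lambda sc, la: roc_auc_score(la, sc),
    "auprc": lambda sc, la: average_precision_score(la, sc),
}


def significance_compare(
    a: ScoredSet,
    b: ScoredSet,
    n_pos: int = 1500,
    repeats: int = 100,
    rng_state: np.random.Generator | None = None,
    metrics: tuple[str, ...] = ("auc", "auprc"),
    continuity: bool = False,
) -> dict[str, float]:
    """Paired one-sided resampling comparison of two models on the same windows.

    Per repeat, ``n_pos`` positives and ``n_pos * R`` negatives are drawn
    (R = #neg/#pos of the full set, preserving the original imbalance) and
    each metric is computed for both models on the same draw. The p-value
    for "a beats b" is the fraction of repeats where it does not, with ties
    counted half; ``continuity`` applies the (x+1)/(repeats+1) correction.
    """
    if not np.array_equal(a.labels, b.labels):
        raise ValueError("a and b must score the same windows (labels differ)")
    rng = rng_state if rng_state is not None else np.random.default_rng(0)
    pos_idx = np.flatnonzero(a.labels == 1)
    neg_idx = np.flatnonzero(a.labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    ratio = len(neg_idx) / len(pos_idx)
    n_neg = max(1, int(round(n_pos * ratio)))
    replace_pos = len(pos_idx) < n_pos
    replace_neg = len(neg_idx) < n_neg
    if replace_pos or replace_neg:
        warnings.warn("fewer windows than the resample size; sampling with replacement")
    wins = {m: 0.0 for m in metrics}
    for _ in range(repeats):
        pi = rng.choice(pos_idx, size=n_pos, replace=replace_pos)
        ni = rng.choice(neg_idx, size=n_neg, replace=replace_neg)
        idx = np.concatenate([pi, ni])
        labels = a.labels[idx]
        for m in metrics:
            ma = _METRIC_FUNCS[m](a.scores[idx], labels)
            mb = _METRIC_FUNCS[m](b.scores[idx], labels)
            if ma < mb:
                wins[m] += 1.0
            elif ma == mb:
                wins[m] += 0.5
    if continuity:
        return {m: (wins[m] + 1.0) / (repeats + 1.0) for m in metrics}
    return {m: wins[m] / repeats for m in metrics}
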