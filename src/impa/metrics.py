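"""Binary-classification metric suite.

Accuracy, sensitivity, specificity and precision from the 2x2 confusion
table; macro-averaged F-score; AUC from the Mann-Whitney rank-sum
formula

    AUC = (sum of positive ranks - I_t (I_t + 1) / 2) / (I_t * I_f)

with mid-ranks for tied scores, where I_t and I_f are the positive and
negative counts.  Also the percentage-point improvement tables used to
compare an optimized model with a manually configured baseline, and the
per-split sample accounting used when reporting dataset compositions.

Class 1 is the positive (abnormal / cancer) class throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "ScoredPredictions",
    "MetricsReport",
    "confusion",
    "basic_metrics",
    "f_score",
    "auc_rank",
    "improvement",
    "dataset_accounting",
    "report_from_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally: true/false positives and negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def flipped(self) -> "ConfusionCounts":
        """Counts for the complementary class labelling."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class ScoredPredictions:
    """Continuous scores with binary ground-truth labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length vectors")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(self.labels.size - self.labels.sum())


def _binary_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(int)


def confusion(labels, predictions) -> ConfusionCounts:
    """Tally the 2x2 confusion table (class 1 = positive)."""
    y = _binary_vector(labels, "labels")
    p = _binary_vector(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def basic_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, precision).

    A zero denominator yields NaN as the undefined marker rather than
    raising.
    """
    if c.total < 1:
        raise ValueError("at least one observation is required")
    acc = _ratio(c.tp + c.tn, c.total)
    sn = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    pr = _ratio(c.tp, c.tp + c.fp)
    return acc, sn, sp, pr


def f_score(per_class_counts: Sequence[ConfusionCounts], q: int | None = None) -> float:
    """Macro-averaged F-score over ``q`` classes.

    Per class, F1_j is the harmonic mean of precision and sensitivity;
    a class with Pr + Sn = 0 contributes 0 with a warning.
    """
    counts = list(per_class_counts)
    if q is None:
        q = len(counts)
    if q < 1 or q != len(counts):
        raise ValueError(f"class count {q} must match the {len(counts)} supplied tables")
    f1s = []
    for j, c in enumerate(counts):
        pr = _ratio(c.tp, c.tp + c.fp)
        sn = _ratio(c.tp, c.tp + c.fn)
        pr = 0.0 if math.isnan(pr) else pr
        sn = 0.0 if math.isnan(sn) else sn
        if pr + sn == 0.0:
            warnings.warn(f"class {j}: precision + sensitivity is zero; F1 set to 0")
            f1s.append(0.0)
        else:
            f1s.append(2.0 * pr * sn / (pr + sn))
    return float(np.mean(f1s))


def auc_rank(p: ScoredPredictions) -> float:
    """Area under the ROC curve from rank sums (mid-ranks for ties)."""
    it, if_ = p.n_positive, p.n_negative
    if it == 0 or if_ == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(p.scores)  # average (mid) ranks
    rank_sum = float(ranks[p.labels == 1].sum())
    return (rank_sum - it * (it + 1) / 2.0) / (it * if_)


@dataclass(frozen=True)
class MetricsReport:
    """The six headline metrics, each on the [0, 1] scale."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float

    _ORDER = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")
    _LABELS = ("Accuracy", "Sensitivity", "Specificity", "Precision", "F-score", "AUC")

    def __post_init__(self) -> None:
        for name in self._ORDER:
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {name: getattr(self, name) * scale for name in self._ORDER}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_percent_table(self, model_name: str = "model") -> str:
        """Two-decimal percent table in the usual reporting layout."""
        lines = [f"Metrics\t{model_name} (%)"]
        for label, name in zip(self._LABELS, self._ORDER):
            lines.append(f"{label}\t{getattr(self, name) * 100:.2f}")
        return "\n".join(lines)


def report_from_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report from continuous scores thresholded at ``threshold``."""
    scores = np.asarray(scores, dtype=float)
    preds = (scores >= threshold).astype(int)
    c = confusion(labels, preds)
    acc, sn, sp, pr = basic_metrics(c)
    f1 = f_score([c, c.flipped()])
    auc = auc_rank(ScoredPredictions(scores=scores, labels=np.asarray(labels)))
    return MetricsReport(acc, sn, sp, pr, f1, auc)


def improvement(
    optimized: Mapping[str, float] | MetricsReport,
    baseline: Mapping[str, float] | MetricsReport,
) -> dict[str, float]:
    """Per-metric percentage-point differences (optimized minus baseline).

    Both inputs must be on the same percent scale; values are reported
    rounded to two decimals, the convention of the comparison tables.
    """
    if isinstance(optimized, MetricsReport):
        optimized = optimized.as_dict(percent=True)
    if isinstance(baseline, MetricsReport):
        baseline = baseline.as_dict(percent=True)
    if set(optimized) != set(baseline):
        raise ValueError("reports must cover the same metrics")
    return {k: round(optimized[k] - baseline[k], 2) for k in optimized}


def dataset_accounting(
    split_counts: Mapping[str, Mapping[str, int]],
) -> dict[str, int]:
    """Per-split and grand totals from {split: {class: count}} tallies."""
    totals: dict[str, int] = {}
    grand = 0
    for split, classes in split_counts.items():
        sub = 0
        for cls, n in classes.items():
            if n < 0:
                raise ValueError(f"negative count for {split}/{cls}")
            sub += int(n)
        totals[split] = sub
        grand += sub
    totals["total"] = grand
    return totals
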