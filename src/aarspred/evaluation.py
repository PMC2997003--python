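"""Stratified cross-validation and threshold-dependent evaluation metrics.

The four standard metrics of binary protein-class prediction:

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Sensitivity/specificity are reported as percentages; a metric whose
denominator is zero is reported as ``None`` (undefined), except MCC where
a zero denominator yields 0 by convention. Cross-validated performance is
the unweighted mean over folds, with pooled-count metrics reported
alongside. ROC curves are computed internally with tie grouping and
trapezoidal area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from aarspred.errors import ComputationError, InputError, ValidationError
from aarspred.sequence_io import LabeledDataset, ProteinSequence


@dataclass(frozen=True)
class CVSplit:
    """Deterministic stratified fold assignment: sequence id -> fold 1..k."""

    assignment: dict[str, int]
    k: int
    seed: int

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(1, self.k + 1)):
            raise ValidationError(
                f"fold indices {sorted(folds)} outside 1..{self.k}"
            )

    def ids_in_fold(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignment.items() if f == fold]

    def ids_not_in_fold(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignment.items() if f != fold]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally; TP/FN count positives, TN/FP count negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class EvaluationReport:
    """Metric bundle; percentages in [0, 100], MCC in [-1, 1].

    ``None`` marks an undefined metric (zero denominator). Optional fields
    carry per-fold breakdowns, pooled-count metrics, threshold-sweep rows
    and ROC data when produced by the corresponding routines.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    mcc: float
    counts: ConfusionCounts | None = None
    per_fold: list["EvaluationReport"] | None = None
    pooled: "EvaluationReport | None" = None
    threshold_rows: list[tuple[float, "EvaluationReport"]] | None = None
    roc_points: list[tuple[float, float]] | None = None
    roc_area: float | None = None

    def rounded(self) -> dict[str, float | None]:
        """Presentation form: 2-decimal rounding, the tables' convention."""
        r2 = lambda x: None if x is None else round(x, 2)
        return {
            "sensitivity": r2(self.sensitivity),
            "specificity": r2(self.specificity),
            "accuracy": r2(self.accuracy),
            "mcc": r2(self.mcc),
        }


def make_folds(ds: LabeledDataset, k: int = 5, seed: int = 0) -> CVSplit:
    """Stratified random k-fold assignment, deterministic per seed.

    Each fold receives one k-th of the positives and one k-th of the
    negatives (per-fold class counts differ by at most 1).
    """
    labels = np.array(ds.labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if min(n_pos, n_neg) < k:
        raise InputError(
            f"each class needs >= {k} members for {k}-fold CV "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    ids = [s.id for s in ds.sequences]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), labels), 1):
        for i in test_idx:
            assignment[ids[i]] = fold
    return CVSplit(assignment, k, seed)


def confusion(
    labels: Sequence[int], predictions: Sequence[int]
) -> ConfusionCounts:
    """Tally a 2x2 confusion table from 0/1 labels and predictions."""
    if len(labels) != len(predictions):
        raise InputError(
            f"length mismatch: {len(labels)} labels, {len(predictions)} predictions"
        )
    if len(labels) == 0:
        raise InputError("cannot tally an empty prediction set")
    tp = tn = fp = fn = 0
    for y, p in zip(labels, predictions):
        if y == 1:
            tp += p == 1
            fn += p == 0
        else:
            tn += p == 0
            fp += p == 1
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(c: ConfusionCounts) -> EvaluationReport:
    """Sensitivity, specificity, accuracy (percent) and MCC from counts."""
    if c.total == 0:
        raise InputError("empty confusion counts")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return EvaluationReport(sens, spec, acc, mcc, counts=c)


class Pipeline(Protocol):
    """Anything trainable on a labeled dataset that scores sequences."""

    def fit(self, ds: LabeledDataset) -> "Pipeline": ...
    def decision_values(self, seqs: Sequence[ProteinSequence]) -> np.ndarray: ...


def _mean_or_none(vals: list[float | None]) -> float | None:
    if any(v is None for v in vals):
        return None
    return float(np.mean([v for v in vals if v is not None]))


def cross_validate(
    ds: LabeledDataset,
    split: CVSplit,
    pipeline_factory,
    threshold: float = 0.0,
) -> EvaluationReport:
    """k-fold cross-validation of a scoring pipeline.

    ``pipeline_factory()`` must return a fresh unfitted :class:`Pipeline`
    per fold. Headline metrics are the unweighted mean over folds; metrics
    from the pooled confusion counts are attached as ``.pooled``.
    """
    missing = {s.id for s in ds.sequences} - set(split.assignment)
    if missing:
        raise InputError(f"split does not cover ids {sorted(missing)[:5]}")
    fold_reports: list[EvaluationReport] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in range(1, split.k + 1):
        train_ds = ds.subset(split.ids_not_in_fold(fold))
        test_ds = ds.subset(split.ids_in_fold(fold))
        if len(set(train_ds.labels)) < 2:
            raise ComputationError(f"fold {fold}: training partition has one class")
        pipe = pipeline_factory()
        pipe.fit(train_ds)
        scores = np.asarray(pipe.decision_values(test_ds.sequences))
        preds = (scores >= threshold).astype(int)
        c = confusion(test_ds.labels, list(preds))
        fold_reports.append(metrics(c))
        pooled = pooled + c
    report = EvaluationReport(
        sensitivity=_mean_or_none([r.sensitivity for r in fold_reports]),
        specificity=_mean_or_none([r.specificity for r in fold_reports]),
        accuracy=_mean_or_none([r.accuracy for r in fold_reports]),
        mcc=float(np.mean([r.mcc for r in fold_reports])),
        per_fold=fold_reports,
        pooled=metrics(pooled),
    )
    return report


DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    round(-1.0 + 0.1 * i, 1) for i in range(21)
)


def sweep_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> EvaluationReport:
    """Metrics at each decision threshold (ascending), from raw scores."""
    if len(thresholds) == 0:
        raise InputError("threshold list must be non-empty")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rows: list[tuple[float, EvaluationReport]] = []
    for t in sorted(thresholds):
        preds = (scores >= t).astype(int)
        rows.append((t, metrics(confusion(list(y), list(preds)))))
    points, area = roc(scores, y)
    headline = rows[len(rows) // 2][1]  # row at the middle threshold
    return EvaluationReport(
        headline.sensitivity, headline.specificity, headline.accuracy,
        headline.mcc, counts=headline.counts,
        threshold_rows=rows, roc_points=points, roc_area=area,
    )


def threshold_sweep(
    model,
    X: np.ndarray,
    y: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> EvaluationReport:
    """Threshold sweep of a fitted model on an evaluation matrix.

    ``model`` needs an sklearn-style ``decision_function``; rows are
    emitted in ascending threshold order.
    """
    scores = np.asarray(model.decision_function(np.asarray(X, dtype=float)))
    return sweep_scores(scores, y, thresholds)


def roc(
    decision_values: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal area, with tied scores grouped.

    Points are (false-positive proportion, true-positive proportion) at
    every distinct decision value, plus (0,0) and (1,1).
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += y[order[j]] == 1
            fp += y[order[j]] == 0
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(area)


def report_to_tsv(report: EvaluationReport) -> str:
    """Render threshold-sweep rows as a TSV table.

    Columns mirror the conventional layout: Threshold, Sensitivity,
    Specificity, Accuracy, MCC, 2-decimal rounded.
    """
    if not report.threshold_rows:
        raise InputError("report has no threshold rows")
    fmt = lambda x: "NA" if x is None else f"{x:.2f}"
    lines = ["Threshold\tSensitivity\tSpecificity\tAccuracy\tMCC"]
    for t, r in report.threshold_rows:
        m = r.rounded()
        lines.append(
            f"{t:.1f}\t{fmt(m['sensitivity'])}\t{fmt(m['specificity'])}"
            f"\t{fmt(m['accuracy'])}\t{fmt(m['mcc'])}"
        )
    return "\n".join(lines) + "\n"
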