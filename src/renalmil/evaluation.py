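"""Evaluation: confusion matrices, one-vs-rest class metrics, CV harnesses.

Per-class metrics are computed one-vs-rest from the confusion matrix —
accuracy (TP+TN)/N, sensitivity TP/(TP+FN), specificity TN/(TN+FP), all in
percent — and summarized across classes as mean ± sample SD (n−1
denominator). Display rounding is half-up to one decimal; raw values are
retained. Cross-validation comes in two schemes: stratified k-fold over
slides and leave-one-subject-out (LOSO), where each fold tests every slide
of exactly one subject and no subject ever appears on both sides of a fold.

INDETERMINATE slide predictions (all patches discarded) are scored as a
prediction of no class: a false negative for the actual class, and reported
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .fusion import INDETERMINATE

__all__ = [
    "ConfusionMatrix",
    "SummaryStats",
    "CVSplit",
    "confusion_matrix",
    "per_class_metrics",
    "macro_summary",
    "kfold_split",
    "loso_split",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (table display convention)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i][j] = #(actual=class_i and predicted=class_j).

    Rows are actual classes, columns predicted. An extra
    ``n_indeterminate`` vector counts per-actual-class predictions that were
    INDETERMINATE; those items are included in ``total`` but appear in no
    column.
    """

    classes: tuple[str, ...]
    counts: np.ndarray
    n_indeterminate: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum() + self.n_indeterminate.sum())


def confusion_matrix(
    actual: list[str], predicted: list[str], classes: list[str]
) -> ConfusionMatrix:
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    indeterminate = np.zeros(k, dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index:
            raise ValueError(f"unknown actual label {a!r}")
        if p == INDETERMINATE:
            indeterminate[index[a]] += 1
            continue
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(tuple(classes), counts, indeterminate)


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, dict]:
    """One-vs-rest accuracy/sensitivity/specificity per class, in percent.

    A class with zero actual positives gets ``sensitivity: None`` with a
    ``flags`` entry; callers exclude flagged values from macro summaries.
    INDETERMINATE predictions count against the actual class (a miss) and as
    correctly-negative for every other class.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    out: dict[str, dict] = {}
    for i, cls in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum() - tp + cm.n_indeterminate[i])
        fp = int(cm.counts[:, i].sum() - tp)
        tn = n - tp - fn - fp
        entry = {
            "accuracy": 100.0 * (tp + tn) / n,
            "specificity": 100.0 * tn / (tn + fp) if tn + fp > 0 else None,
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn > 0 else None,
            "support": tp + fn,
            "flags": [],
        }
        if tp + fn == 0:
            entry["flags"].append("no_positives")
        out[cls] = entry
    return out


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int
    flags: tuple[str, ...] = ()

    def rounded(self, decimals: int = 1) -> tuple[float, float]:
        return round_half_up(self.mean, decimals), round_half_up(self.sd, decimals)


def macro_summary(values: list[float]) -> SummaryStats:
    """Mean ± sample SD (n−1) over per-class percentage values."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("macro_summary requires at least one value")
    arr = np.asarray(vals, dtype=np.float64)
    mean = float(arr.mean())
    if arr.size == 1:
        return SummaryStats(mean=mean, sd=0.0, n=1, flags=("single_value",))
    return SummaryStats(mean=mean, sd=float(arr.std(ddof=1)), n=arr.size)


@dataclass(frozen=True)
class CVSplit:
    scheme: str  # kfold | loso
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train ids, test ids)
    seed: int | None = None

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)


def kfold_split(slide_records, k: int, seed: int = 0) -> CVSplit:
    """Seeded k-fold over slides, stratified by class where class counts allow."""
    if k < 2:
        raise ValueError("k must be >= 2")
    records = list(slide_records)
    if k > len(records):
        raise ValueError("k exceeds number of slides")
    ids = np.array([r.slide_id for r in records])
    labels = np.array([r.label for r in records])
    min_count = min(np.unique(labels, return_counts=True)[1])
    if min_count >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids, labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids)
    folds = tuple(
        (tuple(ids[tr].tolist()), tuple(ids[te].tolist())) for tr, te in split_iter
    )
    return CVSplit(scheme="kfold", folds=folds, seed=seed)


def loso_split(slide_records) -> CVSplit:
    """Leave-one-subject-out: one fold per subject, testing all its slides."""
    records = list(slide_records)
    subjects: dict[str, list[str]] = {}
    for r in records:
        if r.subject_id is None:
            raise ValueError("LOSO requires subject ids on every slide")
        subjects.setdefault(r.subject_id, []).append(r.slide_id)
    all_ids = [r.slide_id for r in records]
    folds = []
    for subject in sorted(subjects):
        test = tuple(subjects[subject])
        train = tuple(i for i in all_ids if i not in test)
        folds.append((train, test))
    return CVSplit(scheme="loso", folds=tuple(folds))
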