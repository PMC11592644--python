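"""Performance metrics, cross-validation and masking-based feature importance.

Five indices summarise classifier performance: sensitivity Sn = TP/(TP+FN),
specificity Sp = TN/(TN+FP), accuracy Acc = (TP+TN)/N, the Matthews
correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and the area under the ROC curve (mid-rank tie handling).  MCC with a zero
denominator is reported as 0 by the usual convention; AUC is undefined (NaN)
when only one class is present.

Feature importance follows a zero-masking protocol: with a *fixed* trained
model, the target feature columns are set to zero for every sample of an
evaluation set, predictions are recomputed, and the importance score is the
resulting error rate

    importance = (FP + FN) / (TP + TN + FP + FN),

so a feature whose removal breaks many predictions scores high.  Features
can be masked singly or as named groups; the five physicochemical patterns
(geometrical, electronic, hydrophobic, steric, composition) are masked
pattern-wise through the descriptor registry's tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset
from .descriptors import (
    DescriptorCombination,
    DescriptorRegistry,
    encode_many,
    mask_features,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ImportanceReport",
    "compute_metrics",
    "improvement_percent",
    "kfold_cv",
    "importance_scores",
    "rank_patterns",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN: correctly predicted positives, missed positives,
    false alarms, correctly predicted negatives."""

    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


@dataclass(frozen=True)
class MetricsReport:
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    AUC: float  # NaN when undefined (single-class labels)
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "Sn": self.Sn,
            "Sp": self.Sp,
            "Acc": self.Acc,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "TP": self.counts.TP,
            "FN": self.counts.FN,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
        }


def compute_metrics(
    labels: Sequence[int] | np.ndarray,
    predicted_probabilities: Sequence[float] | np.ndarray,
    threshold: float = 0.5,
) -> MetricsReport:
    """Score probabilistic predictions against 0/1 labels.

    Classification is ``probability > threshold``.  AUC uses rank-based ROC
    integration (equivalent to the Mann–Whitney statistic with mid-rank
    ties); with a single-class label vector AUC is reported as NaN while the
    threshold metrics are still computed.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted_probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if y.size == 0:
        raise ValueError("cannot compute metrics on an empty set")
    pred = (p > threshold).astype(int)
    TP = int(np.sum((y == 1) & (pred == 1)))
    FN = int(np.sum((y == 1) & (pred == 0)))
    FP = int(np.sum((y == 0) & (pred == 1)))
    TN = int(np.sum((y == 0) & (pred == 0)))
    counts = ConfusionCounts(TP, FN, FP, TN)
    sn = TP / (TP + FN) if TP + FN else float("nan")
    sp = TN / (TN + FP) if TN + FP else float("nan")
    acc = (TP + TN) / counts.total
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / np.sqrt(denom) if denom else 0.0
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    return MetricsReport(sn, sp, acc, float(mcc), auc, counts)


def improvement_percent(acc_new: float, acc_reference: float) -> float:
    """Accuracy enhancement of one model over another, in percentage points.

    E.g. a 0.9479 model over a 0.9211 reference is a 2.68 % enhancement.
    """
    return round((acc_new - acc_reference) * 100.0, 2)


TrainFn = Callable[[LabeledDataset, int], object]
# a TrainFn fits a predictor on a training dataset with a seed and returns an
# object exposing predict_encoded / or a (sequences -> probs) callable


def kfold_cv(
    ds: LabeledDataset,
    train_fn: Callable[[LabeledDataset, int], Callable[[list[str]], np.ndarray]],
    k: int = 5,
    rng_seed: int = 0,
) -> tuple[list[MetricsReport], dict[str, tuple[float, float]]]:
    """Stratified k-fold cross-validation.

    ``train_fn(train_ds, seed)`` must return a callable mapping a list of
    sequences to positive-class probabilities; each fold is trained from
    scratch.  Returns the per-fold reports and a ``metric -> (mean, sd)``
    summary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = ds.labels()
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < k:
            raise ValueError(f"class {cls} has {cnt} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    reports: list[MetricsReport] = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_ds = LabeledDataset([ds.records[i] for i in tr])
        predict_fn = train_fn(train_ds, rng_seed + fold)
        probs = predict_fn([ds.records[i].sequence for i in va])
        reports.append(compute_metrics(y[va], probs))
    summary = {}
    for m in ("Sn", "Sp", "Acc", "MCC", "AUC"):
        vals = np.array([getattr(r, m) for r in reports])
        summary[m] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return reports, summary


@dataclass
class ImportanceReport:
    """Masking-importance scores per feature group and per pattern."""

    per_group: dict[str, float]
    per_pattern: dict[str, float]
    baseline_acc: float
    evaluation_set: str = ""

    def ranked_groups(self) -> list[tuple[str, float]]:
        return sorted(self.per_group.items(), key=lambda kv: (-kv[1], kv[0]))


def importance_scores(
    model,
    ds: LabeledDataset,
    registry: DescriptorRegistry,
    feature_groups: Mapping[str, Iterable[int]] | None = None,
    *,
    split: str | None = "test",
    threshold: float = 0.5,
    patterns: bool = True,
) -> ImportanceReport:
    """Zero-masking importance of feature groups for a fixed trained model.

    The model's own descriptor combination determines the encoding.  By
    default every single feature forms its own group (named by its
    combination-qualified feature name); pass ``feature_groups`` to score
    custom groups.  When ``patterns`` is true, each of the five
    physicochemical patterns is additionally masked as a whole.
    """
    records = ds.records if split is None else [r for r in ds.records if r.split == split]
    if not records:
        raise ValueError(f"no records in evaluation split {split!r}")
    combo: DescriptorCombination = model.combination
    encs = encode_many([r.sequence for r in records], combo, registry)
    y = np.array([1 if r.label == "positive" else 0 for r in records])

    def error_rate(feature_idx: Iterable[int]) -> float:
        masked = [mask_features(e, feature_idx) for e in encs]
        p = model.predict_encoded(masked)
        rep = compute_metrics(y, p, threshold)
        return (rep.counts.FP + rep.counts.FN) / rep.counts.total

    baseline = error_rate([])
    if feature_groups is None:
        names = registry.combination_feature_names(combo)
        feature_groups = {name: [j] for j, name in enumerate(names)}
    else:
        feature_groups = {k: list(v) for k, v in feature_groups.items()}
        for name, idx in feature_groups.items():
            if not idx:
                raise ValueError(f"feature group {name!r} is empty")
    per_group = {name: error_rate(idx) for name, idx in feature_groups.items()}
    per_pattern: dict[str, float] = {}
    if patterns:
        tags = registry.combination_pattern_tags(combo)
        for pat in sorted(set(tags)):
            idx = [j for j, t in enumerate(tags) if t == pat]
            per_pattern[pat] = error_rate(idx)
    return ImportanceReport(
        per_group=per_group,
        per_pattern=per_pattern,
        baseline_acc=1.0 - baseline,
        evaluation_set=split or "all",
    )


def rank_patterns(report: ImportanceReport) -> list[str]:
    """Patterns by descending importance; ties broken alphabetically."""
    if not report.per_pattern:
        raise ValueError("report has no per-pattern scores")
    return [p for p, _ in sorted(report.per_pattern.items(), key=lambda kv: (-kv[1], kv[0]))]
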