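"""Evaluation: precision/recall/F1, macro-averaging, ROC/AUC, and LOOCV.

Per-class metrics follow the one-vs-rest convention: precision
P = TP/(TP+FP), recall R = TP/(TP+FN), and F1 the harmonic mean
2PR/(P+R), with the zero-division conventions P=0 when TP+FP=0, R=0 when
TP+FN=0 and F1=0 when P=R=0.  Macro averages are unweighted means over the
classes present in the gold labels; the overall figure is the mean of the
three per-task macros.

Leave-one-out cross-validation trains one model per record on the other
n−1 records (per-fold seeds derived from the base seed, so the whole
experiment is reproducible) and pools the n held-out predictions into a
single confusion matrix — per-fold metrics on test sets of size one would
be degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .model import (
    ModelConfig,
    PredictionResult,
    TASK_ENUMS,
    TASK_ORDER,
    _argmax_labels,
    encode_labels,
    fit_arrays,
    init_model,
    predict_proba_matrix,
)
from .schema import Cohort, SemanticLabels, cohort_matrix

__all__ = [
    "ClassCounts",
    "ConfusionCounts",
    "TaskMetrics",
    "MetricsReport",
    "ROCCurve",
    "confusion_counts",
    "precision_recall_f1",
    "macro_average",
    "metrics_report",
    "roc_curve",
    "one_vs_rest_auc",
    "loocv_folds",
    "loocv",
]


class ClassCounts(NamedTuple):
    TP: int
    FP: int
    FN: int
    TN: int


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class, over a fixed class list."""

    classes: tuple
    counts: dict

    @property
    def n_evaluated(self) -> int:
        if not self.classes:
            return 0
        first = self.counts[self.classes[0]]
        return first.TP + first.FP + first.FN + first.TN


def confusion_counts(gold: Sequence, predicted: Sequence,
                     classes: Sequence) -> ConfusionCounts:
    """One-vs-rest confusion counts per class."""
    if len(gold) != len(predicted):
        raise ValueError(
            f"gold ({len(gold)}) and predicted ({len(predicted)}) lengths differ"
        )
    class_set = set(classes)
    for label in list(gold) + list(predicted):
        if label not in class_set:
            raise ValueError(f"label {label!r} not in class list")
    counts = {}
    n = len(gold)
    for cls in classes:
        tp = sum(1 for g, p in zip(gold, predicted) if g == cls and p == cls)
        fp = sum(1 for g, p in zip(gold, predicted) if g != cls and p == cls)
        fn = sum(1 for g, p in zip(gold, predicted) if g == cls and p != cls)
        counts[cls] = ClassCounts(TP=tp, FP=fp, FN=fn, TN=n - tp - fp - fn)
    return ConfusionCounts(classes=tuple(classes), counts=counts)


def precision_recall_f1(counts: ConfusionCounts, cls) -> tuple[float, float, float]:
    """(P, R, F1) for one class with the stated zero-division conventions."""
    c = counts.counts[cls]
    p = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else 0.0
    r = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return (p, r, f1)


def macro_average(per_class_metrics: Sequence[tuple[float, float, float]]
                  ) -> tuple[float, float, float]:
    """Unweighted componentwise mean of (P, R, F1) triples."""
    if not per_class_metrics:
        raise ValueError("cannot macro-average an empty metric list")
    arr = np.asarray(per_class_metrics, dtype=float)
    return tuple(arr.mean(axis=0))


@dataclass(frozen=True)
class TaskMetrics:
    """Per-class and macro metrics for one task."""

    per_class: dict  # label -> (P, R, F1)
    macro: tuple[float, float, float]
    classes_present: tuple


@dataclass(frozen=True)
class MetricsReport:
    """Three-task metric summary over one pooled prediction set."""

    per_task: dict  # task -> TaskMetrics
    overall_macro: tuple[float, float, float]
    n_evaluated: int

    def macro_f1(self, task: str) -> float:
        return self.per_task[task].macro[2]

    def as_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "overall_macro": dict(zip(("precision", "recall", "f1"),
                                      self.overall_macro)),
            "tasks": {
                task: {
                    "macro": dict(zip(("precision", "recall", "f1"), tm.macro)),
                    "per_class": {
                        cls.value: dict(zip(("precision", "recall", "f1"), prf))
                        for cls, prf in tm.per_class.items()
                    },
                }
                for task, tm in self.per_task.items()
            },
        }


def metrics_report(gold: Sequence[SemanticLabels],
                   predicted: Sequence[SemanticLabels]) -> MetricsReport:
    """Pooled three-task metrics from gold and predicted label triples.

    Macro averages run over the classes present in gold; classes never seen
    in gold would have undefined recall and are excluded.
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted lengths differ")
    if not gold:
        raise ValueError("cannot compute metrics on an empty prediction set")
    per_task = {}
    task_macros = []
    for task in TASK_ORDER:
        enum_cls = TASK_ENUMS[task]
        g = [getattr(s, task) for s in gold]
        p = [getattr(s, task) for s in predicted]
        counts = confusion_counts(g, p, list(enum_cls))
        present = tuple(c for c in enum_cls if any(x == c for x in g))
        per_class = {c: precision_recall_f1(counts, c) for c in present}
        macro = macro_average(list(per_class.values()))
        per_task[task] = TaskMetrics(per_class=per_class, macro=macro,
                                     classes_present=present)
        task_macros.append(macro)
    overall = tuple(np.mean([m[i] for m in task_macros]) for i in range(3))
    return MetricsReport(per_task=per_task, overall_macro=overall,
                         n_evaluated=len(gold))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    """Monotone (FPR, TPR) staircase from (0,0) to (1,1) plus trapezoid AUC."""

    points: tuple  # ((fpr, tpr), ...)
    auc: float


def roc_curve(scores: Sequence[float], binary_gold: Sequence[int]) -> ROCCurve:
    """ROC by threshold sweep over distinct scores (ties grouped).

    Instances are sorted by decreasing score; each distinct score value
    contributes one operating point, so tied scores move the curve
    diagonally and receive half credit in the AUC, matching the
    Mann–Whitney convention.
    """
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(binary_gold, dtype=int)
    if scores.shape != gold.shape or scores.ndim != 1:
        raise ValueError("scores and binary_gold must be equal-length 1-D")
    n_pos = int((gold == 1).sum())
    n_neg = int((gold == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    s, g = scores[order], gold[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(g[j] == 1)
            fp += int(g[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = float(np.trapezoid([p[1] for p in points], [p[0] for p in points]))
    return ROCCurve(points=tuple(points), auc=auc)


def one_vs_rest_auc(probabilities: np.ndarray,
                    gold_idx: Sequence[int]) -> tuple[dict, float]:
    """Per-class one-vs-rest ROC curves and their macro-mean AUC.

    ``probabilities`` is n × k softmax output; classes absent from gold (or
    covering all of it) are skipped, as their ROC is undefined.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    gold_idx = np.asarray(gold_idx, dtype=int)
    curves = {}
    for c in range(probabilities.shape[1]):
        binary = (gold_idx == c).astype(int)
        if binary.min() == binary.max():
            continue
        curves[c] = roc_curve(probabilities[:, c], binary)
    if not curves:
        raise ValueError("no class with both positives and negatives in gold")
    macro_auc = float(np.mean([c.auc for c in curves.values()]))
    return curves, macro_auc


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


def loocv_folds(n: int):
    """Yield (train_indices, test_index) for each of the n folds.

    Exposed separately so the no-leakage property (a record never trains
    its own fold) is directly testable.
    """
    if n < 2:
        raise ValueError("LOOCV needs at least two records")
    indices = np.arange(n)
    for i in range(n):
        yield np.delete(indices, i), i


def fold_seed(base_seed: int, fold: int) -> int:
    """Deterministic per-fold seed derived from (base seed, fold index)."""
    ss = np.random.SeedSequence(entropy=int(base_seed) & 0x7FFFFFFF,
                                spawn_key=(int(fold),))
    return int(ss.generate_state(1)[0] % (2**31))


def loocv(
    cohort: Cohort,
    config: ModelConfig,
    probabilities_out: Optional[list] = None,
) -> tuple[list[PredictionResult], MetricsReport]:
    """Leave-one-out cross-validation of the three-task model.

    Runs exactly ``len(cohort)`` train/test folds: fold i trains a fresh
    model (seeded from ``fold_seed(config.seed, i)``, standardization
    fitted on the training rows only) on every record except i and predicts
    record i.  The pooled held-out predictions feed one MetricsReport.
    """
    n = len(cohort)
    if n < 2:
        raise ValueError("LOOCV needs at least two records")
    X = cohort_matrix(cohort)
    y_idx = encode_labels(cohort)  # raises on unlabeled records
    gold = [r.labels for r in cohort]

    predictions: list[PredictionResult] = []
    for train_idx, test_idx in loocv_folds(n):
        cfg = replace(config, seed=fold_seed(config.seed, test_idx))
        model = init_model(cfg, cohort.registry)
        fit_arrays(model, X[train_idx], {t: y_idx[t][train_idx] for t in TASK_ORDER})
        probs = predict_proba_matrix(model, X[test_idx:test_idx + 1])
        prob_row = {task: probs[task][0] for task in TASK_ORDER}
        predictions.append(
            PredictionResult(probabilities=prob_row,
                             labels=_argmax_labels(prob_row))
        )
        if probabilities_out is not None:
            probabilities_out.append(prob_row)

    report = metrics_report(gold, [p.labels for p in predictions])
    return predictions, report
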