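"""Metrics against brute-force/scikit-learn oracles, ROC, and LOOCV."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from lungreport import (
    GeneratorConfig,
    ModelConfig,
    confusion_counts,
    loocv,
    macro_average,
    metrics_report,
    precision_recall_f1,
    roc_curve,
    simulate_cohort,
)
from lungreport.evaluation import ClassCounts, ConfusionCounts, fold_seed, loocv_folds


class TestConfusionCounts:
    def test_perfect_agreement(self):
        counts = confusion_counts(["A", "B", "A"], ["A", "B", "A"], ["A", "B"])
        for cls in ("A", "B"):
            assert counts.counts[cls].FP == 0
            assert counts.counts[cls].FN == 0

    def test_hand_case(self):
        counts = confusion_counts(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert counts.counts["A"] == ClassCounts(TP=1, FP=0, FN=1, TN=1)
        assert counts.counts["B"] == ClassCounts(TP=1, FP=1, FN=0, TN=1)

    def test_empty_lists(self):
        counts = confusion_counts([], [], ["A", "B"])
        assert counts.counts["A"] == ClassCounts(0, 0, 0, 0)
        assert counts.n_evaluated == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(["A"], [], ["A"])

    def test_counts_partition_instances(self):
        rng = np.random.default_rng(0)
        gold = rng.choice(list("ABC"), size=37).tolist()
        pred = rng.choice(list("ABC"), size=37).tolist()
        counts = confusion_counts(gold, pred, list("ABC"))
        for cls in "ABC":
            c = counts.counts[cls]
            assert c.TP + c.FP + c.FN + c.TN == 37


class TestPrecisionRecallF1:
    def _counts(self, tp, fp, fn, tn=0):
        return ConfusionCounts(classes=("X",),
                               counts={"X": ClassCounts(tp, fp, fn, tn)})

    def test_direct_arithmetic(self):
        assert precision_recall_f1(self._counts(2, 1, 1), "X") == pytest.approx(
            (2 / 3, 2 / 3, 2 / 3))

    def test_perfect_class(self):
        assert precision_recall_f1(self._counts(5, 0, 0), "X") == (1.0, 1.0, 1.0)

    def test_zero_division_conventions(self):
        assert precision_recall_f1(self._counts(0, 0, 0, 3), "X") == (0.0, 0.0, 0.0)
        assert precision_recall_f1(self._counts(0, 2, 0), "X") == (0.0, 0.0, 0.0)

    def test_macro_average(self):
        assert macro_average([(1, 1, 1.0), (0, 0, 0.5)])[2] == pytest.approx(0.75)
        assert macro_average([(0.3, 0.4, 0.5)]) == pytest.approx((0.3, 0.4, 0.5))
        assert macro_average([(1, 1, 1), (1, 1, 1), (0, 0, 0)])[2] == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            macro_average([])


def test_metrics_agree_with_sklearn_on_randomized_fixtures():
    """1000 random label vectors: P/R/F1 must match scikit-learn exactly."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(1, 40))
        classes = list(range(k))
        gold = rng.integers(0, k, size=n).tolist()
        pred = rng.integers(0, k, size=n).tolist()
        counts = confusion_counts(gold, pred, classes)
        p, r, f, _ = precision_recall_fscore_support(
            gold, pred, labels=classes, zero_division=0)
        for c in classes:
            assert precision_recall_f1(counts, c) == pytest.approx(
                (p[c], r[c], f[c]), abs=1e-12)
        present = sorted(set(gold))
        ours = macro_average([precision_recall_f1(counts, c) for c in present])
        sk = precision_recall_fscore_support(
            gold, pred, labels=present, average="macro", zero_division=0)
        assert ours == pytest.approx(sk[:3], abs=1e-12)


class TestROC:
    def test_perfect_separation(self):
        assert roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_rank_sum_hand_case(self):
        # 3 of 4 (pos, neg) pairs concordant -> AUC 0.75
        assert roc_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]).auc == pytest.approx(0.75)

    def test_all_scores_tied(self):
        curve = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.5)
        assert curve.points == ((0.0, 0.0), (1.0, 1.0))

    def test_curve_is_monotone_staircase(self):
        rng = np.random.default_rng(1)
        curve = roc_curve(rng.normal(size=50), rng.integers(0, 2, size=50))
        pts = np.asarray(curve.points)
        assert pts[0] == pytest.approx([0, 0])
        assert pts[-1] == pytest.approx([1, 1])
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_gold_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_auc_equals_mann_whitney_on_random_fixtures(self):
        """Trapezoid AUC == normalized rank-sum with half credit for ties."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            gold = rng.integers(0, 2, size=n)
            if gold.min() == gold.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            pos = scores[gold == 1]
            neg = scores[gold == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() \
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
            oracle = pairs / (len(pos) * len(neg))
            ours = roc_curve(scores, gold).auc
            assert ours == pytest.approx(oracle, abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(gold, scores), abs=1e-12)


class TestLOOCV:
    def test_fold_structure_prevents_leakage(self):
        n = 17
        seen = []
        for train_idx, test_idx in loocv_folds(n):
            assert test_idx not in set(train_idx.tolist())
            assert len(train_idx) == n - 1
            seen.append(test_idx)
        assert seen == list(range(n))

    def test_fold_seeds_deterministic_and_distinct(self):
        seeds = [fold_seed(0, i) for i in range(100)]
        assert seeds == [fold_seed(0, i) for i in range(100)]
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2**31 for s in seeds)

    def test_three_record_cohort_yields_three_pooled_predictions(self, registry):
        cohort = simulate_cohort(GeneratorConfig(n=3, seed=1), registry)
        predictions, report = loocv(cohort, ModelConfig(epochs=2))
        assert len(predictions) == 3
        assert report.n_evaluated == 3

    def test_too_small_cohort_rejected(self, registry):
        cohort = simulate_cohort(GeneratorConfig(n=1, seed=1), registry)
        with pytest.raises(ValueError):
            loocv(cohort, ModelConfig(epochs=1))

    def test_separable_cohort_recovers_labels(self, registry):
        """delta=3, n=100, 10 epochs: pooled macro-F1 >= 0.85 on all tasks."""
        cohort = simulate_cohort(GeneratorConfig(n=100, seed=0, effect_size=3.0),
                                 registry)
        _, report = loocv(cohort, ModelConfig(epochs=10, seed=0))
        for task in ("location", "texture", "margin"):
            assert report.macro_f1(task) >= 0.85, (task, report.macro_f1(task))

    def test_no_signal_cohort_is_at_chance_for_radiomics_tasks(self, registry):
        """delta=0 leaves texture/margin at chance; location keeps SISN signal.

        The slice-position features encode the nodule's axial band by
        design (they exist precisely because slicing information indicates
        location), so only the two radiomics-only tasks lose all signal
        when the prototype separation is zeroed.
        """
        n = 120
        cohort = simulate_cohort(GeneratorConfig(n=n, seed=5, effect_size=0.0),
                                 registry)
        gold = {t: np.array([getattr(r.labels, t).value for r in cohort])
                for t in ("texture", "margin")}
        predictions, report = loocv(cohort, ModelConfig(epochs=5, seed=0))
        for task, k in (("texture", 3), ("margin", 4)):
            pred = np.array([getattr(p.labels, task).value for p in predictions])
            accuracy = float(np.mean(pred == gold[task]))
            se = np.sqrt((1 / k) * (1 - 1 / k) / n)
            assert abs(accuracy - 1 / k) < 4 * se, (task, accuracy)
            assert report.macro_f1(task) < 1 / k + 4 * se
        # location keeps a slice-position signal; at this small n the weakly
        # trained towers only exceed naive chance (the sharp 4-SE version of
        # this check runs at larger n in the acceptance suite)
        loc_pred = np.array([p.labels.location.value for p in predictions])
        loc_gold = np.array([r.labels.location.value for r in cohort])
        assert float(np.mean(loc_pred == loc_gold)) > 1 / 6
        assert report.macro_f1("location") > 1 / 6


def test_metrics_report_macro_over_present_classes_only():
    from lungreport import LocationLabel, MarginLabel, SemanticLabels, TextureLabel

    triple = SemanticLabels(LocationLabel.RUL, TextureLabel.SOLID,
                            MarginLabel.LOBULATED)
    report = metrics_report([triple, triple], [triple, triple])
    assert report.per_task["location"].classes_present == (LocationLabel.RUL,)
    assert report.overall_macro == pytest.approx((1.0, 1.0, 1.0))
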