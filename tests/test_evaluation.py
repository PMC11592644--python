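"""Metrics, cross-validation and zero-masking importance."""

import numpy as np
import pytest

from acepep.datasets import LabeledDataset
from acepep.descriptors import encode_many
from acepep.evaluation import (
    compute_metrics,
    importance_scores,
    improvement_percent,
    kfold_cv,
    rank_patterns,
)
from acepep.model import MeanPoolLogistic


def brute_force_counts(y, p, thr=0.5):
    """Independent per-sample recount of the confusion table."""
    tp = fn = fp = tn = 0
    for yi, pi in zip(y, p):
        pred = 1 if pi > thr else 0
        if yi == 1 and pred == 1:
            tp += 1
        elif yi == 1:
            fn += 1
        elif pred == 1:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([1] * 50 + [0] * 50)
        p = np.array([0.9] * 50 + [0.1] * 50)
        r = compute_metrics(y, p)
        assert (r.Sn, r.Sp, r.Acc, r.MCC, r.AUC) == (1, 1, 1, 1, 1)

    def test_hand_worked_confusion_table(self):
        # TP=9 FN=1 TN=8 FP=2: Sn=0.9 Sp=0.8 Acc=0.85 MCC=(72-2)/sqrt(11*10*10*9)
        y = np.array([1] * 10 + [0] * 10)
        p = np.array([0.9] * 9 + [0.1] + [0.9] * 2 + [0.1] * 8)
        r = compute_metrics(y, p)
        assert r.Sn == pytest.approx(0.9)
        assert r.Sp == pytest.approx(0.8)
        assert r.Acc == pytest.approx(0.85)
        assert r.MCC == pytest.approx(70 / np.sqrt(11 * 10 * 10 * 9))
        assert r.MCC == pytest.approx(0.7035, abs=1e-4)

    def test_matches_bruteforce_recount_on_random_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, size=n)
            p = rng.random(n)
            r = compute_metrics(y, p)
            tp, fn, fp, tn = brute_force_counts(y, p)
            assert (r.counts.TP, r.counts.FN, r.counts.FP, r.counts.TN) == (tp, fn, fp, tn)
            assert r.Acc == pytest.approx((tp + tn) / n)
            assert -1 <= r.MCC <= 1

    def test_label_swap_symmetry(self, rng):
        y = rng.integers(0, 2, size=100)
        p = rng.random(100)
        r = compute_metrics(y, p)
        # swapping classes and predictions maps Sn <-> Sp, preserves Acc, |MCC|
        r2 = compute_metrics(1 - y, 1 - p, threshold=0.5 - 1e-12)
        assert r2.Sn == pytest.approx(r.Sp)
        assert r2.Sp == pytest.approx(r.Sn)
        assert r2.Acc == pytest.approx(r.Acc)
        assert abs(r2.MCC) == pytest.approx(abs(r.MCC))

    def test_constant_probabilities_give_half_auc(self):
        y = np.array([1, 0, 1, 0])
        r = compute_metrics(y, np.full(4, 0.7))
        assert r.AUC == pytest.approx(0.5)

    def test_single_class_auc_undefined_other_metrics_computed(self):
        r = compute_metrics(np.ones(5, dtype=int), np.array([0.9, 0.8, 0.3, 0.9, 0.6]))
        assert np.isnan(r.AUC)
        assert r.Sn == pytest.approx(0.8)

    def test_zero_denominator_mcc_is_zero(self):
        r = compute_metrics(np.array([1, 1]), np.array([0.9, 0.2]))
        assert r.MCC == 0.0

    def test_improvement_percent_report(self):
        assert improvement_percent(0.9479, 0.9211) == pytest.approx(2.68)


class TestKFold:
    @staticmethod
    def _train_fn(registry, combo):
        def fn(train_ds: LabeledDataset, seed: int):
            encs = encode_many(train_ds.sequences(), combo, registry)
            clf = MeanPoolLogistic(combo, seed=seed).fit(encs, train_ds.labels())

            def predict_seqs(seqs):
                return clf.predict_encoded(encode_many(seqs, combo, registry))

            return predict_seqs

        return fn

    def test_folds_are_stratified_disjoint_exhaustive(self, registry, planted_small):
        from sklearn.model_selection import StratifiedKFold

        y = planted_small.labels()
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        seen = []
        for _, va in skf.split(np.zeros(len(y)), y):
            seen.extend(va)
            pos = y[va].sum()
            assert abs(pos - y.sum() / 5) <= 1
        assert sorted(seen) == list(range(len(y)))

    def test_cv_accuracy_consistent_with_holdout(self, registry, planted_small):
        """Mean CV accuracy tracks the held-out accuracy of a full-data fit."""
        combo = registry.single("Z-scales")
        _, summary = kfold_cv(planted_small, self._train_fn(registry, combo), 5, 0)
        train = planted_small.subset("train")
        test = planted_small.subset("test")
        clf = MeanPoolLogistic(combo).fit(
            encode_many(train.sequences(), combo, registry), train.labels()
        )
        holdout = compute_metrics(
            test.labels(),
            clf.predict_encoded(encode_many(test.sequences(), combo, registry)),
        ).Acc
        assert abs(summary["Acc"][0] - holdout) < 0.05

    def test_k_larger_than_class_rejected(self, registry, planted_small):
        with pytest.raises(ValueError, match="fewer than"):
            kfold_cv(planted_small, self._train_fn(registry, registry.single("Z-scales")),
                     k=10_000)


@pytest.fixture(scope="module")
def proxy_model(registry, planted_small):
    combo = registry.single("Z-scales")
    train = planted_small.subset("train")
    encs = encode_many(train.sequences(), combo, registry)
    return MeanPoolLogistic(combo, seed=0).fit(encs, train.labels())


class TestImportance:
    def test_empty_mask_score_equals_one_minus_acc(
        self, registry, planted_small, proxy_model
    ):
        report = importance_scores(
            proxy_model, planted_small, registry,
            feature_groups={"probe": [0]}, patterns=False,
        )
        combo = registry.single("Z-scales")
        test = planted_small.subset("test")
        probs = proxy_model.predict_encoded(
            encode_many(test.sequences(), combo, registry)
        )
        acc = compute_metrics(test.labels(), probs).Acc
        assert report.baseline_acc == pytest.approx(acc)

    def test_planted_feature_ranks_first(self, registry, planted_small, proxy_model):
        """Masking the label-generating column breaks the most predictions."""
        report = importance_scores(proxy_model, planted_small, registry, patterns=False)
        top_feature = report.ranked_groups()[0][0]
        planted = planted_small.construction_params["feature_index"]
        assert top_feature == f"Z-scales:z{planted + 1}"

    def test_empty_group_rejected(self, registry, planted_small, proxy_model):
        with pytest.raises(ValueError, match="empty"):
            importance_scores(
                proxy_model, planted_small, registry, feature_groups={"bad": []}
            )

    def test_pattern_scores_cover_all_five_patterns(
        self, registry, std_combos, planted_small
    ):
        combo = std_combos["VVSFZL37"]
        train = planted_small.subset("train")
        encs = encode_many(train.sequences(), combo, registry)
        model = MeanPoolLogistic(combo, seed=0).fit(encs, train.labels())
        report = importance_scores(model, planted_small, registry, feature_groups={})
        # feature_groups={} means: no per-group scores, patterns only
        assert set(report.per_pattern) == {
            "geometrical", "electronic", "hydrophobic", "steric", "composition"
        }
        assert len(rank_patterns(report)) == 5


class TestRankPatterns:
    def test_descending_order(self):
        from acepep.evaluation import ImportanceReport

        r = ImportanceReport({}, {"a": 0.3, "b": 0.2}, baseline_acc=0.9)
        assert rank_patterns(r) == ["a", "b"]

    def test_ties_break_alphabetically(self):
        from acepep.evaluation import ImportanceReport

        r = ImportanceReport({}, {"b": 0.3, "a": 0.3, "c": 0.1}, baseline_acc=0.9)
        assert rank_patterns(r) == ["a", "b", "c"]
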