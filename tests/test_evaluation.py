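"""Confusion counts, the four metrics with macro averaging, and CV evaluation."""

import numpy as np
import pytest

from vewselect import (
    GeneSubset,
    aggregate_runs,
    compute_metrics,
    confusion_counts,
    crossval_evaluate,
)
from .conftest import make_dataset


def brute_force_counts(y_true, y_pred, positive):
    """Independent one-vs-rest tally, sample by sample."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}


class TestConfusionCounts:
    def test_binary_positive_class_view(self):
        y_true = list("+++++-----")
        y_pred = list("+++---+---").copy()
        y_pred = ["+", "+", "+", "-", "-", "-", "-", "-", "-", "+"]
        cc = confusion_counts(y_true, y_pred)
        view = cc.binary_view(positive="+")
        assert (view["TP"], view["FN"], view["TN"], view["FP"]) == (3, 2, 4, 1)
        assert view["P"] == 5 and view["N"] == 5

    def test_perfect_prediction_has_no_errors(self):
        y = ["a", "b", "c", "a", "b"]
        cc = confusion_counts(y, y)
        for counts in cc.per_class().values():
            assert counts["FP"] == 0 and counts["FN"] == 0

    def test_three_class_matches_brute_force(self):
        rng = np.random.default_rng(5)
        classes = ["x", "y", "z"]
        y_true = rng.choice(classes, 30).tolist()
        y_pred = rng.choice(classes, 30).tolist()
        cc = confusion_counts(y_true, y_pred)
        for c in classes:
            assert cc.per_class()[c] == brute_force_counts(y_true, y_pred, c)

    def test_counts_sum_to_total_for_every_class(self):
        cc = confusion_counts(["a", "b", "a"], ["b", "b", "a"])
        for counts in cc.per_class().values():
            assert sum(counts.values()) == 3

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_counts(["a", "q"], ["a", "a"], classes=["a", "b"])


class TestComputeMetrics:
    @pytest.fixture
    def skewed(self):
        y_true = ["+"] * 5 + ["-"] * 5
        y_pred = ["+", "+", "+", "-", "-", "-", "-", "-", "-", "+"]
        return confusion_counts(y_true, y_pred)

    def test_positive_class_values(self, skewed):
        rep = compute_metrics(skewed)
        assert rep.acc == pytest.approx(0.7)
        assert rep.per_class["+"]["precision"] == pytest.approx(0.75)
        assert rep.per_class["+"]["recall"] == pytest.approx(0.6)
        assert rep.per_class["+"]["f1"] == pytest.approx(0.6667, abs=1e-4)

    def test_macro_averages(self, skewed):
        rep = compute_metrics(skewed)
        # negative class: precision 4/6, recall 4/5
        assert rep.precision == pytest.approx((0.75 + 4 / 6) / 2, abs=1e-4)
        assert rep.recall == pytest.approx(0.7)

    def test_perfect_classifier_scores_one(self):
        rep = compute_metrics(confusion_counts(["a", "b"], ["a", "b"]))
        assert (rep.acc, rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_constant_predictor_on_balanced_binary(self):
        y_true = ["a"] * 10 + ["b"] * 10
        rep = compute_metrics(confusion_counts(y_true, ["a"] * 20))
        assert rep.acc == 0.5
        assert rep.recall == 0.5  # macro: recall 1 for 'a', 0 for 'b'
        assert rep.per_class["b"]["precision"] == 0.0  # zero-denominator rule

    def test_macro_f1_between_class_extremes(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            y_true = rng.choice(["a", "b", "c"], 25)
            y_pred = rng.choice(["a", "b", "c"], 25)
            rep = compute_metrics(confusion_counts(y_true, y_pred))
            f1s = [v["f1"] for v in rep.per_class.values()]
            assert min(f1s) - 1e-12 <= rep.f1 <= max(f1s) + 1e-12

    def test_agrees_with_sklearn_macro_scores(self):
        from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                                     recall_score)

        rng = np.random.default_rng(17)
        for _ in range(100):
            k = rng.integers(2, 4)
            y_true = rng.choice([f"c{i}" for i in range(k)], 40)
            y_pred = rng.choice([f"c{i}" for i in range(k)], 40)
            classes = [f"c{i}" for i in range(k)]
            rep = compute_metrics(confusion_counts(y_true, y_pred, classes=classes))
            assert rep.acc == pytest.approx(accuracy_score(y_true, y_pred))
            kw = dict(average="macro", zero_division=0, labels=classes)
            assert rep.precision == pytest.approx(precision_score(y_true, y_pred, **kw))
            assert rep.recall == pytest.approx(recall_score(y_true, y_pred, **kw))
            assert rep.f1 == pytest.approx(f1_score(y_true, y_pred, **kw))


class TestCrossval:
    @pytest.mark.parametrize("classifier", ["dt", "svm", "lr"])
    def test_separable_data_scores_perfectly(self, separable_dataset, classifier):
        subset = GeneSubset(np.array([0]), ("g0",))
        report = crossval_evaluate(separable_dataset, subset, classifier,
                                   folds=5, seed=0)
        assert report.metric_means["acc"] == 1.0

    def test_stratification_contract(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.uniform(0, 1, (100, 5)),
                          labels=["a"] * 50 + ["b"] * 50)
        from sklearn.model_selection import StratifiedKFold
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test in splitter.split(ds.values, ds.labels):
            labels = ds.labels[test]
            assert len(test) == 10
            assert (labels == "a").sum() == 5

    def test_seed_determinism(self, separable_dataset):
        subset = GeneSubset.full(separable_dataset)
        a = crossval_evaluate(separable_dataset, subset, "dt", folds=5, seed=3)
        b = crossval_evaluate(separable_dataset, subset, "dt", folds=5, seed=3)
        assert a.metric_means == b.metric_means
        assert [m.as_dict() for m in a.fold_metrics] == [m.as_dict() for m in b.fold_metrics]

    def test_small_class_reduces_folds_with_warning(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.uniform(0, 1, (13, 4)), labels=["a"] * 10 + ["b"] * 3)
        with pytest.warns(UserWarning, match="folds reduced"):
            report = crossval_evaluate(ds, GeneSubset.full(ds), "dt", folds=10, seed=0)
        assert report.n_folds == 3


class TestAggregateRuns:
    def _report(self, acc):
        from vewselect.evaluation import CVReport, METRIC_NAMES
        means = {m: acc for m in METRIC_NAMES}
        return CVReport("dt", 10, (), means, {m: 0.0 for m in METRIC_NAMES})

    def test_single_report_is_identity_with_zero_sd(self):
        agg = aggregate_runs([self._report(0.8)])
        assert agg.metric_means["acc"] == 0.8 and agg.metric_sds["acc"] == 0.0

    def test_mean_of_two_runs(self):
        agg = aggregate_runs([self._report(0.8), self._report(0.9)])
        assert agg.metric_means["acc"] == pytest.approx(0.85)
        assert agg.metric_sds["acc"] > 0

    def test_identical_runs_have_zero_sd(self):
        agg = aggregate_runs([self._report(0.7)] * 10)
        assert agg.metric_sds["acc"] == 0.0

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([])
        from vewselect.evaluation import CVReport, METRIC_NAMES
        other = CVReport("svm", 10, (), {m: 0.5 for m in METRIC_NAMES},
                         {m: 0.0 for m in METRIC_NAMES})
        with pytest.raises(ValueError, match="mixed"):
            aggregate_runs([self._report(0.5), other])
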