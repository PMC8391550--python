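"""Cross-validation structure, metrics, ROC, significance tests and reporting."""

import numpy as np
import pytest
from scipy import stats as spstats

from hsitissue import (
    confusion,
    lopocv_split,
    macro_average,
    one_vs_all_metrics,
    paired_t_test,
    roc_curve,
    run_cv,
)
from hsitissue.core import AnnotationMask, TissueClassSet
from hsitissue.evaluation import CVReport, ConfusionMatrix, FoldResult
from hsitissue.report import error_map, metrics_table, render_report


class TestLopocvSplit:
    def test_eight_subjects_give_eight_folds(self):
        ids = [f"subject_{i}" for i in range(8)]
        folds = lopocv_split(ids)
        assert len(folds) == 8
        assert [test for _, test in folds] == ids

    def test_test_subject_never_in_training(self):
        for train, test in lopocv_split(list("abcde")):
            assert test not in train
            assert len(train) == 4

    def test_three_subject_enumeration(self):
        folds = lopocv_split(["1", "2", "3"])
        assert folds == [(["2", "3"], "1"), (["1", "3"], "2"), (["1", "2"], "3")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            lopocv_split(["a", "a", "b"])


class TestConfusion:
    def test_perfect_predictions_give_identity(self):
        labels = np.array([1, 2, 3, 4, 5, 6, 7] * 3)
        cm = confusion(labels, labels)
        np.testing.assert_array_equal(cm.normalized, np.eye(7))

    def test_two_class_example_counted_by_hand(self):
        cs = TissueClassSet(("a", "b"))
        cm = confusion(np.array([1, 1, 2]), np.array([1, 2, 2]), cs)
        np.testing.assert_allclose(cm.normalized, [[0.5, 0.5], [0.0, 1.0]])

    def test_rows_sum_to_one_and_diagonal_is_sensitivity(self, rng):
        true = rng.integers(1, 8, size=400)
        pred = rng.integers(1, 8, size=400)
        cm = confusion(true, pred)
        sums = np.nansum(cm.normalized, axis=1)
        support = cm.counts.sum(axis=1)
        np.testing.assert_allclose(sums[support > 0], 1.0, atol=1e-12)
        for code in range(1, 8):
            if support[code - 1]:
                expected = one_vs_all_metrics(true, pred, code)["sensitivity"]
                assert cm.normalized[code - 1, code - 1] == pytest.approx(expected)

    def test_zero_support_row_flagged_not_divided(self):
        cs = TissueClassSet(("a", "b"))
        cm = confusion(np.array([1, 1]), np.array([1, 2]), cs)
        assert np.all(np.isnan(cm.normalized[1]))

    def test_labels_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="8"):
            confusion(np.array([1, 8]), np.array([1, 1]))


class TestOneVsAll:
    def test_perfect_prediction(self):
        labels = np.array([1, 2, 1, 2])
        m = one_vs_all_metrics(labels, labels, 1)
        assert (m["sensitivity"], m["specificity"], m["dsc"]) == (1.0, 1.0, 1.0)

    def test_counts_plugged_into_formulas(self):
        # TP=3, FN=1, FP=2, TN=4 for class 1
        true = np.array([1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
        pred = np.array([1, 1, 1, 2, 1, 1, 2, 2, 2, 2])
        m = one_vs_all_metrics(true, pred, 1)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(2 / 3, abs=1e-4)
        assert m["dsc"] == pytest.approx(2 / 3, abs=1e-4)

    def test_dsc_is_harmonic_mean_of_precision_and_sensitivity(self, rng):
        for _ in range(20):
            true = rng.integers(1, 4, size=60)
            pred = rng.integers(1, 4, size=60)
            for code in (1, 2, 3):
                m = one_vs_all_metrics(true, pred, code)
                tp = np.sum((true == code) & (pred == code))
                if tp == 0:
                    continue
                precision = tp / np.sum(pred == code)
                recall = m["sensitivity"]
                harmonic = 2 * precision * recall / (precision + recall)
                assert m["dsc"] == pytest.approx(harmonic)

    def test_zero_support_gives_nan_not_zero(self):
        m = one_vs_all_metrics(np.array([2, 2]), np.array([2, 2]), 1)
        assert np.isnan(m["sensitivity"]) and np.isnan(m["dsc"])


class TestMacroAverage:
    def test_simple_means(self):
        assert macro_average([1.0, 1.0, 1.0]) == 1.0
        assert macro_average([0.5, 1.0]) == 0.75

    def test_nan_classes_excluded(self):
        assert macro_average([1.0, np.nan, 0.0]) == 0.5

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValueError):
            macro_average([np.nan, np.nan])

    def test_macro_sensitivity_equals_mean_confusion_diagonal(self, rng):
        true = rng.integers(1, 8, size=700)
        pred = rng.integers(1, 8, size=700)
        cm = confusion(true, pred)
        per_class = [
            one_vs_all_metrics(true, pred, c)["sensitivity"] for c in range(1, 8)
        ]
        assert macro_average(per_class) == pytest.approx(np.nanmean(np.diag(cm.normalized)))


def brute_force_auc(pos_scores, neg_scores):
    """Pairwise-comparison probability with ties counted 1/2."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos_scores
        for n in neg_scores
    )
    return wins / (len(pos_scores) * len(neg_scores))


class TestROC:
    def test_perfect_separation_auc_one(self):
        roc = roc_curve(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]))
        assert roc.auc == 1.0

    def test_uninformative_scores_auc_half(self):
        roc = roc_curve(np.array([1, 0, 1, 0]), np.full(4, 0.5))
        assert roc.auc == 0.5

    def test_worked_example(self):
        # positives (0.9, 0.4), negatives (0.5, 0.1): 3 of 4 pairs won
        roc = roc_curve(np.array([1, 1, 0, 0]), np.array([0.9, 0.4, 0.5, 0.1]))
        assert roc.auc == pytest.approx(0.75)

    def test_auc_equals_pairwise_probability(self, rng):
        for _ in range(30):
            n = rng.integers(4, 40)
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            roc = roc_curve(labels, scores)
            expected = brute_force_auc(scores[labels == 1], scores[labels == 0])
            assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_curve_is_monotone_within_unit_square(self, rng):
        labels = rng.integers(0, 2, size=100)
        labels[0], labels[1] = 0, 1
        roc = roc_curve(labels, rng.normal(size=100))
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
        assert 0 <= roc.auc <= 1

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.ones(5), np.arange(5.0))


class TestPairedTTest:
    def test_textbook_example(self):
        """Differences (0.1, 0.2, 0.0): t = mean/(sd/sqrt(3)), df = 2."""
        a = np.array([0.5, 0.7, 0.3])
        b = a - np.array([0.1, 0.2, 0.0])
        res = paired_t_test(a, b)
        d = np.array([0.1, 0.2, 0.0])
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_expected = 2 * spstats.t.sf(abs(t_expected), df=2)
        assert res["t"] == pytest.approx(t_expected, abs=1e-4)
        assert res["t"] == pytest.approx(1.7321, abs=1e-4)
        assert res["p"] == pytest.approx(p_expected, abs=1e-6)
        assert res["p"] == pytest.approx(0.2254, abs=1e-4)
        assert res["df"] == 2

    def test_identical_samples_are_degenerate(self):
        res = paired_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["degenerate"] and np.isnan(res["p"])

    def test_swapping_negates_t_preserves_p(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        fwd, rev = paired_t_test(a, b), paired_t_test(b, a)
        assert fwd["t"] == pytest.approx(-rev["t"])
        assert fwd["p"] == pytest.approx(rev["p"])

    def test_significance_stars(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        res = paired_t_test(base + 5.0 + 0.01 * rng.normal(size=10), base)
        assert res["stars"] == "**"


class TestFoldStructure:
    def test_leaked_subject_rejected(self):
        with pytest.raises(ValueError, match="leaked"):
            FoldResult(
                test_subject="s1",
                train_subjects=("s1", "s2"),
                true=np.array([1]),
                predicted=np.array([1]),
                scores=np.zeros((1, 7)),
                confusion=confusion(np.array([1]), np.array([1])),
                per_class={},
            )


def _fake_report(name, rng, n_folds=3):
    """Assemble a CVReport from random predictions without any training."""
    cs = TissueClassSet()
    folds = []
    for i in range(n_folds):
        true = rng.integers(1, 8, size=200)
        pred = np.where(rng.random(200) < 0.7, true, rng.integers(1, 8, size=200))
        scores = rng.normal(size=(200, 7))
        scores[np.arange(200), pred - 1] += 3.0
        from hsitissue.evaluation import one_vs_all_metrics as ova

        folds.append(
            FoldResult(
                test_subject=f"s{i}",
                train_subjects=tuple(f"s{j}" for j in range(n_folds) if j != i),
                true=true,
                predicted=pred,
                scores=scores,
                confusion=confusion(true, pred, cs),
                per_class={c: ova(true, pred, c) for c in cs.codes},
            )
        )
    return CVReport(name, cs, folds)


class TestReporting:
    def test_summary_standard_error_definition(self, rng):
        report = _fake_report("CNN", rng)
        summary = report.summary("sensitivity")
        values = report.per_class_metric("sensitivity")[1]
        assert summary[1]["se"] == pytest.approx(values.std(ddof=1) / np.sqrt(3))

    def test_render_report_writes_bundle(self, rng, tmp_path):
        reports = {name: _fake_report(name, rng) for name in ("CNN", "SVM")}
        bundle = render_report(reports, tmp_path)
        for artifact in (
            "confusion_matrices.png",
            "roc_curves.png",
            "metric_bars.png",
            "metrics.csv",
            "metrics.json",
        ):
            assert (tmp_path / artifact).exists()
        assert set(bundle["models"]) == {"CNN", "SVM"}
        table = metrics_table(reports)
        assert len(table) == 2 * 3  # 2 models x 3 metrics
        assert all(label in table.columns for label in TissueClassSet().labels)

    def test_error_map_blacks_out_agreement_and_colors_mistakes(self):
        cs = TissueClassSet()
        labels = np.zeros((4, 4), dtype=int)
        labels[1, 1] = cs.code("nerve")
        labels[2, 2] = cs.code("artery")
        mask = AnnotationMask(labels, cs)
        predicted = labels.copy()
        img = error_map(mask, predicted)
        assert img.sum() == 0  # perfect agreement -> all black
        predicted[1, 1] = cs.code("muscle")
        img = error_map(mask, predicted)
        assert tuple(img[1, 1]) == cs.color(cs.code("muscle"))
        assert img[0, 0].sum() == 0  # unlabeled stays black
        with pytest.raises(ValueError):
            error_map(mask, predicted[:3])


class TestRunCV:
    def test_two_subject_cohort_yields_two_structured_folds(self, separable_cohort):
        from hsitissue import CNNConfig

        report = run_cv(
            separable_cohort[:2], "CNN",
            cnn_config=CNNConfig(epochs=2, batch_size=32),
        )
        assert len(report.folds) == 2
        for fold in report.folds:
            assert fold.test_subject not in fold.train_subjects

    def test_unknown_configuration_rejected(self, separable_cohort):
        with pytest.raises(ValueError, match="unknown model"):
            run_cv(separable_cohort[:2], "FOREST")
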