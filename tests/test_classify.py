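"""SVM training, confusion metrics, ROC tabulation and comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batsel import (
    compare_reports,
    confusion_counts,
    cross_validate,
    generate_dataset,
    mean_tpr,
    metrics_report,
    report_from_percent_metrics,
    roc_table,
    train_svm,
)
from batsel.classify import ConfusionCounts, trapezoid_auc


class TestTrainSvm:
    def test_separable_toy_data_fits_exactly(self):
        X = np.array([[0, 0, 0, 5, 5, 5], [1, 0, 1, 6, 5, 6]], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        model = train_svm(X, y, kernel="linear")
        np.testing.assert_array_equal(model.predict(X), y)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 30))
        y = rng.integers(0, 2, size=30)
        a = train_svm(X, y, seed=3).predict(X)
        b = train_svm(X, y, seed=3).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_svm(np.zeros((2, 4)), np.ones(4, dtype=int))

    def test_selected_genes_beat_permuted_labels(self):
        margins = []
        for seed in range(10):
            x, y, truth = generate_dataset(n_genes=40, n_samples=40,
                                           n_informative=5, effect_size=2.0,
                                           seed=seed)
            sel = np.isin(x.gene_ids, list(truth.informative))
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(y)
            real = cross_validate(x.values[sel], y, folds=4, seed=seed)
            null = cross_validate(x.values[sel], y_perm, folds=4, seed=seed)
            margins.append(real.accuracy - null.accuracy)
        assert np.mean(margins) >= 0.3


class TestConfusionCounts:
    def test_perfect_prediction(self):
        c = confusion_counts([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.tpv, c.fpv, c.fnv, c.tnv) == (2, 0, 0, 2)

    def test_inverted_prediction(self):
        c = confusion_counts([1, 0, 1], [0, 1, 0])
        assert (c.tpv, c.tnv) == (0, 0)
        assert (c.fpv, c.fnv) == (1, 2)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 2, size=50)
        y_pred = rng.integers(0, 2, size=50)
        c = confusion_counts(y_true, y_pred)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for t, p in zip(y_true, y_pred):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tpv, c.fpv, c.fnv, c.tnv) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"])
        assert c.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts([0, 1], [0, 1, 1])


class TestMetricsReport:
    def test_symmetric_counts(self):
        r = metrics_report(ConfusionCounts(9, 1, 1, 9))
        for name in ("precision", "recall", "f_measure", "specificity",
                     "accuracy"):
            assert getattr(r, name) == pytest.approx(0.9)

    def test_no_false_positives_gives_precision_one(self):
        r = metrics_report(ConfusionCounts(5, 0, 2, 3))
        assert r.precision == 1.0

    def test_zero_denominator_flagged_not_zero(self):
        r = metrics_report(ConfusionCounts(0, 0, 3, 7))
        assert r.precision is None
        assert "precision" in r.undefined
        assert r.accuracy == pytest.approx(0.7)

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_ranges_and_harmonic_mean_bound(self, counts):
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        r = metrics_report(ConfusionCounts(tp, fp, fn, tn))
        for name in ("precision", "recall", "f_measure", "specificity",
                     "accuracy"):
            v = getattr(r, name)
            assert v is None or 0.0 <= v <= 1.0
        if r.f_measure is not None:
            assert min(r.precision, r.recall) - 1e-12 <= r.f_measure
            assert r.f_measure <= max(r.precision, r.recall) + 1e-12
        expect = (tp + fp + fn + tn == 0)
        assert r.counts.total == tp + fp + fn + tn or expect

    def test_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 30, size=4)
            r = metrics_report(ConfusionCounts(tp, fp, fn, tn))
            assert r.precision == pytest.approx(tp / (tp + fp))
            assert r.recall == pytest.approx(tp / (tp + fn))
            assert r.specificity == pytest.approx(tn / (tn + fp))
            assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))
            assert r.f_measure == pytest.approx(
                2 * r.precision * r.recall / (r.precision + r.recall))


class TestRocTable:
    def test_separating_scores_reach_corner(self):
        y = np.array([0, 0, 1, 1])
        pts = roc_table(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert (0.0, 1.0) in pts

    def test_extreme_thresholds(self):
        y = np.array([0, 1, 0, 1])
        s = np.array([0.2, 0.4, 0.3, 0.9])
        pts = roc_table(s, y, thresholds=[-10.0, 10.0])
        assert (1.0, 1.0) in pts and (0.0, 0.0) in pts

    def test_counting_matches_brute_force(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=40)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=40)
        s = rng.normal(size=40)
        ts = np.linspace(-2, 2, 9)
        pts = roc_table(s, y, thresholds=ts)
        expect = set()
        for t in ts:
            pred = (s > t).astype(int)
            tpr = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
            fpr = ((pred == 1) & (y == 0)).sum() / (y == 0).sum()
            expect.add((round(fpr, 12), round(tpr, 12)))
        assert {(round(f, 12), round(t, 12)) for f, t in pts} == expect

    def test_rates_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 15)
        s = rng.normal(size=30)
        ts = np.sort(rng.normal(size=11))
        tprs, fprs = [], []
        for t in ts:
            pred = s > t
            tprs.append((pred & (y == 1)).sum())
            fprs.append((pred & (y == 0)).sum())
        assert all(a >= b for a, b in zip(tprs, tprs[1:]))
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_table([0.5, 0.6], [1, 1])


class TestMeanTpr:
    def test_published_operating_points_first_method(self):
        # five tabulated TPR values averaging to 76.5%
        tprs = [0.72, 0.76, 0.77, 0.783, 0.790]
        pts = [(fpr, tpr) for fpr, tpr in zip([.02, .04, .06, .08, 1], tprs)]
        assert round(100 * mean_tpr(pts), 1) == 76.5

    def test_published_operating_points_second_method(self):
        tprs = [0.83, 0.86, 0.865, 0.870, 0.890]
        pts = [(fpr, tpr) for fpr, tpr in zip([.02, .04, .06, .08, 1], tprs)]
        assert round(100 * mean_tpr(pts), 1) == 86.3

    def test_constant_unit_tpr(self):
        assert mean_tpr([(0.1, 1.0), (0.5, 1.0)]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_tpr([])

    def test_auc_of_perfect_curve(self):
        assert trapezoid_auc([(0.0, 1.0)]) == pytest.approx(1.0)


class TestCompareReports:
    @pytest.fixture
    def published_reports(self):
        return {
            "proposed": report_from_percent_metrics(91.59, 90.66, 91.13, 90.5, 91.56),
            "dca": report_from_percent_metrics(89.75, 70.0, 80.92, 69.45, 83.50),
            "dcn": report_from_percent_metrics(90.94, 76.66, 85.91, 75.61, 86.75),
        }

    def test_published_differences(self, published_reports):
        table = compare_reports(published_reports, reference="proposed")
        assert table.loc["precision", "dca"] == 1.84
        assert table.loc["recall", "dca"] == 20.66
        assert table.loc["f_measure", "dca"] == 10.21
        assert table.loc["specificity", "dca"] == 21.05
        assert table.loc["accuracy", "dca"] == 8.06

    def test_self_comparison_zero(self, published_reports):
        table = compare_reports({"a": published_reports["dca"],
                                 "b": published_reports["dca"]})
        assert (table["b"] == 0.0).all()

    def test_antisymmetry(self, published_reports):
        fwd = compare_reports(published_reports, reference="proposed")["dcn"]
        rev = compare_reports(published_reports, reference="dcn")["proposed"]
        np.testing.assert_allclose(fwd.to_numpy(dtype=float),
                                   -rev.to_numpy(dtype=float))

    def test_requires_two_reports(self, published_reports):
        with pytest.raises(ValueError, match="at least 2"):
            compare_reports({"only": published_reports["dca"]})


class TestCrossValidate:
    def test_noise_only_near_chance(self):
        accs = []
        for seed in range(10):
            x, y, _ = generate_dataset(n_genes=50, n_samples=40,
                                       n_informative=0, effect_size=0.0,
                                       seed=seed)
            accs.append(cross_validate(x, y, folds=4, seed=seed).accuracy)
        assert all(0.35 <= a <= 0.65 for a in accs)

    def test_separable_planted_data_perfect(self):
        x, y, truth = generate_dataset(n_genes=20, n_samples=30,
                                       n_informative=5, effect_size=3.0,
                                       noise_sd=0.0, seed=0)
        sel = np.isin(x.gene_ids, list(truth.informative))
        rep = cross_validate(x.values[sel] + 0.01 * np.random.default_rng(0)
                             .normal(size=(5, 30)), y, folds=5, seed=0)
        assert rep.accuracy == 1.0

    def test_stratified_fold_shapes(self):
        from sklearn.model_selection import StratifiedKFold
        y = np.array([0] * 12 + [1] * 12)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        sizes, ratios = [], []
        for _, te in skf.split(np.zeros((24, 1)), y):
            sizes.append(len(te))
            ratios.append(y[te].mean())
        assert max(sizes) - min(sizes) <= 1
        assert all(abs(r - 0.5) <= 0.15 for r in ratios)

    def test_infeasible_stratification_rejected(self):
        x, y, _ = generate_dataset(n_genes=5, n_samples=6, n_informative=0,
                                   seed=0)
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(x, y, folds=5, seed=0)

    def test_selector_runs_inside_folds(self):
        calls = []

        def selector(G, y_train, fold_seed):
            calls.append(G.shape[1])
            mask = np.zeros(G.shape[0], bool)
            mask[:3] = True
            return mask

        x, y, _ = generate_dataset(n_genes=10, n_samples=20, n_informative=2,
                                   seed=1)
        cross_validate(x, y, selector=selector, folds=4, seed=0)
        assert len(calls) == 4
        assert all(c == 15 for c in calls)  # training folds only
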