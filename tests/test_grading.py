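"""Band selection, classifiers and confusion-matrix metrics."""

import numpy as np
import pytest

from aphiddrs.grading import (
    ClassifierSpec,
    ConfusionMatrix,
    PearsonBandSelector,
    SAMClassifier,
    confusion_metrics,
    make_classifier,
    pearson_band_correlation,
    predict_map,
    sam_classify,
    select_bands,
    stratified_split,
    train_grading_model,
)

# Printed held-out confusion counts of the reference field study
# (rows = predicted, columns = truth; classes Health, Grade 1..4; n = 20).
TABLE3_COUNTS = np.array(
    [
        [6, 1, 0, 0, 0],
        [0, 5, 1, 1, 0],
        [0, 0, 3, 0, 0],
        [0, 0, 0, 1, 1],
        [0, 0, 0, 0, 1],
    ]
)


class TestPearson:
    def test_perfect_positive_correlation(self):
        g = np.repeat(np.arange(5), 12)  # 60 points
        table = pearson_band_correlation(g, g[:, None].astype(float))
        assert table.r[0] == pytest.approx(1.0)
        assert table.p[0] < 0.001
        assert table.to_frame()["significance"][0] == "***"

    def test_perfect_negative_correlation(self):
        g = np.arange(10)
        table = pearson_band_correlation(g, -g[:, None].astype(float))
        assert table.r[0] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        g = np.array([0, 1, 2, 3, 4])
        f = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        table = pearson_band_correlation(g, f[:, None])
        assert table.r[0] == pytest.approx(0.8, rel=1e-12)

    def test_constant_feature_flagged_and_excluded(self):
        g = np.array([0, 1, 2, 3, 4])
        X = np.column_stack([g.astype(float), np.full(5, 2.0)])
        table = pearson_band_correlation(g, X, labels=("a", "b"))
        assert table.defined[0] and not table.defined[1]
        assert np.isnan(table.r[1])
        sel = select_bands(table, alpha=0.05)
        assert sel.labels == ("a",)

    def test_agrees_with_brute_force_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(4, 20)
            g = rng.normal(size=n)
            f = rng.normal(size=n)
            if np.ptp(g) == 0:
                continue
            table = pearson_band_correlation(g, f[:, None])
            num = np.sum((g - g.mean()) * (f - f.mean()))
            den = np.sqrt(np.sum((g - g.mean()) ** 2) * np.sum((f - f.mean()) ** 2))
            assert table.r[0] == pytest.approx(num / den, rel=1e-10)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="3 points"):
            pearson_band_correlation([0, 1], np.ones((2, 1)))
        with pytest.raises(ValueError, match="all equal"):
            pearson_band_correlation([1, 1, 1], np.ones((3, 1)))


class TestSelection:
    def test_exactly_significant_features_selected(self):
        from aphiddrs.grading import CorrelationTable

        ps = np.array([0.5, 0.004, 0.0005, 0.002, 0.009, 0.0001, 0.2, 0.008, 0.3])
        labels = tuple(f"s{i}" for i in range(9))
        table = CorrelationTable(
            labels, np.zeros(9), ps, np.ones(9, dtype=bool)
        )
        sel = select_bands(table, 0.01)
        assert sel.labels == ("s1", "s2", "s3", "s4", "s5", "s7")
        assert len(sel.labels) == 6

    def test_alpha_one_selects_all_defined(self):
        from aphiddrs.grading import CorrelationTable

        table = CorrelationTable(
            ("a", "b"), np.array([0.5, 0.1]), np.array([0.3, 0.9]),
            np.ones(2, bool),
        )
        assert select_bands(table, 1.0).labels == ("a", "b")

    def test_empty_selection_errors_with_hint(self):
        from aphiddrs.grading import CorrelationTable

        table = CorrelationTable(
            ("a",), np.array([0.1]), np.array([0.5]), np.ones(1, bool)
        )
        with pytest.raises(ValueError, match="alpha"):
            select_bands(table, 0.01)

    def test_sklearn_selector_transform(self):
        rng = np.random.default_rng(0)
        y = np.repeat(np.arange(5), 12)
        signal = y + rng.normal(0, 0.1, 60)
        noise = rng.normal(size=60)
        X = np.column_stack([signal, noise])
        sel = PearsonBandSelector(alpha=0.01).fit(X, y)
        assert sel.support_.tolist() == [True, False]
        assert sel.transform(X).shape == (60, 1)


class TestSAM:
    def test_exact_reference_match(self):
        refs = {0: np.array([1.0, 0.0]), 1: np.array([0.0, 1.0])}
        assert sam_classify(np.array([1.0, 0.0]), refs)[0] == 0

    def test_tie_breaks_to_lower_class(self):
        refs = {0: np.array([1.0, 0.0]), 1: np.array([0.0, 1.0])}
        assert sam_classify(np.array([1.0, 1.0]), refs)[0] == 0

    def test_scale_invariance(self):
        refs = {0: np.array([1.0, 0.0]), 1: np.array([1.0, 1.0])}
        x = np.array([2.0, 0.0])
        assert sam_classify(x, refs)[0] == sam_classify(5.0 * x, refs)[0] == 0

    def test_zero_norm_errors(self):
        refs = {0: np.array([1.0, 0.0])}
        with pytest.raises(ValueError, match="zero-norm"):
            sam_classify(np.array([0.0, 0.0]), refs)

    def test_classifier_uses_class_means(self):
        X = np.array([[1.0, 0.0], [3.0, 0.0], [0.0, 2.0], [0.0, 4.0]])
        y = np.array([5, 5, 9, 9])
        clf = SAMClassifier().fit(X, y)
        assert np.allclose(clf.references_[0], [2.0, 0.0])
        assert clf.predict(np.array([[10.0, 0.1]]))[0] == 5
        # scale invariance end to end
        assert clf.predict(np.array([[100.0, 1.0]]))[0] == 5


class TestConfusionMatrix:
    def test_reference_table_metrics(self):
        cm = ConfusionMatrix(
            TABLE3_COUNTS, labels=("Health", "G1", "G2", "G3", "G4")
        )
        assert cm.n == 20
        assert cm.oa == pytest.approx(0.80)
        assert cm.kappa == pytest.approx(218 / 298, rel=1e-12)
        assert round(cm.kappa, 2) == 0.73
        assert np.allclose(cm.ua, [6 / 7, 5 / 7, 1.0, 0.5, 1.0])
        assert np.allclose(cm.pa, [1.0, 5 / 6, 0.75, 0.5, 0.5])

    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 2, 1, 0])
        cm = confusion_metrics(y, y)
        assert cm.oa == 1.0 and cm.kappa == 1.0
        assert np.all(np.diag(cm.counts) == [2, 2, 2])

    def test_kappa_zero_for_single_class_predictor(self):
        truth = np.repeat([0, 1, 2, 3], 5)
        pred = np.zeros(20, dtype=int)
        cm = confusion_metrics(pred, truth, labels=[0, 1, 2, 3])
        assert cm.kappa == pytest.approx(0.0)

    def test_metric_consistency_identity(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 5, 100)
        truth = rng.integers(0, 5, 100)
        cm = confusion_metrics(pred, truth)
        col_totals = cm.counts.sum(axis=0)
        pa = np.nan_to_num(cm.pa)
        assert np.sum(pa * col_totals) == pytest.approx(cm.oa * cm.n)

    def test_brute_force_oracle_on_random_instances(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(11)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(5, 40))
            pred = rng.integers(0, k, n)
            truth = rng.integers(0, k, n)
            cm = confusion_metrics(pred, truth, labels=range(k))
            # brute-force loop oracle over the definitions
            counts = np.zeros((k, k))
            for p, t in zip(pred, truth):
                counts[p, t] += 1
            oa = sum(counts[i, i] for i in range(k)) / n
            chance = sum(counts[i].sum() * counts[:, i].sum() for i in range(k))
            kappa = (n * np.trace(counts) - chance) / (n * n - chance)
            assert cm.oa == pytest.approx(oa, rel=1e-12)
            assert cm.kappa == pytest.approx(kappa, rel=1e-10)
            # independent library cross-check
            assert cm.kappa == pytest.approx(
                cohen_kappa_score(pred, truth), rel=1e-10
            )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            confusion_metrics([], [])


class TestSplit:
    def test_default_counts_give_40_20(self):
        grades = np.repeat(np.arange(5), (20, 20, 10, 6, 4))
        train, test = stratified_split(grades, seed=0)
        assert len(train) == 40 and len(test) == 20
        # stratification keeps every grade in both splits
        assert set(grades[train]) == set(range(5))
        assert set(grades[test]) == set(range(5))

    def test_small_grade_warns_best_effort(self):
        grades = np.array([0] * 10 + [1] * 2)
        with pytest.warns(UserWarning, match="fewer"):
            train, test = stratified_split(grades, seed=0)
        assert len(train) + len(test) == 12

    def test_same_seed_identical(self):
        grades = np.repeat(np.arange(5), (20, 20, 10, 6, 4))
        a = stratified_split(grades, seed=3)
        b = stratified_split(grades, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestTraining:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        grades = np.repeat(np.arange(5), (20, 20, 10, 6, 4))
        X = grades[:, None] * np.ones((1, 4)) + rng.normal(0, 0.01, (60, 4))
        return X, grades

    def test_separable_features_perfect_rf(self):
        X, y = self._separable()
        res = train_grading_model(
            X, y, ClassifierSpec("rf", tune=False, params={"n_estimators": 100})
        )
        assert res.confusion.oa == 1.0
        assert len(res.train_idx) == 40 and len(res.test_idx) == 20

    def test_same_seed_reproducible(self):
        X, y = self._separable()
        spec = ClassifierSpec("rf", tune=False, params={"n_estimators": 50})
        a = train_grading_model(X, y, spec)
        b = train_grading_model(X, y, spec)
        assert np.array_equal(a.confusion.counts, b.confusion.counts)
        assert np.array_equal(a.train_idx, b.train_idx)

    @pytest.mark.parametrize("algo", ["rf", "sam", "dt", "svm", "bp"])
    def test_all_algorithms_run(self, algo):
        X, y = self._separable(1)
        spec = ClassifierSpec(algo, tune=False)
        res = train_grading_model(X, y, spec)
        assert res.confusion.n == 20
        assert 0.0 <= res.confusion.oa <= 1.0

    def test_cv_tuning_runs_on_default_grid(self):
        X, y = self._separable(2)
        res = train_grading_model(X, y, ClassifierSpec("dt", tune=True))
        assert res.confusion.oa > 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two grades"):
            train_grading_model(np.ones((10, 2)), np.zeros(10))

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="unsupported"):
            ClassifierSpec("knn")
        with pytest.raises(ValueError, match="cv_folds"):
            ClassifierSpec("rf", cv_folds=1)

    def test_make_classifier_shapes(self):
        est, grid = make_classifier(ClassifierSpec("rf"))
        assert "n_estimators" in grid
        est, grid = make_classifier(ClassifierSpec("sam"))
        assert grid == {}


class TestPredictMap:
    def test_constant_raster_predicts_training_label(self):
        X = np.vstack([np.zeros((5, 3)), np.ones((5, 3))])
        y = np.array([0] * 5 + [3] * 5)
        clf = SAMClassifier().fit(X + 0.1, y)
        raster = np.full((4, 4, 3), 1.1)
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        gm = predict_map(clf, raster, mask)
        assert gm[0, 0] == -1
        assert np.all(gm[mask] == 3)

    def test_missing_feature_planes_error(self):
        clf = SAMClassifier().fit(np.ones((4, 3)) + np.eye(4, 3), [0, 0, 1, 1])
        with pytest.raises(ValueError, match="features"):
            predict_map(clf, np.ones((2, 2, 2)), np.ones((2, 2), bool))

    def test_nan_features_masked_out(self):
        clf = SAMClassifier().fit(np.eye(4, 3) + 1, [0, 0, 1, 1])
        raster = np.ones((2, 2, 3))
        raster[1, 1, 0] = np.nan
        gm = predict_map(clf, raster, np.ones((2, 2), bool))
        assert gm[1, 1] == -1 and gm[0, 0] != -1
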