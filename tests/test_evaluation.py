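import numpy as np
import pandas as pd
import pytest
import sklearn.metrics

import toonet as tn


class TestKfoldPartition:
    def test_equal_split(self):
        ids = [f"s{i}" for i in range(100)]
        labels = ["A"] * 50 + ["B"] * 50
        folds = tn.kfold_partition(ids, labels, k=10, seed=0)
        assert sorted(len(f) for f in folds) == [10] * 10
        assert sorted(s for f in folds for s in f) == sorted(ids)

    def test_same_seed_identical(self):
        ids = [f"s{i}" for i in range(30)]
        labels = ["A", "B", "C"] * 10
        f1 = tn.kfold_partition(ids, labels, k=5, seed=9)
        f2 = tn.kfold_partition(ids, labels, k=5, seed=9)
        assert f1 == f2
        f3 = tn.kfold_partition(ids, labels, k=5, seed=10)
        assert f1 != f3

    def test_stratified_fold_composition(self):
        ids = [f"s{i}" for i in range(100)]
        labels = ["A"] * 30 + ["B"] * 30 + ["C"] * 40
        by_id = dict(zip(ids, labels))
        folds = tn.kfold_partition(ids, labels, k=10, seed=1, stratified=True)
        for fold in folds:
            counts = pd.Series([by_id[s] for s in fold]).value_counts()
            assert counts["A"] == 3 and counts["B"] == 3 and counts["C"] == 4

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tn.kfold_partition(["s1", "s2"], ["A", "B"], k=3)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = tn.confusion(["A", "B", "A"], ["A", "B", "A"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_hand_counted_example(self):
        cm = tn.confusion(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_matches_sklearn_on_random_labels(self, rng):
        classes = ["A", "B", "C", "D"]
        true = rng.choice(classes, size=200).tolist()
        pred = rng.choice(classes, size=200).tolist()
        cm = tn.confusion(true, pred, classes)
        expected = sklearn.metrics.confusion_matrix(true, pred, labels=classes)
        np.testing.assert_array_equal(cm.counts, expected)
        np.testing.assert_array_equal(
            cm.counts.sum(axis=1),
            [true.count(c) for c in classes])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="Z"):
            tn.confusion(["A"], ["Z"], ["A", "B"])


class TestMetricsFromConfusion:
    def test_diagonal_matrix_is_perfect(self):
        cm = tn.ConfusionMatrix(classes=["A", "B"], counts=np.diag([5, 7]))
        m = tn.metrics_from_confusion(cm)
        assert m.overall_accuracy == 1.0
        assert m.macro_sensitivity == 1.0 and m.macro_precision == 1.0

    def test_two_class_hand_arithmetic(self):
        cm = tn.ConfusionMatrix(classes=["A", "B"],
                                counts=np.array([[8, 2], [1, 9]]))
        m = tn.metrics_from_confusion(cm)
        np.testing.assert_allclose(m.per_class["sensitivity"], [0.8, 0.9])
        np.testing.assert_allclose(m.per_class["precision"], [8 / 9, 9 / 11])
        assert m.overall_accuracy == pytest.approx(17 / 20)

    def test_never_predicted_class_gets_zero_precision(self):
        cm = tn.ConfusionMatrix(classes=["A", "B"],
                                counts=np.array([[3, 0], [2, 0]]))
        with pytest.warns(UserWarning, match="never predicted"):
            m = tn.metrics_from_confusion(cm)
        assert m.per_class.loc["B", "precision"] == 0.0

    def test_empty_matrix_rejected(self):
        cm = tn.ConfusionMatrix(classes=["A"], counts=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="empty"):
            tn.metrics_from_confusion(cm)


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def cohort(self):
        cfg = tn.SimulationConfig(n_classes=4, samples_per_class=[20] * 4,
                                  n_genes=200, markers_per_class=4,
                                  marker_effect=8.0, seed=3)
        matrix, labels, truth = tn.simulate(cfg)
        return tn.normalize_by_sample_sum(matrix), labels, truth

    @pytest.fixture(scope="class")
    def result(self, cohort):
        matrix, labels, _ = cohort
        cfg = tn.CVConfig(k=5, repeats=2, n_per_class=4, seed=1,
                          model_kind="logistic")
        return tn.cross_validate(matrix, labels, cfg)

    def test_strong_markers_give_high_accuracy(self, result):
        assert result.mean_accuracy >= 0.95

    def test_every_sample_predicted_once_per_repeat(self, result, cohort):
        matrix, _, _ = cohort
        for rep, group in result.predictions.groupby("repeat"):
            assert sorted(group["sample_id"]) == sorted(matrix.sample_ids)

    def test_two_route_accuracy_equality(self, result):
        # merged-prediction accuracy must equal trace/total of the pooled grid
        merged = (result.predictions["true_label"]
                  == result.predictions["predicted_label"]).mean()
        assert result.pooled_accuracy == pytest.approx(merged)
        assert result.metrics.overall_accuracy == pytest.approx(merged)

    def test_panels_collected_per_fold(self, result):
        assert len(result.panels) == 2 * 5
        for _, _, panel in result.panels:
            assert len(panel) <= 4 * 4

    def test_selection_ignores_held_out_folds(self, cohort):
        """Leakage sentinel: corrupting a sample's expression must not change
        the panel of the fold where that sample is held out."""
        matrix, labels, _ = cohort
        cfg = tn.CVConfig(k=5, repeats=1, n_per_class=4, seed=2,
                          model_kind="logistic")
        baseline = tn.cross_validate(matrix, labels, cfg)
        # reproduce the partition actually used inside cross_validate
        rng = np.random.default_rng(cfg.seed)
        part_seed = int(rng.integers(2**31 - 1))
        folds = tn.kfold_partition(matrix.sample_ids, labels.class_labels,
                                   cfg.k, seed=part_seed, stratified=True)
        victim_fold = 0
        corrupted = matrix.data.copy()
        corrupted.loc[folds[victim_fold]] = 1e6   # sentinel noise
        res2 = tn.cross_validate(tn.ExpressionMatrix(corrupted), labels, cfg)
        panel_before = dict(((r, f), p.gene_ids) for r, f, p in baseline.panels)
        panel_after = dict(((r, f), p.gene_ids) for r, f, p in res2.panels)
        assert panel_before[(0, victim_fold)] == panel_after[(0, victim_fold)]

    def test_scarce_class_suggests_smaller_k(self):
        cfg = tn.SimulationConfig(n_classes=3, samples_per_class=[10, 10, 2],
                                  n_genes=50, markers_per_class=2, seed=0)
        matrix, labels, _ = tn.simulate(cfg)
        with pytest.raises(ValueError, match="smaller k"):
            tn.cross_validate(tn.normalize_by_sample_sum(matrix), labels,
                              tn.CVConfig(k=10, repeats=1, n_per_class=2,
                                          model_kind="logistic"))


class TestSweep:
    def test_single_value_matches_cross_validate(self):
        cfg = tn.SimulationConfig(n_classes=3, samples_per_class=[15] * 3,
                                  n_genes=100, markers_per_class=3,
                                  marker_effect=8.0, seed=5)
        matrix, labels, _ = tn.simulate(cfg)
        matrix = tn.normalize_by_sample_sum(matrix)
        cv_cfg = tn.CVConfig(k=3, repeats=1, n_per_class=3, seed=4,
                             model_kind="logistic")
        table = tn.sweep_feature_number(matrix, labels, cv_cfg, [3])
        direct = tn.cross_validate(matrix, labels, cv_cfg)
        assert len(table) == 1
        assert table.loc[0, "mean_accuracy"] == pytest.approx(direct.mean_accuracy)
        assert table.loc[0, "total_genes"] <= 9

    def test_empty_n_values_rejected(self, small_cohort):
        matrix, labels, _, _ = small_cohort
        with pytest.raises(ValueError, match="non-empty"):
            tn.sweep_feature_number(matrix, labels, tn.CVConfig(), [])


class TestPanelStability:
    def test_identical_panels_count_everywhere(self):
        panel = tn.GenePanel(gene_ids=["a", "b"])
        table = tn.panel_stability([panel] * 100)
        assert table["count"].tolist() == [100, 100]

    def test_disjoint_panels_count_once(self):
        panels = [tn.GenePanel(gene_ids=["a"]), tn.GenePanel(gene_ids=["b"])]
        table = tn.panel_stability(panels)
        assert table["count"].tolist() == [1, 1]
        assert table["gene_id"].tolist() == ["a", "b"]

    def test_planted_markers_more_stable_than_background(self, small_cohort):
        matrix, labels, truth, _ = small_cohort
        cfg = tn.CVConfig(k=5, repeats=2, n_per_class=4, seed=6,
                          model_kind="logistic")
        result = tn.cross_validate(matrix, labels, cfg)
        stability = result.stability().set_index("gene_id")["count"]
        planted = set(truth.all_markers())
        marker_mean = stability[stability.index.isin(planted)].mean()
        others = stability[~stability.index.isin(planted)]
        background_mean = others.mean() if len(others) else 0.0
        assert marker_mean > background_mean


class TestPredictionTableAccuracy:
    def test_all_correct_is_one(self):
        table = pd.DataFrame({"predicted": ["BRCA", "LUNG"],
                              "true_label": ["BRCA", "LUNG"]})
        assert tn.prediction_table_accuracy(table, "predicted") == 1.0

    def test_synonym_spellings_compare_equal(self):
        table = pd.DataFrame({"predicted": ["COADREAD", "UCEC"],
                              "true_label": ["COAD + READ", "CESC"]})
        assert tn.prediction_table_accuracy(table, "predicted") == 0.5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tn.prediction_table_accuracy(pd.DataFrame(columns=["p", "true_label"]), "p")
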