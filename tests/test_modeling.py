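"""Splitting, mutual-information ranking, grid-search tuning and metric
identities of the classification harness."""
import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

import restmdd as rm
from restmdd.modeling import LeakageError


def make_table(n_per_class=20, n_features=30, seed=0, separation=0.0):
    """Synthetic feature table; ``separation`` shifts the first feature's
    class means."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    groups = ["MDD"] * n_per_class + ["HEALTHY"] * n_per_class
    X[:n_per_class, 0] += separation
    ids = [f"s{i:03d}" for i in range(n)]
    cols = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(X, index=pd.Index(ids, name="subject_id"), columns=cols)
    df.insert(0, "group", groups)
    return df


class TestSplit:
    def test_balanced_cohort_splits_exactly(self):
        table = make_table(n_per_class=70)
        split = rm.stratified_subject_split(table, test_size=40, seed=0)
        assert len(split.train_ids) == 100
        assert len(split.test_ids) == 40
        test_groups = table.loc[list(split.test_ids), "group"]
        assert (test_groups == "MDD").sum() == 20
        assert set(split.train_ids) | set(split.test_ids) == set(table.index)
        assert not set(split.train_ids) & set(split.test_ids)

    def test_same_seed_reproduces_partition(self):
        table = make_table(n_per_class=70)
        a = rm.stratified_subject_split(table, 40, seed=3)
        b = rm.stratified_subject_split(table, 40, seed=3)
        assert a == b

    def test_unbalanced_cohort_largest_remainder(self):
        table = make_table(n_per_class=30)
        table = table.iloc[:50]  # 30 MDD / 20 healthy
        split = rm.stratified_subject_split(table, test_size=10, seed=1)
        test_groups = table.loc[list(split.test_ids), "group"]
        assert (test_groups == "MDD").sum() == 6
        assert (test_groups == "HEALTHY").sum() == 4

    def test_zero_test_size_rejected(self):
        with pytest.raises(ValueError):
            rm.stratified_subject_split(make_table(), test_size=0, seed=0)


class TestMIRanking:
    def test_label_copy_ranks_first(self):
        table = make_table(n_per_class=50, seed=1)
        table["f0"] = (table["group"] == "MDD").astype(float)
        ranking = rm.mi_rank_features(table, seed=0)
        assert ranking["feature"].iloc[0] == "f0"
        assert ranking["mi"].iloc[0] == ranking["mi"].max()

    def test_independent_noise_has_near_zero_mi(self):
        """Across 100 null features of n=100, MI estimates stay within
        estimator noise of zero (mean near 0, 95th percentile < 0.1)."""
        table = make_table(n_per_class=50, n_features=100, seed=2)
        ranking = rm.mi_rank_features(table, seed=0)
        assert ranking["mi"].mean() < 0.03
        assert ranking["mi"].quantile(0.95) < 0.1

    def test_ranking_deterministic(self):
        table = make_table(n_per_class=30, seed=3)
        a = rm.mi_rank_features(table, seed=5)
        b = rm.mi_rank_features(table, seed=5)
        assert list(a["feature"]) == list(b["feature"])

    def test_leakage_guard_refuses_test_subjects(self):
        table = make_table(n_per_class=30)
        split = rm.stratified_subject_split(table, 10, seed=0)
        with pytest.raises(LeakageError):
            rm.mi_rank_features(table, seed=0, split=split)

    def test_knn_estimate_matches_quadrature_oracle(self):
        """Gaussian-mixture fixture: X|Y ~ N(+-1, 1), Y ~ Bernoulli(1/2).
        The kNN estimate agrees with numerically integrated ground truth
        within 0.05 nats."""
        mu = 1.0

        def mix(x):
            return 0.5 * (scipy.stats.norm.pdf(x, -mu) +
                          scipy.stats.norm.pdf(x, mu))

        def integrand(x):
            m = mix(x)
            return -m * np.log(m) if m > 0 else 0.0

        h_x = scipy.integrate.quad(integrand, -12, 12, limit=200)[0]
        h_x_given_y = 0.5 * np.log(2 * np.pi * np.e)  # unit-variance normal
        mi_true = h_x - h_x_given_y

        rng = np.random.default_rng(11)
        n = 2000
        y = np.repeat([1, 0], n)
        x = rng.normal(np.where(y == 1, mu, -mu), 1.0)
        df = pd.DataFrame({"x": x},
                          index=pd.Index([f"s{i}" for i in range(2 * n)],
                                         name="subject_id"))
        df.insert(0, "group", np.where(y == 1, "MDD", "HEALTHY"))
        est = rm.mi_rank_features(df, seed=0)["mi"].iloc[0]
        assert est == pytest.approx(mi_true, abs=0.05)


class TestSelectTopK:
    def test_top_k_preserves_order(self):
        ranking = pd.DataFrame({"feature": list("abcde"),
                                "mi": [5, 4, 3, 2, 1]})
        assert rm.select_top_k(ranking, 3) == ["a", "b", "c"]
        assert rm.select_top_k(ranking, 5) == list("abcde")

    def test_invalid_k_rejected(self):
        ranking = pd.DataFrame({"feature": ["a"], "mi": [1.0]})
        with pytest.raises(ValueError):
            rm.select_top_k(ranking, 0)
        with pytest.raises(ValueError):
            rm.select_top_k(ranking, 2)


class TestGridSearch:
    def test_single_point_grid_is_chosen(self):
        table = make_table(n_per_class=20, separation=3.0)
        model = rm.grid_search_cv("DT", table, folds=5, seed=0,
                                  grid={"max_depth": [2]})
        assert model.best_params == {"max_depth": 2}
        assert 0.0 <= model.cv_accuracy <= 1.0

    def test_separable_fixture_reaches_perfect_cv_accuracy(self):
        table = make_table(n_per_class=20, separation=8.0)
        model = rm.grid_search_cv("DT", table, folds=5, seed=0)
        assert model.cv_accuracy == 1.0

    def test_same_seed_same_hyperparameters(self):
        table = make_table(n_per_class=25, separation=1.0, seed=4)
        a = rm.grid_search_cv("GBOOST", table, folds=5, seed=2)
        b = rm.grid_search_cv("GBOOST", table, folds=5, seed=2)
        assert a.best_params == b.best_params
        assert a.cv_accuracy == b.cv_accuracy

    def test_too_many_folds_rejected(self):
        table = make_table(n_per_class=4)
        with pytest.raises(ValueError, match="folds"):
            rm.grid_search_cv("NB", table, folds=10, seed=0)

    def test_grids_contain_reference_operating_points(self):
        """Every family's default grid offers the canonical tuned values
        (e.g. depth-2 random-splitter tree, RBF C=1 SVM, 50-tree forest,
        5-NN, lr 0.5/depth 5/50 trees/gamma 3 boosting)."""
        grids = rm.default_model_grids()
        _, g = grids["DT"]
        assert 2 in g["max_depth"] and "random" in g["splitter"]
        assert 1 in g["min_samples_leaf"] and 2 in g["min_samples_split"]
        _, g = grids["SVM"]
        assert "rbf" in g["clf__kernel"] and 1.0 in g["clf__C"]
        assert "scale" in g["clf__gamma"]
        _, g = grids["RF"]
        assert 50 in g["n_estimators"] and 10 in g["min_samples_split"]
        assert 2 in g["min_samples_leaf"]
        _, g = grids["KNN"]
        assert 5 in g["clf__n_neighbors"] and 30 in g["clf__leaf_size"]
        assert "uniform" in g["clf__weights"]
        _, g = grids["GBOOST"]
        assert 0.5 in g["learning_rate"] and 50 in g["n_estimators"]
        assert 5 in g["max_depth"] and 3 in g["gamma"]


class TestEvaluate:
    def _fit(self, table, fam="NB"):
        return rm.grid_search_cv(fam, table, folds=5, seed=0)

    def test_perfect_predictions(self):
        table = make_table(n_per_class=20, separation=10.0)
        model = self._fit(table)
        res = rm.evaluate(model, table)
        assert res.accuracy == 1.0 and res.f1 == 1.0
        assert res.fp == 0 and res.fn == 0

    def test_metric_identities_from_confusion_matrix(self):
        table = make_table(n_per_class=25, separation=1.5, seed=6)
        split = rm.stratified_subject_split(table, 20, seed=0)
        train = table.loc[list(split.train_ids)]
        test = table.loc[list(split.test_ids)]
        res = rm.evaluate(self._fit(train), test, split=split)
        n = res.tp + res.tn + res.fp + res.fn
        assert n == 20
        assert res.accuracy == pytest.approx((res.tp + res.tn) / n)
        denom = 2 * res.tp + res.fp + res.fn
        assert res.f1 == pytest.approx(2 * res.tp / denom)

    def test_all_positive_predictor_arithmetic(self):
        """An always-MDD predictor on a 20/20 set: accuracy 0.50, F1 2/3."""
        class AlwaysMDD:
            def predict(self, X):
                return np.ones(len(X), dtype=int)

        model = rm.TrainedModel("NB", {}, 0.5, AlwaysMDD(), ["f0"])
        table = make_table(n_per_class=20)
        res = rm.evaluate(model, table)
        assert res.accuracy == pytest.approx(0.5)
        assert res.f1 == pytest.approx(2 * 20 / (2 * 20 + 20))

    def test_evaluate_rejects_training_subjects(self):
        table = make_table(n_per_class=10)
        split = rm.stratified_subject_split(table, 8, seed=0)
        model = self._fit(table.loc[list(split.train_ids)])
        with pytest.raises(LeakageError):
            rm.evaluate(model, table, split=split)


class TestRunExperiment:
    def test_twelve_cells_and_determinism(self):
        table = make_table(n_per_class=20, n_features=40, separation=2.0,
                           seed=8)
        rep = rm.run_experiment(table, seed=0, k=10, test_size=10, folds=5,
                                grids=rm.compact_model_grids())
        assert len(rep.cells) == 12
        assert not rep.errors
        assert {(c.family, c.feature_set) for c in rep.cells} == {
            (f, s) for f in rm.MODEL_FAMILIES for s in ("full", "reduced")}
        for c in rep.cells:
            if c.feature_set == "reduced":
                assert c.n_features == 10
        rep2 = rm.run_experiment(table, seed=0, k=10, test_size=10, folds=5,
                                 grids=rm.compact_model_grids())
        assert rep.to_json() == rep2.to_json()

    def test_report_serialization_and_summary(self, tmp_path):
        table = make_table(n_per_class=15, n_features=20, separation=2.0)
        rep = rm.run_experiment(table, seed=1, k=5, test_size=10, folds=5,
                                grids=rm.compact_model_grids(),
                                families=("DT", "NB"))
        summary = rep.summary_table()
        assert list(summary.columns) == ["accuracy_all", "f1_all",
                                         "accuracy_selected", "f1_selected"]
        rep.to_json(tmp_path / "report.json")
        rep.plot_confusions(tmp_path / "cm.png")
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "cm.png").stat().st_size > 0
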