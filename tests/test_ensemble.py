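"""Two-step ensemble training, baselines and the subset experiment."""

import numpy as np
import pandas as pd
import pytest

from forestbind import ensemble
from forestbind.ensemble import (
    EnsembleBindingClassifier,
    TissueForestClassifier,
    averaging_baseline,
    build_ensemble_matrix,
    fit_ensemble,
    fit_forest,
    load_model,
    pooled_baseline,
    reduce_and_refit,
    save_model,
    stack_tissue_data,
    tissue_subset_experiment,
)
from forestbind.exceptions import DataError


def toy_data(n=300, p=6, seed=0, informative=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)])
    y = (X.iloc[:, informative] > 0).astype(int).to_numpy()
    return X, y


class TestTissueForest:
    def test_single_determining_feature_has_top_importance(self):
        X, y = toy_data(seed=1, informative=2)
        forest = fit_forest(X, y, n_trees=100, seed=0)
        assert forest.top_features(1) == ["f2"]

    def test_same_seed_gives_identical_oob_error(self):
        X, y = toy_data(seed=2)
        a = fit_forest(X, y, n_trees=80, seed=9)
        b = fit_forest(X, y, n_trees=80, seed=9)
        assert a.oob_error_ == b.oob_error_
        np.testing.assert_array_equal(a.oob_proba_, b.oob_proba_)

    def test_single_class_labels_raise(self):
        X, _ = toy_data()
        with pytest.raises(DataError, match="single class"):
            fit_forest(X, np.ones(len(X)), n_trees=10, seed=0)

    def test_oob_probabilities_within_unit_interval(self):
        X, y = toy_data(seed=3)
        forest = fit_forest(X, y, n_trees=60, seed=1)
        assert forest.oob_proba_.min() >= 0 and forest.oob_proba_.max() <= 1

    def test_top_features_tie_break_is_lexicographic(self):
        forest = TissueForestClassifier()
        forest.feature_names_ = ["d", "c", "a", "b"]
        forest.importances_ = pd.Series([3.0, 2.0, 2.0, 1.0],
                                        index=forest.feature_names_)
        assert forest.top_features(2) == ["d", "a"]

    def test_top_features_with_t_equal_to_all_returns_all(self):
        X, y = toy_data(seed=4, p=5)
        forest = fit_forest(X, y, n_trees=30, seed=2)
        assert sorted(forest.top_features(5)) == sorted(X.columns)

    @pytest.mark.parametrize("t", [0, -3, 99])
    def test_invalid_t_raises(self, t):
        X, y = toy_data(seed=5, p=4)
        forest = fit_forest(X, y, n_trees=20, seed=3)
        with pytest.raises(ValueError):
            forest.top_features(t)

    def test_predict_requires_training_columns(self):
        X, y = toy_data(seed=6)
        forest = fit_forest(X, y, n_trees=20, seed=4)
        with pytest.raises(DataError, match="missing feature"):
            forest.positive_proba(X.drop(columns=["f0"]))


class TestTwoStepConstruction:
    @pytest.fixture(scope="class")
    @staticmethod
    def two_tissue():
        X1, y1 = toy_data(n=240, seed=10, informative=0)
        X2, y2 = toy_data(n=180, seed=11, informative=1)
        return {"liver": (X1, y1), "kidney": (X2, y2)}

    def test_union_of_top_lists(self):
        f1 = TissueForestClassifier()
        f1.importances_ = pd.Series({"A": 3.0, "B": 2.0, "C": 0.1})
        f2 = TissueForestClassifier()
        f2.importances_ = pd.Series({"A": 0.5, "B": 4.0, "C": 3.0})
        union = ensemble.feature_union([f1, f2], {"t1": ["A", "B"], "t2": ["B", "C"]})
        assert set(union) == {"A", "B", "C"}
        assert union[0] == "B"  # largest max-importance first

    def test_reduce_and_refit_trains_on_union_columns(self, two_tissue):
        forests = {t: fit_forest(X, y, n_trees=50, seed=i)
                   for i, (t, (X, y)) in enumerate(two_tissue.items())}
        union, reduced = reduce_and_refit(two_tissue, forests, t=3, seed=5)
        assert 3 <= len(union) <= 6
        for rf in reduced.values():
            assert rf.feature_names_ == union

    def test_ensemble_matrix_shape_and_range(self, two_tissue):
        forests = {t: fit_forest(X, y, n_trees=50, seed=i)
                   for i, (t, (X, y)) in enumerate(two_tissue.items())}
        union, reduced = reduce_and_refit(two_tissue, forests, t=3, seed=5)
        sub = {t: (X[union], y) for t, (X, y) in two_tissue.items()}
        te, ye = build_ensemble_matrix(reduced, sub)
        assert te.shape == (240 + 180, 2)
        assert ye.shape == (420,)
        assert te.to_numpy().min() >= 0 and te.to_numpy().max() <= 1

    def test_ensemble_matrix_own_columns_are_in_sample_probabilities(self, two_tissue):
        forests = {t: fit_forest(X, y, n_trees=50, seed=i)
                   for i, (t, (X, y)) in enumerate(two_tissue.items())}
        union, reduced = reduce_and_refit(two_tissue, forests, t=3, seed=5)
        sub = {t: (X[union], y) for t, (X, y) in two_tissue.items()}
        te, _ = build_ensemble_matrix(reduced, sub)
        own = reduced["liver"].positive_proba(sub["liver"][0])
        np.testing.assert_allclose(te["pred_liver"].to_numpy()[:240], own)

    def test_fit_ensemble_refuses_single_column(self):
        te = pd.DataFrame({"pred_only": np.linspace(0, 1, 50)})
        y = (te["pred_only"] > 0.5).astype(int)
        with pytest.raises(DataError, match="reduced tissue forest"):
            fit_ensemble(te, y, n_trees=20, seed=0)

    def test_estimator_single_tissue_path_uses_reduced_forest(self):
        X, y = toy_data(n=200, seed=12)
        model = EnsembleBindingClassifier(n_estimators=40, t=3, random_state=0)
        model.fit(X, y)
        assert model.ensemble_forest_ is None
        assert len(model.reduced_forests_) == 1
        p = model.positive_proba(X)
        only = next(iter(model.reduced_forests_.values()))
        np.testing.assert_allclose(p, only.positive_proba(X[model.feature_union_]))

    def test_estimator_multi_tissue_end_to_end_determinism(self, two_tissue):
        X, y, tags = stack_tissue_data(two_tissue)
        runs = []
        for _ in range(2):
            m = EnsembleBindingClassifier(n_estimators=40, t=3, random_state=7)
            m.fit(X, y, tissues=tags)
            runs.append(m.positive_proba(X))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_prediction_constant_on_identical_all_zero_rows(self, two_tissue):
        X, y, tags = stack_tissue_data(two_tissue)
        m = EnsembleBindingClassifier(n_estimators=40, t=3, random_state=7)
        m.fit(X, y, tissues=tags)
        zeros = pd.DataFrame(0.0, index=range(5), columns=X.columns)
        p = m.positive_proba(zeros)
        assert len(np.unique(p)) == 1

    def test_predict_missing_union_columns_raises(self, two_tissue):
        X, y, tags = stack_tissue_data(two_tissue)
        m = EnsembleBindingClassifier(n_estimators=40, t=3, random_state=7)
        m.fit(X, y, tissues=tags)
        with pytest.raises(DataError, match="union"):
            m.positive_proba(X[[X.columns[0]]])

    def test_class_cap_reapplied_to_ensemble_rows(self):
        X1, y1 = toy_data(n=400, seed=13)
        X2, y2 = toy_data(n=400, seed=14)
        data = {"a": (X1, y1), "b": (X2, y2)}
        X, y, tags = stack_tissue_data(data)
        m = EnsembleBindingClassifier(n_estimators=30, t=3, cap=100, random_state=1)
        m.fit(X, y, tissues=tags)
        counts = np.bincount(m.oob_y_)
        assert counts.max() <= 100

    def test_sklearn_get_set_params_round_trip(self):
        m = EnsembleBindingClassifier(n_estimators=10, t=5)
        params = m.get_params()
        assert params["t"] == 5
        m.set_params(t=7)
        assert m.t == 7

    def test_model_bundle_round_trip(self, two_tissue, tmp_path):
        X, y, tags = stack_tissue_data(two_tissue)
        m = EnsembleBindingClassifier(n_estimators=30, t=3, random_state=2)
        m.fit(X, y, tissues=tags)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.positive_proba(X), m.positive_proba(X))


class TestBaselinesAndExperiments:
    def test_averaging_of_two_columns(self):
        class Stub:
            def __init__(self, value, names):
                self.value = value
                self.feature_names_ = names

            def positive_proba(self, X):
                return np.full(len(X), self.value)

        X = pd.DataFrame({"a": [0.0, 1.0]})
        out = averaging_baseline({"t1": Stub(0.2, ["a"]), "t2": Stub(0.8, ["a"])}, X)
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_averaging_single_model_is_identity(self):
        X, y = toy_data(n=150, seed=15)
        forest = fit_forest(X, y, n_trees=30, seed=0)
        out = averaging_baseline({"t": forest}, X)
        np.testing.assert_allclose(out, forest.positive_proba(X))

    def test_pooled_baseline_row_count(self):
        X1, y1 = toy_data(n=100, seed=16)
        X2, y2 = toy_data(n=140, seed=17)
        pooled = pooled_baseline({"a": (X1, y1), "b": (X2, y2)},
                                 t=3, n_trees=30, seed=0)
        assert len(pooled.oob_proba_) == 240

    def test_subset_experiment_enumerates_all_subsets(self):
        X1, y1 = toy_data(n=120, seed=18)
        X2, y2 = toy_data(n=120, seed=19)
        table = tissue_subset_experiment({"a": (X1, y1), "b": (X2, y2)},
                                         t=3, n_trees=30, seed=4)
        assert len(table) == 3  # 2^2 - 1
        assert sorted(table["size"]) == [1, 1, 2]

    def test_subset_experiment_deterministic_under_seed(self):
        X1, y1 = toy_data(n=120, seed=20)
        X2, y2 = toy_data(n=120, seed=21)
        data = {"a": (X1, y1), "b": (X2, y2)}
        t1 = tissue_subset_experiment(data, t=3, n_trees=30, seed=4)
        t2 = tissue_subset_experiment(data, t=3, n_trees=30, seed=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_subset_experiment_guards_combinatorial_explosion(self):
        data = {f"t{i}": toy_data(n=30, seed=i) for i in range(9)}
        with pytest.raises(DataError, match="allow_large"):
            tissue_subset_experiment(data, n_trees=5, seed=0)
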