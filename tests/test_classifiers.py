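"""The 11-classifier suite: bespoke algorithms, registry, probability contracts."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.tree import DecisionTreeClassifier

from conftest import small_dataset
from srdeval.classifiers import (
    CfsFilteredClassifier,
    DecorateClassifier,
    EnsembleSelectionClassifier,
    HyperPipesClassifier,
    MultiBoostABClassifier,
    OneRClassifier,
    REGISTRY_ABBREVIATIONS,
    cfs_merit,
    cfs_select,
    make_classifier,
    registry_specs,
)


class TestRegistry:
    def test_exactly_eleven_members(self):
        assert len(REGISTRY_ABBREVIATIONS) == 11
        assert len(registry_specs()) == 11

    def test_unknown_abbreviation_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("XGB")

    def test_probability_rows_sum_to_one(self):
        data = small_dataset(0, separation=1.0)
        for abbr in REGISTRY_ABBREVIATIONS:
            model = make_classifier(abbr, 3).fit(data.X_train, data.y_train)
            probs = model.predict_proba(data.X_test)
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9), abbr
            assert probs.min() >= 0

    def test_bagging_has_ten_members(self):
        data = small_dataset(1)
        bag = make_classifier("Bag", 0).fit(data.X_train, data.y_train)
        assert len(bag.estimators_) == 10

    def test_one_nn_memorizes_training_points(self):
        data = small_dataset(2)
        knn = make_classifier("lBk").fit(data.X_train, data.y_train)
        probs = knn.predict_proba(data.X_train[:10])
        assert np.allclose(probs[np.arange(10), data.y_train[:10] - 1], 1.0)

    def test_separable_data_learned_by_all(self):
        # strong per-feature separation: a single attribute separates, so the
        # one-rule learner is held to the same bar as the rest
        data = small_dataset(4, separation=6.0, counts=((100, 100), (200, 200)))
        for abbr in REGISTRY_ABBREVIATIONS:
            model = make_classifier(abbr, 5).fit(data.X_train, data.y_train)
            acc = (model.predict(data.X_test) == data.y_test).mean()
            assert acc >= 0.95, f"{abbr}: {acc}"

    def test_no_signal_gives_chance_bacc(self):
        # mean cross-validated balanced accuracy over 20 seeds stays near 0.5
        from srdeval.metrics import composite_local_metrics, confusion_matrix
        from srdeval.pipeline import run_scenario

        baccs = {abbr: [] for abbr in REGISTRY_ABBREVIATIONS}
        for seed in range(20):
            data = small_dataset(seed, separation=0.0,
                                 counts=((25, 25), (5, 5)), n_features=5)
            preds = run_scenario(data, cv_folds=5, seed=seed)
            for abbr in REGISTRY_ABBREVIATIONS:
                p = preds[(abbr, "CV")]
                cm = confusion_matrix(
                    p.true_labels, np.argmax(p.probabilities, axis=1) + 1, 2)
                baccs[abbr].append(composite_local_metrics(*cm.binary(2))["BACC"])
        for abbr, values in baccs.items():
            assert 0.4 <= np.mean(values) <= 0.6, f"{abbr}: {np.mean(values)}"


class TestHyperPipes:
    def test_disjoint_pipes(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, 1, 2, 2])
        model = HyperPipesClassifier().fit(X, y)
        assert model.predict([[0.5]])[0] == 1
        assert model.predict([[2.5]])[0] == 2

    def test_query_inside_both_pipes_is_uniform(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.1, 0.1], [0.9, 0.9]])
        y = np.array([1, 1, 2, 2])
        model = HyperPipesClassifier().fit(X, y)
        assert model.predict_proba([[0.5, 0.5]])[0] == pytest.approx([0.5, 0.5])

    def test_training_points_score_one_for_own_class(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(1, 4, size=30)
        model = HyperPipesClassifier().fit(X, y)
        inside = (X[:, None, :] >= model.bounds_min_) & (X[:, None, :] <= model.bounds_max_)
        own = inside.mean(axis=2)[np.arange(30), y - 1]
        assert np.all(own == 1.0)


class TestOneR:
    def test_perfect_attribute_selected_with_zero_error(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.r_[np.zeros(10), np.ones(10)], rng.normal(size=20)])
        y = np.r_[np.ones(10), np.full(10, 2)].astype(int)
        model = OneRClassifier().fit(X, y)
        assert model.feature_ == 0
        assert model.training_error_ == 0

    def test_lower_error_attribute_wins(self):
        rng = np.random.default_rng(1)
        good = np.r_[rng.normal(0, 1, 60), rng.normal(8, 1, 60)]
        poor = np.r_[rng.normal(0, 1, 60), rng.normal(0.5, 1, 60)]
        y = np.r_[np.ones(60), np.full(60, 2)].astype(int)
        model = OneRClassifier().fit(np.column_stack([poor, good]), y)
        assert model.feature_ == 1

    def test_constant_features_predict_majority(self):
        X = np.zeros((12, 2))
        y = np.r_[np.ones(8), np.full(4, 2)].astype(int)
        model = OneRClassifier().fit(X, y)
        assert np.all(model.predict(np.zeros((5, 2))) == 1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            OneRClassifier(bucket_size=6).fit(np.zeros((4, 1)), [1, 1, 2, 2])


class TestMultiBoost:
    def test_separable_1d_reaches_zero_training_error(self):
        X = np.linspace(0, 1, 40).reshape(-1, 1)
        y = (X.ravel() > 0.5).astype(int) + 1
        model = MultiBoostABClassifier(random_state=0).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_ensemble_size_capped_at_iterations(self):
        data = small_dataset(5, separation=0.5)
        model = MultiBoostABClassifier(random_state=1).fit(data.X_train, data.y_train)
        assert len(model.estimators_) <= 10

    def test_deterministic_given_seed(self):
        data = small_dataset(6)
        a = MultiBoostABClassifier(random_state=7).fit(data.X_train, data.y_train)
        b = MultiBoostABClassifier(random_state=7).fit(data.X_train, data.y_train)
        assert a.alphas_ == b.alphas_
        assert np.array_equal(a.predict_proba(data.X_test), b.predict_proba(data.X_test))


class TestDecorate:
    def test_training_error_not_above_single_tree(self):
        data = small_dataset(7, separation=0.8)
        model = DecorateClassifier(random_state=0).fit(data.X_train, data.y_train)
        tree = DecisionTreeClassifier(random_state=0).fit(data.X_train, data.y_train)
        tree_err = (tree.predict(data.X_train) != data.y_train).mean()
        assert model.training_error_ <= tree_err + 1e-12

    def test_single_iteration_behaves_as_one_tree(self):
        data = small_dataset(8)
        model = DecorateClassifier(n_iterations=1, random_state=0).fit(
            data.X_train, data.y_train)
        assert len(model.estimators_) == 1

    def test_separable_data_zero_error(self):
        data = small_dataset(9, separation=6.0)
        model = DecorateClassifier(random_state=0).fit(data.X_train, data.y_train)
        assert model.training_error_ == 0.0

    def test_degenerate_zero_sd_attribute_tolerated(self):
        X = np.column_stack([np.r_[np.zeros(20), np.ones(20)], np.full(40, 3.0)])
        y = np.r_[np.ones(20), np.full(20, 2)].astype(int)
        model = DecorateClassifier(random_state=0).fit(X, y)
        assert model.training_error_ == 0.0


class TestEnsembleSelection:
    def test_perfect_model_dominates_random_library(self):
        data = small_dataset(10, separation=6.0)
        library = [
            DecisionTreeClassifier(random_state=0),       # near-perfect here
            DecisionTreeClassifier(max_depth=1, random_state=0),
        ]
        model = EnsembleSelectionClassifier(
            library=library, random_state=0).fit(data.X_train, data.y_train)
        acc = (model.predict(data.X_test) == data.y_test).mean()
        assert acc >= 0.95

    def test_identical_library_matches_single_member(self):
        data = small_dataset(11)
        library = [clone(DecisionTreeClassifier(random_state=3)) for _ in range(4)]
        model = EnsembleSelectionClassifier(
            library=library, random_state=1).fit(data.X_train, data.y_train)
        single = DecisionTreeClassifier(random_state=3).fit(data.X_train, data.y_train)
        assert np.allclose(model.predict_proba(data.X_test),
                           single.predict_proba(data.X_test))

    def test_selection_rmse_not_above_best_single(self):
        data = small_dataset(12, separation=1.0)
        model = EnsembleSelectionClassifier(random_state=2).fit(
            data.X_train, data.y_train)
        assert np.isfinite(model.selection_rmse_)
        assert len(model.selected_indices_) >= 1

    def test_empty_library_rejected(self):
        data = small_dataset(13)
        with pytest.raises(ValueError):
            EnsembleSelectionClassifier(library=[]).fit(data.X_train, data.y_train)


class TestCfs:
    def test_single_feature_merit_is_class_correlation(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=50) > 0).astype(int) + 1
        rcf = np.array([abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(3)])
        assert cfs_merit(rcf, np.eye(3), [0]) == pytest.approx(rcf[0])

    def test_informative_feature_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            informative = np.r_[rng.normal(0, 1, 40), rng.normal(2.5, 1, 40)]
            X = np.column_stack([informative] + [rng.normal(size=80) for _ in range(8)])
            y = np.r_[np.ones(40), np.full(40, 2)].astype(int)
            if 0 in cfs_select(X, y):
                hits += 1
        assert hits >= 18  # frequency >= 0.9 over 20 seeds

    def test_duplicated_informative_feature_not_selected_twice(self):
        rng = np.random.default_rng(0)
        informative = np.r_[rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
        dup = informative + rng.normal(0, 0.01, 100)
        X = np.column_stack([informative, dup, rng.normal(size=(100, 4))])
        y = np.r_[np.ones(50), np.full(50, 2)].astype(int)
        selected = cfs_select(X, y)
        assert len({0, 1} & set(selected)) <= 1

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            cfs_select(np.zeros((20, 3)), np.r_[np.ones(10), np.full(10, 2)])

    def test_filtered_classifier_exposes_subset(self):
        data = small_dataset(14, separation=2.0)
        model = CfsFilteredClassifier(random_state=0).fit(data.X_train, data.y_train)
        assert len(model.selected_features_) >= 1
        probs = model.predict_proba(data.X_test)
        assert np.allclose(probs.sum(axis=1), 1.0)
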