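import numpy as np
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeClassifier

from mpminer.modeling import (
    SVMParams,
    balanced_accuracy,
    build_consensus,
    consensus_predict,
    expected_outliers,
    filter_outliers,
    fivefold_cv,
    grid_search,
    rmse,
    stratified_bagging_classify,
)


class TestMetrics:
    def test_rmse_identical_vectors(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_rmse_closed_form(self):
        assert rmse([3.0, 0.0], [0.0, 4.0]) == pytest.approx(
            np.sqrt(25.0 / 2.0))

    def test_rmse_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    def test_balanced_accuracy_of_all_majority_classifier(self):
        y = [0] * 95 + [1] * 5
        assert balanced_accuracy(y, [0] * 100) == 0.5

    def test_balanced_accuracy_is_mean_of_recalls(self):
        y = [0, 0, 0, 0, 1, 1]
        pred = [0, 0, 1, 1, 1, 0]  # recall0 = 1/2, recall1 = 1/2
        assert balanced_accuracy(y, pred) == 0.5


class TestFivefoldCV:
    def test_learnable_identity_has_near_zero_cv_rmse(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 10, size=(100, 1))
        y = 3.0 * X[:, 0] + 2.0
        res = fivefold_cv(X, y, model_factory=LinearRegression, seed=0)
        assert res.rmse < 1e-3 * np.std(y)

    def test_every_row_predicted_once_with_balanced_folds(self):
        rng = np.random.default_rng(1)
        X = rng.random((53, 3))
        y = rng.random(53)
        res = fivefold_cv(X, y, model_factory=LinearRegression, seed=0)
        counts = np.bincount(res.fold_assignment, minlength=5)
        assert counts.min() >= 53 // 5 and counts.max() <= 53 // 5 + 1
        assert res.oof_predictions.shape == (53,)

    def test_pure_noise_cv_rmse_near_unit_sigma(self):
        rng = np.random.default_rng(2)
        n = 2000
        X = rng.random((n, 5))  # uninformative descriptors
        y = rng.normal(0.0, 1.0, size=n)
        res = fivefold_cv(X, y, model_factory=LinearRegression, seed=0)
        assert 0.9 <= res.rmse <= 1.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X, y = rng.random((60, 2)), rng.random(60)
        a = fivefold_cv(X, y, params=SVMParams(1.0, 0.5, 0.01), seed=9)
        b = fivefold_cv(X, y, params=SVMParams(1.0, 0.5, 0.01), seed=9)
        assert a.rmse == b.rmse
        assert (a.fold_assignment == b.fold_assignment).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fivefold_cv(np.zeros((8, 1)), np.zeros(8),
                        model_factory=LinearRegression)


class TestGridSearch:
    def _data(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, size=(120, 2))
        y = 10.0 * X[:, 0] + rng.normal(0, 0.1, 120)
        return X, y

    def test_single_element_grid(self):
        X, y = self._data()
        only = SVMParams(1.0, 1.0, 0.1)
        assert grid_search(X, y, [only]) == only

    def test_suitable_triple_beats_degenerate_one(self):
        X, y = self._data()
        good = SVMParams(C=100.0, gamma=0.5, epsilon=0.1)
        bad = SVMParams(C=0.001, gamma=1000.0, epsilon=50.0)
        assert grid_search(X, y, [bad, good], seed=0) == good

    def test_full_fraction_equals_plain_cv_selection(self):
        X, y = self._data()
        grid = [SVMParams(1.0, 0.5, 0.1), SVMParams(10.0, 0.5, 0.1),
                SVMParams(100.0, 2.0, 0.1)]
        manual = min(
            ((fivefold_cv(X, y, params=p, seed=0).rmse, p.C, p.gamma,
              p.epsilon, p) for p in grid),
            key=lambda t: t[:4])[4]
        assert grid_search(X, y, grid, fraction=1.0, seed=0) == manual

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((20, 1)), np.zeros(20), [])


class TestConsensus:
    def test_simple_average_and_distance(self):
        pred, dist = consensus_predict([150.0, 160.0, 170.0], "simple")
        assert pred[0] == pytest.approx(160.0)
        assert dist[0] == pytest.approx(np.std([150, 160, 170], ddof=1))

    def test_weighted_equals_simple_for_equal_rmses(self):
        preds = np.array([[150.0, 200.0], [160.0, 210.0], [170.0, 220.0]])
        simple, _ = consensus_predict(preds, "simple")
        weighted, _ = consensus_predict(preds, "weighted",
                                        member_rmses=[35.0, 35.0, 35.0])
        np.testing.assert_allclose(weighted, simple)

    def test_printed_normalization_breaks_that_reduction(self):
        preds = np.array([[150.0], [160.0], [170.0]])
        alt, _ = consensus_predict(preds, "weighted",
                                   member_rmses=[35.0, 35.0, 35.0],
                                   printed_normalization=True)
        assert alt[0] != pytest.approx(160.0)

    def test_single_member_passthrough_with_zero_distance(self):
        pred, dist = consensus_predict([123.0], "simple")
        assert pred[0] == 123.0 and dist[0] == 0.0

    def test_prediction_bounded_by_members(self):
        rng = np.random.default_rng(5)
        preds = rng.uniform(100, 200, size=(4, 50))
        simple, _ = consensus_predict(preds, "simple")
        assert (simple >= preds.min(axis=0)).all()
        assert (simple <= preds.max(axis=0)).all()

    def test_mlra_requires_coefficients(self):
        with pytest.raises(ValueError):
            consensus_predict([[1.0], [2.0]], "mlra")

    def test_mlra_stack_fits_member_blend(self):
        rng = np.random.default_rng(6)
        n = 200
        X = rng.random((n, 3))
        y = 5.0 * X[:, 0] + rng.normal(0, 0.05, n)
        members = [fivefold_cv(X[:, [j]], y, model_factory=LinearRegression,
                               seed=0) for j in range(3)]
        model = build_consensus(members, y=y, strategy="mlra")
        pred, _ = consensus_predict(
            [m.oof_predictions for m in members], "mlra",
            stack_coefficients=model.stack_coefficients,
            stack_intercept=model.stack_intercept)
        assert rmse(y, pred) <= min(m.rmse for m in members) + 1e-9


class TestOutlierFiltering:
    def test_expected_count_is_exact(self):
        assert expected_outliers(229_000, 1e-4) == pytest.approx(22.9)

    def test_two_sigma_tail_mass(self):
        rng = np.random.default_rng(7)
        r = rng.normal(0, 10.0, 1000)
        rep = filter_outliers(r, sigma=10.0, p=0.0455)
        assert rep.z_threshold == pytest.approx(2.0, abs=0.005)

    def test_null_snr_is_one_within_monte_carlo_error(self):
        rng = np.random.default_rng(8)
        n, p = 100_000, 0.01
        r = rng.normal(0.0, 40.0, n)
        rep = filter_outliers(r, sigma=40.0, p=p)
        assert abs(rep.snr - 1.0) < 3.0 / np.sqrt(n * p)
        assert rep.expected_count == n * p

    def test_outlier_rows_are_the_large_residuals(self):
        r = np.array([0.0, 1.0, -50.0, 2.0, 60.0])
        rep = filter_outliers(r, sigma=5.0, p=0.01)
        assert set(rep.outlier_rows) == {2, 4}
        assert rep.observed_count == 2

    def test_invalid_sigma_and_p_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers([1.0], sigma=0.0, p=0.01)
        with pytest.raises(ValueError):
            filter_outliers([1.0], sigma=1.0, p=0.7)


class TestStratifiedBagging:
    @staticmethod
    def _tree():
        return [DecisionTreeClassifier(max_depth=4, random_state=0)]

    def test_bag_composition_double_minority_equal_classes(self):
        rng = np.random.default_rng(9)
        X = rng.random((110, 2))
        y = np.array(["decompose"] * 10 + ["melt"] * 100)
        res = stratified_bagging_classify(X, y, n_models=16,
                                          base_learners=self._tree(), seed=0)
        min_idx = set(range(10))
        for bag in res.bag_indices:
            assert bag.size == 20
            labels = y[bag]
            assert (labels == "decompose").sum() == 10
            assert (labels == "melt").sum() == 10
            maj = [i for i in bag if i not in min_idx]
            assert len(set(maj)) == len(maj)  # majority drawn w/o replacement

    def test_separable_classes_recovered(self):
        rng = np.random.default_rng(10)
        n_min, n_maj = 50, 950
        X = np.vstack([rng.normal(5.0, 0.3, size=(n_min, 2)),
                       rng.normal(0.0, 0.3, size=(n_maj, 2))])
        y = np.array([1] * n_min + [0] * n_maj)
        res = stratified_bagging_classify(X, y, n_models=32,
                                          base_learners=self._tree(), seed=1)
        assert res.balanced_accuracy >= 0.95

    def test_shuffled_labels_give_chance_level(self):
        rng = np.random.default_rng(11)
        n = 2000
        X = rng.random((n, 4))
        y = np.array([1] * 110 + [0] * (n - 110))
        rng.shuffle(y)
        res = stratified_bagging_classify(X, y, n_models=32,
                                          base_learners=self._tree(), seed=2)
        assert abs(res.balanced_accuracy - 0.5) <= 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_bagging_classify(np.zeros((10, 1)), np.zeros(10))
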