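"""Classification: splits, SVM, ANFIS and the diagnostic metric suite."""

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from ecgcreativity.anfis import (
    ANFISModel,
    anfis_predict,
    anfis_train,
    firing_strengths,
    subtractive_clustering,
)
from ecgcreativity.classify import (
    SplitSpec,
    evaluate,
    format_lr,
    repeated_evaluation,
    split_train_test,
    svm_rbf,
)


def blobs(rng, n_per_class, sep, d=2):
    X = np.vstack([
        rng.standard_normal((n_per_class, d)),
        rng.standard_normal((n_per_class, d)) + sep,
    ])
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestSplit:
    def test_stratified_arithmetic(self):
        rng = np.random.default_rng(0)
        X, y = blobs(rng, 50, 0.0)
        split = split_train_test(X, y, SplitSpec(seed=1), 0)
        assert len(split.y_train) == 70 and len(split.y_test) == 30
        assert np.sum(split.y_train == 0) == 35 and np.sum(split.y_test == 0) == 15

    def test_deterministic_per_run_index(self):
        rng = np.random.default_rng(0)
        X, y = blobs(rng, 20, 0.0)
        a = split_train_test(X, y, SplitSpec(seed=3), 5)
        b = split_train_test(X, y, SplitSpec(seed=3), 5)
        assert np.array_equal(a.X_train, b.X_train)
        c = split_train_test(X, y, SplitSpec(seed=3), 6)
        assert not np.array_equal(a.X_train, c.X_train)

    @pytest.mark.parametrize("n", [10, 57, 400])
    def test_disjoint_and_exhaustive(self, n):
        rng = np.random.default_rng(n)
        X = rng.standard_normal((n, 3))
        y = (rng.random(n) < 0.5).astype(int)
        if min(np.sum(y == 0), np.sum(y == 1)) < 4:
            y[: 4] = 0
            y[4: 8] = 1
        split = split_train_test(X, y, SplitSpec(seed=n), 0)
        combined = np.vstack([split.X_train, split.X_test])
        assert combined.shape == X.shape
        assert set(map(tuple, combined)) == set(map(tuple, X))

    def test_single_row_class_errors(self):
        X = np.zeros((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(X, y, SplitSpec(), 0)


class TestSVM:
    def test_separable_blobs_are_perfect(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng, 60, 6.0)
        split = split_train_test(X, y, SplitSpec(seed=2), 0)
        preds = svm_rbf(split)
        assert np.mean(preds == split.y_test) == 1.0

    def test_permutation_null_near_chance(self):
        rng = np.random.default_rng(2)
        X, y = blobs(rng, 60, 6.0)
        y_perm = rng.permutation(y)
        rep = repeated_evaluation(X, y_perm, SplitSpec(n_runs=20, seed=4))
        assert 40.0 <= rep.accuracy <= 60.0

    def test_known_bayes_error(self):
        # 1-D Gaussians, centers +-Phi^-1(0.9): Bayes accuracy 90%
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        mu = norm.ppf(0.9)
        X = np.concatenate([
            rng.normal(-mu, 1.0, 1500), rng.normal(mu, 1.0, 1500)])[:, None]
        y = np.repeat([0, 1], 1500)
        rep = repeated_evaluation(X, y, SplitSpec(n_runs=10, seed=5))
        assert rep.accuracy == pytest.approx(90.0, abs=5.0)

    def test_non_finite_feature_named(self):
        X = np.zeros((20, 2))
        X[3, 1] = np.nan
        y = np.repeat([0, 1], 10)
        split = split_train_test(X, y, SplitSpec(seed=0), 0)
        split.X_train[0, 1] = np.nan
        with pytest.raises(ValueError, match="col_b"):
            svm_rbf(split, feature_names=["col_a", "col_b"])

    def test_no_test_set_leakage_into_scaler(self):
        rng = np.random.default_rng(4)
        X, y = blobs(rng, 40, 3.0)
        split = split_train_test(X, y, SplitSpec(seed=6), 0)
        preds = svm_rbf(split)
        mutated = type(split)(split.X_train, split.y_train,
                              split.X_test.copy(), split.y_test)
        mutated.X_test[1:] += 100.0  # corrupt every test row but the first
        assert svm_rbf(mutated)[0] == preds[0]


class TestMetrics:
    @staticmethod
    def _confusion_arrays(sens_pct, spec_pct, n=10000):
        tp = round(n * sens_pct / 100)
        tn = round(n * spec_pct / 100)
        truth = np.repeat([1, 0], n)
        preds = np.concatenate([
            np.repeat([1, 0], [tp, n - tp]), np.repeat([0, 1], [tn, n - tn])])
        return preds, truth

    def test_printed_sensitivity_specificity_pair(self):
        preds, truth = self._confusion_arrays(97.91, 97.23)
        rep = evaluate(preds, truth, positive_label=1)
        assert rep.sensitivity == pytest.approx(97.91)
        assert rep.specificity == pytest.approx(97.23)
        assert round(rep.lr_pos, 2) == 35.35
        assert round(rep.lr_neg, 2) == 0.02

    def test_perfect_predictions(self):
        truth = np.repeat([0, 1], 10)
        rep = evaluate(truth.copy(), truth, positive_label=1)
        assert rep.accuracy == 100.0 and rep.error_rate == 0.0
        assert rep.lr_neg == 0.0
        assert np.isinf(rep.lr_pos)
        assert format_lr(rep.lr_pos) == ">100"

    def test_degenerate_all_positive_predictor(self):
        truth = np.repeat([0, 1], 25)
        rep = evaluate(np.ones(50), truth, positive_label=1)
        assert rep.sensitivity == 100.0 and rep.specificity == 0.0

    def test_metric_identities_on_random_confusions(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            sens = rng.uniform(1, 99)
            spec = rng.uniform(1, 99)
            preds, truth = self._confusion_arrays(sens, spec, n=500)
            rep = evaluate(preds, truth, positive_label=1)
            assert rep.error_rate == pytest.approx(100 - rep.accuracy, abs=1e-12)
            assert rep.lr_pos * (100 - rep.specificity) == pytest.approx(
                rep.sensitivity, abs=1e-9)
            assert rep.lr_neg * rep.specificity == pytest.approx(
                100 - rep.sensitivity, abs=1e-9)

    def test_missing_class_errors(self):
        with pytest.raises(ValueError, match="class"):
            evaluate(np.ones(5), np.ones(5), positive_label=1)

    def test_repeated_mean_within_run_bounds(self):
        rng = np.random.default_rng(6)
        X, y = blobs(rng, 40, 1.5)
        rep = repeated_evaluation(X, y, SplitSpec(n_runs=10, seed=7))
        accs = rep.per_run["accuracy"]
        assert accs.min() <= rep.accuracy <= accs.max()

    def test_repeated_evaluation_reproducible(self):
        rng = np.random.default_rng(7)
        X, y = blobs(rng, 30, 2.0)
        a = repeated_evaluation(X, y, SplitSpec(n_runs=5, seed=8))
        b = repeated_evaluation(X, y, SplitSpec(n_runs=5, seed=8))
        assert a.to_dict() == b.to_dict()


class TestANFIS:
    def test_subtractive_clustering_centers_are_data_points(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(4, 0.3, (40, 2))])
        centers = subtractive_clustering(X, radius=0.5)
        assert centers.shape[0] >= 2
        for c in centers:
            assert np.min(np.linalg.norm(X - c, axis=1)) == 0.0

    def test_empty_data_errors(self):
        with pytest.raises(ValueError):
            subtractive_clustering(np.empty((0, 2)))

    def test_sinc_approximation(self):
        x = np.linspace(-10, 10, 121)[:, None]
        y = np.sinc(x.ravel() / np.pi)  # sin(x)/x
        model = anfis_train(x, y, n_epochs=300, cluster_radius=0.5, n_rules=6)
        assert model.error_trace[-1] < 0.05

    def test_training_error_mostly_nonincreasing(self):
        x = np.linspace(-10, 10, 121)[:, None]
        y = np.sinc(x.ravel() / np.pi)
        model = anfis_train(x, y, n_epochs=100, cluster_radius=0.5, n_rules=6)
        diffs = np.diff(model.error_trace)
        assert np.mean(diffs <= 1e-12) >= 0.90

    def test_zero_epochs_is_single_lse_pass(self):
        from ecgcreativity.anfis import _lse_consequents

        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 2))
        y = X[:, 0] - 0.5 * X[:, 1]
        model = anfis_train(X, y, n_epochs=0, cluster_radius=0.6)
        assert model.epochs_trained == 0
        ref = ANFISModel(centers=model.centers, sigmas=model.sigmas,
                         coeffs=np.zeros_like(model.coeffs))
        np.testing.assert_allclose(model.coeffs, _lse_consequents(ref, X, y))

    def test_firing_strengths_normalized(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        model = anfis_train(X, y, n_epochs=2, cluster_radius=0.8)
        _, wn = firing_strengths(model, X)
        np.testing.assert_allclose(wn.sum(axis=1), 1.0, atol=1e-12)

    def test_single_rule_constant_consequent(self):
        model = ANFISModel(centers=np.zeros((1, 2)), sigmas=np.ones((1, 2)),
                           coeffs=np.array([[0.0, 0.0, 1.0]]))
        out = anfis_predict(model, np.array([[5.0, -3.0], [0.0, 0.0]]))
        np.testing.assert_allclose(out, 1.0)

    def test_symmetric_two_rule_midpoint(self):
        model = ANFISModel(
            centers=np.array([[-1.0], [1.0]]),
            sigmas=np.ones((2, 1)),
            coeffs=np.array([[0.0, 2.0], [0.0, 6.0]]),
        )
        out = anfis_predict(model, np.array([[0.0]]))
        assert out[0] == pytest.approx(4.0, abs=1e-12)

    def test_predict_matches_rule_equation_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        model = anfis_train(X, y, n_epochs=3, cluster_radius=0.7)
        preds = anfis_predict(model, X)
        for i, xi in enumerate(X):
            w = []
            for r in range(model.n_rules):
                mu = 1.0
                for j in range(2):
                    mu *= np.exp(-((xi[j] - model.centers[r, j]) ** 2)
                                 / (2 * model.sigmas[r, j] ** 2))
                w.append(mu)
            w = np.asarray(w) / np.sum(w)
            expected = sum(
                w[r] * (model.coeffs[r, :2] @ xi + model.coeffs[r, 2])
                for r in range(model.n_rules))
            assert preds[i] == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_errors(self):
        model = ANFISModel(centers=np.zeros((1, 2)), sigmas=np.ones((1, 2)),
                           coeffs=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="features"):
            anfis_predict(model, np.zeros((4, 3)))
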