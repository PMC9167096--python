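"""SVM: activation utilities, kernels, SMO dual solver, grid search."""

import math

import numpy as np
import pytest

from nevuscope import (KernelSpec, decision_value, grid_search, kernel_eval,
                       kernel_matrix, predict, sigmoid_activation,
                       sigmoid_derivative, train_svm)
from nevuscope.svm import load_model, save_model, stratified_folds

from oracles import qp_decision_values, solve_dual_qp


class TestSigmoid:
    def test_known_values(self):
        assert sigmoid_activation(0.0) == pytest.approx(0.5)
        assert sigmoid_activation(math.log(3)) == pytest.approx(0.75)

    def test_symmetry(self, rng):
        x = rng.normal(0, 5, size=50)
        assert sigmoid_activation(x) + sigmoid_activation(-x) == pytest.approx(np.ones(50))

    def test_saturation_stable(self):
        assert sigmoid_activation(1000.0) == pytest.approx(1.0)
        assert sigmoid_activation(-1000.0) == pytest.approx(0.0)

    def test_derivative_value_and_bound(self, rng):
        assert sigmoid_derivative(0.0) == pytest.approx(0.25)
        x = rng.normal(0, 5, size=100)
        assert np.all(sigmoid_derivative(x) <= 0.25 + 1e-12)

    def test_derivative_matches_finite_difference(self):
        grid = np.linspace(-4, 4, 41)
        h = 1e-5
        fd = (sigmoid_activation(grid + h) - sigmoid_activation(grid - h)) / (2 * h)
        assert np.allclose(sigmoid_derivative(grid), fd, atol=1e-6)


class TestKernels:
    def test_linear_dot_product(self):
        assert kernel_eval(KernelSpec("linear"), (1, 2), (3, 4)) == pytest.approx(11.0)

    def test_rbf_self_similarity_and_closed_form(self):
        spec = KernelSpec("rbf", delta=1.0)
        assert kernel_eval(spec, (0.3, -1.2), (0.3, -1.2)) == pytest.approx(1.0)
        assert kernel_eval(spec, (1, 0), (0, 0)) == pytest.approx(math.exp(-1))

    def test_delta_gamma_relation(self):
        spec = KernelSpec("rbf", delta=2.0)
        assert spec.gamma == pytest.approx(0.25)
        spec2 = KernelSpec("rbf", gamma=4.0)
        assert spec2.delta == pytest.approx(0.5)

    def test_polynomial_and_sigmoid_forms(self):
        x, y = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        poly = KernelSpec("polynomial", gamma=0.5, degree=2, coef0=1.0)
        assert kernel_eval(poly, x, y) == pytest.approx((0.5 * 11 + 1) ** 2)
        sig = KernelSpec("sigmoid", gamma=0.1, coef0=-0.5)
        assert kernel_eval(sig, x, y) == pytest.approx(math.tanh(0.1 * 11 - 0.5))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec("linear"), (1, 2), (1, 2, 3))

    def test_rbf_gram_positive_semidefinite(self, rng):
        X = rng.normal(size=(30, 4))
        K = kernel_matrix(KernelSpec("rbf", gamma=0.7), X, X)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


WORKED_X = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.0]])
WORKED_Y = np.array([-1.0, -1.0, 1.0, 1.0])


class TestTrainSVM:
    def _worked_model(self):
        return train_svm(WORKED_X, WORKED_Y, penalty=1e6, kernel=KernelSpec("linear"),
                         tol=1e-8, standardize=False)

    def test_worked_example_hyperplane(self):
        """Max-margin separator of the two 2-point columns is x1 = 2."""
        model = self._worked_model()
        assert decision_value(model, np.array([2.0, 0.5])) == pytest.approx(0.0, abs=1e-6)
        assert np.all(predict(model, WORKED_X) == WORKED_Y)
        # margin points sit at decision value +/-1
        for xi, yi in zip(WORKED_X, WORKED_Y):
            assert decision_value(model, xi) == pytest.approx(yi, abs=1e-4)

    def test_kkt_invariants(self, rng):
        for trial in range(20):
            n = int(rng.integers(6, 16))
            x = rng.normal(size=(n, 3))
            y = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            if len(np.unique(y)) < 2:
                continue
            P = float(rng.choice([0.5, 1.0, 10.0]))
            spec = KernelSpec("rbf", gamma=0.5) if trial % 2 else KernelSpec("linear")
            model = train_svm(x, y, penalty=P, kernel=spec, tol=1e-6)
            model.check_kkt(tol=1e-6)
            # non-bound support vectors sit on the margin: |G(x_i)| = 1
            free = (model.multipliers > 1e-8) & (model.multipliers < P - 1e-8)
            if free.any():
                raw = model.support_vectors * model.scale_ + model.mean_
                g = np.atleast_1d(decision_value(model, raw[free]))
                assert np.allclose(np.abs(g), 1.0, atol=1e-4)

    def test_matches_qp_oracle_on_small_instances(self, rng):
        worst = 0.0
        for trial in range(60):
            n = int(rng.integers(4, 9))
            x = rng.normal(size=(n, 2))
            y = np.ones(n)
            y[: n // 2] = -1.0
            rng.shuffle(y)
            spec = KernelSpec("rbf", gamma=0.5) if trial % 2 else KernelSpec("linear")
            C = [1.0, 10.0][trial % 2]
            model = train_svm(x, y, penalty=C, kernel=spec, tol=1e-8,
                              max_iter=100_000, standardize=False)
            a, b = solve_dual_qp(x, y, C, spec)
            xt = rng.normal(size=(5, 2))
            g_oracle = qp_decision_values(x, y, a, b, spec, xt)
            g_model = decision_value(model, xt)
            worst = max(worst, float(np.max(np.abs(g_oracle - g_model))))
        assert worst <= 1e-4

    def test_duplicated_dataset_same_decision_function(self, rng):
        model1 = self._worked_model()
        x2 = np.vstack([WORKED_X, WORKED_X])
        y2 = np.concatenate([WORKED_Y, WORKED_Y])
        model2 = train_svm(x2, y2, penalty=1e6, kernel=KernelSpec("linear"),
                           tol=1e-8, standardize=False)
        xt = rng.normal(2.0, 2.0, size=(20, 2))
        assert np.allclose(decision_value(model1, xt), decision_value(model2, xt),
                           atol=1e-4)

    def test_row_order_invariance(self, rng):
        x = rng.normal(size=(12, 3))
        y = np.where(x[:, 0] > 0, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        m1 = train_svm(x, y, penalty=1.0, kernel=KernelSpec("rbf", gamma=1.0), tol=1e-8)
        perm = rng.permutation(12)
        m2 = train_svm(x[perm], y[perm], penalty=1.0,
                       kernel=KernelSpec("rbf", gamma=1.0), tol=1e-8)
        xt = rng.normal(size=(10, 3))
        assert np.allclose(decision_value(m1, xt), decision_value(m2, xt), atol=1e-4)

    def test_zero_tie_break_predicts_positive(self):
        model = self._worked_model()
        assert predict(model, np.array([2.0, 0.5])) == 1

    def test_invalid_training_sets(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((3, 2)), np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            train_svm(np.zeros((2, 2)), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            train_svm(np.array([[np.nan, 0], [1, 1]]), np.array([1.0, -1.0]))

    def test_dimension_mismatch_at_prediction(self):
        model = self._worked_model()
        with pytest.raises(ValueError):
            decision_value(model, np.array([1.0, 2.0, 3.0]))


class TestAgainstLibsvm:
    def test_decision_agrees_with_sklearn(self, rng):
        """Independent cross-check against the libsvm solver."""
        sklearn_svm = pytest.importorskip("sklearn.svm")
        x = rng.normal(size=(40, 3))
        y = np.where(x[:, 0] + 0.5 * x[:, 1] > 0, 1.0, -1.0)
        for spec, skw in [
            (KernelSpec("linear"), dict(kernel="linear")),
            (KernelSpec("rbf", gamma=0.5), dict(kernel="rbf", gamma=0.5)),
        ]:
            ours = train_svm(x, y, penalty=1.0, kernel=spec, tol=1e-8,
                             standardize=False)
            ref = sklearn_svm.SVC(C=1.0, tol=1e-8, **skw).fit(x, y)
            xt = rng.normal(size=(15, 3))
            assert np.allclose(decision_value(ours, xt),
                               ref.decision_function(xt), atol=1e-3)


class TestGridSearch:
    def _separable(self, rng, n=30):
        x = rng.normal(size=(n, 2))
        y = np.where(x[:, 0] > 0, 1.0, -1.0)
        x[:, 0] += 2.0 * y  # gap along the first axis
        return x, y

    def test_single_grid_point_returned(self, rng):
        x, y = self._separable(rng)
        spec, P, table = grid_search(x, y, kernel_kinds=["linear"], P_grid=[2.0],
                                     gamma_grid=[0.1], folds=3, seed=0)
        assert spec.kind == "linear" and P == 2.0
        assert len(table) == 1

    def test_linear_wins_on_separable_data(self):
        best_counts = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, y = self._separable(rng, n=40)
            spec, P, table = grid_search(
                x, y, kernel_kinds=["linear", "polynomial", "sigmoid", "rbf"],
                P_grid=[1.0], gamma_grid=[0.5], folds=4, seed=seed)
            lin = table[table.kernel == "linear"].cv_accuracy.max()
            others = table[table.kernel != "linear"].cv_accuracy.max()
            if lin >= others - 0.02:
                best_counts += 1
        assert best_counts >= 8

    def test_accuracy_bookkeeping(self, rng):
        x, y = self._separable(rng)
        _, _, table = grid_search(x, y, kernel_kinds=["linear"], P_grid=[1.0, 10.0],
                                  gamma_grid=[0.1], folds=3, seed=1)
        assert (table.n == len(y)).all()
        assert table.cv_accuracy.between(0, 1).all()

    def test_class_smaller_than_folds_rejected(self):
        y = np.array([1.0, 1.0, 1.0, -1.0])
        x = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError, match="fold"):
            grid_search(x, y, kernel_kinds=["linear"], P_grid=[1.0],
                        gamma_grid=[0.1], folds=3, seed=0)

    def test_stratified_folds_cover_and_balance(self, rng):
        y = np.array([1] * 9 + [-1] * 6)
        folds = stratified_folds(y, 3, seed=0)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(15))
        for f in folds:
            assert (y[f] == 1).sum() == 3 and (y[f] == -1).sum() == 2


def test_model_serialization_roundtrip(tmp_path, rng):
    x = rng.normal(size=(20, 3))
    y = np.where(x[:, 0] > 0, 1.0, -1.0)
    model = train_svm(x, y, penalty=2.0, kernel=KernelSpec("rbf", gamma=0.3))
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    xt = rng.normal(size=(10, 3))
    assert np.allclose(decision_value(model, xt), decision_value(loaded, xt))
    assert loaded.kernel.kind == "rbf" and loaded.kernel.gamma == pytest.approx(0.3)
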