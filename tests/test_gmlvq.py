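"""GMLVQ primitives: metric, margin, cost, gradients, training, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mciprog import (
    GmlvqClassifier,
    GmlvqHyper,
    cost_gradients,
    glvq_cost,
    metric_distance,
    numerical_cost_gradient,
    relative_margin,
    relevance_matrix,
    train_gmlvq,
)
from mciprog.exceptions import ClassBalanceError, DegeneracyError


def toy_labels(n):
    return np.array(["sMCI", "pMCI"] * (n // 2) + ["sMCI"] * (n % 2))


def toy_model(X, y, **kw):
    kw.setdefault("epochs", 5)
    return train_gmlvq(X, y, GmlvqHyper(**kw))


class TestRelevanceMatrix:
    def test_identity_normalizes_to_uniform_diagonal(self):
        lam = relevance_matrix(np.eye(3))
        np.testing.assert_allclose(lam, np.eye(3) / 3)

    def test_zero_matrix_is_degenerate(self):
        with pytest.raises(DegeneracyError):
            relevance_matrix(np.zeros((3, 3)))

    def test_matches_longhand_product(self, rng):
        omega = rng.normal(size=(3, 3))
        # longhand Omega^T Omega via explicit triple loop
        gram = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    gram[i, j] += omega[k, i] * omega[k, j]
        expected = gram / (gram[0, 0] + gram[1, 1] + gram[2, 2])
        np.testing.assert_allclose(relevance_matrix(omega), expected, atol=1e-12)

    def test_unit_trace_and_psd(self, rng):
        for _ in range(5):
            lam = relevance_matrix(rng.normal(size=(4, 4)))
            assert abs(np.trace(lam) - 1.0) < 1e-12
            assert np.linalg.eigvalsh(lam).min() >= -1e-10


class TestMetricDistance:
    def test_zero_displacement(self, rng):
        w = rng.normal(size=3)
        assert metric_distance(w, w, np.eye(3) / 3) == 0.0

    def test_uniform_diagonal_arithmetic(self):
        assert metric_distance(np.array([3.0, 0, 0]), np.zeros(3), np.eye(3) / 3) == pytest.approx(3.0)

    def test_matches_double_loop(self, rng):
        x, w = rng.normal(size=3), rng.normal(size=3)
        lam = relevance_matrix(rng.normal(size=(3, 3)))
        expected = sum(
            (x[i] - w[i]) * lam[i, j] * (x[j] - w[j]) for i in range(3) for j in range(3)
        )
        assert metric_distance(x, w, lam) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            metric_distance(np.zeros(3), np.zeros(2), np.eye(3))


class TestRelativeMargin:
    @pytest.mark.parametrize(
        "dj,dk,expected", [(2.0, 2.0, 0.0), (0.0, 4.0, -1.0), (3.0, 1.0, 0.5)]
    )
    def test_known_values(self, dj, dk, expected):
        assert relative_margin(dj, dk) == pytest.approx(expected)

    def test_both_zero_degenerate(self):
        with pytest.raises(DegeneracyError):
            relative_margin(0.0, 0.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_signed(self, dj, dk):
        if dj + dk <= 0:
            return
        mu = relative_margin(dj, dk)
        assert -1.0 <= mu <= 1.0
        assert (mu < 0) == (dj < dk)


class TestCostAndGradients:
    def test_equidistant_samples_cost_zero(self, rng):
        X = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 2.0], [0.0, -2.0]])
        y = toy_labels(4)
        m = toy_model(X, y, epochs=1, alpha_w=1e-9, alpha_omega=0.0)
        # prototypes are class means: both at x=0 axis offsets symmetric in y
        m.prototypes_ = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert glvq_cost(m, X, y) == pytest.approx(0.0, abs=1e-12)

    def test_sample_on_own_prototype_scores_minus_one(self):
        X = np.array([[0.0, 0.0], [3.0, 0.0], [0.1, 0.0], [2.9, 0.0]])
        y = np.array(["sMCI", "pMCI", "sMCI", "pMCI"])
        m = toy_model(X, y, epochs=1, alpha_w=1e-9, alpha_omega=0.0)
        m.prototypes_ = np.array([[0.0, 0.0], [3.0, 0.0]])
        cost = glvq_cost(m, X[:2], y[:2])
        assert cost == pytest.approx(-2.0, abs=1e-12)  # each sample at mu = -1

    def test_four_sample_longhand_sum(self, rng):
        X = rng.normal(size=(4, 3))
        y = toy_labels(4)
        m = toy_model(X, y, epochs=3, seed=1)
        lam_pre = m.omega_.T @ m.omega_
        expected = 0.0
        for i in range(4):
            dj = metric_distance(X[i], m.prototypes_[0 if y[i] == "sMCI" else 1], lam_pre)
            dk = metric_distance(X[i], m.prototypes_[1 if y[i] == "sMCI" else 0], lam_pre)
            expected += (dj - dk) / (dj + dk)
        assert glvq_cost(m, X, y) == pytest.approx(expected, abs=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        worst = 0.0
        for trial in range(20):
            p = (2, 3, 5)[trial % 3]
            n = int(rng.integers(4, 17))
            X = rng.normal(size=(n, p))
            y = toy_labels(n)
            m = toy_model(X, y, epochs=4, seed=trial)
            analytic = cost_gradients(m, X, y)
            numeric = numerical_cost_gradient(m, X, y, h=1e-5)
            for a, b in zip(analytic, numeric):
                scale = np.maximum(np.abs(b), 1e-8)
                worst = max(worst, float(np.max(np.abs(a - b) / scale)))
        assert worst < 1e-5

    def test_duplicating_samples_doubles_gradients(self, rng):
        X = rng.normal(size=(6, 3))
        y = toy_labels(6)
        m = toy_model(X, y, epochs=2, seed=2)
        single = cost_gradients(m, X, y)
        double = cost_gradients(m, np.vstack([X, X]), np.concatenate([y, y]))
        for a, b in zip(single, double):
            np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_finite_difference_halving_h_quarters_error(self, rng):
        X = rng.normal(size=(6, 3))
        y = toy_labels(6)
        m = toy_model(X, y, epochs=2, seed=3)
        exact = cost_gradients(m, X, y)[2]
        err = lambda h: np.abs(numerical_cost_gradient(m, X, y, h=h)[2] - exact).max()
        e1, e2 = err(1e-2), err(5e-3)
        assert e2 < e1 / 3  # second-order scheme: roughly quartered

    def test_unknown_label_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        y = toy_labels(4)
        m = toy_model(X, y, epochs=1)
        with pytest.raises(ClassBalanceError):
            glvq_cost(m, X, np.array(["sMCI", "pMCI", "sMCI", "AD"]))


class TestTraining:
    def separable(self, rng, n=40, gap=8.0):
        X = rng.normal(size=(n, 3)) * 0.5
        X[n // 2 :, 0] += gap
        y = np.array(["sMCI"] * (n // 2) + ["pMCI"] * (n // 2))
        return X, y

    def test_separable_clusters_reach_perfect_accuracy(self, rng):
        X, y = self.separable(rng)
        m = train_gmlvq(X, y, GmlvqHyper(epochs=100))
        assert (m.predict(X) == y).all()
        assert m.cost_trace_[-1] < m.cost_trace_[0]

    def test_same_seed_bit_identical(self, rng):
        X, y = self.separable(rng)
        h = GmlvqHyper(epochs=40, jitter_sd=0.2, seed=5)
        m1, m2 = train_gmlvq(X, y, h), train_gmlvq(X, y, h)
        assert np.array_equal(m1.prototypes_, m2.prototypes_)
        assert np.array_equal(m1.omega_, m2.omega_)

    def test_trace_one_and_psd_after_training(self, rng):
        X, y = self.separable(rng)
        for epochs in (1, 7, 60):
            m = train_gmlvq(X, y, GmlvqHyper(epochs=epochs))
            assert abs(np.trace(m.lambda_) - 1.0) < 1e-12
            assert np.linalg.eigvalsh(m.lambda_).min() >= -1e-10

    def test_relevance_concentrates_on_informative_feature(self, rng):
        n, p = 400, 3
        X = rng.normal(size=(n, p))
        y = np.array(["sMCI"] * (n // 2) + ["pMCI"] * (n // 2))
        X[y == "pMCI", 0] += 2.0  # class signal only in feature 1
        m = train_gmlvq(X, y, GmlvqHyper(epochs=300))
        assert m.lambda_[0, 0] > 1.0 / p

    def test_feature_permutation_equivariance(self, rng):
        X, y = self.separable(rng)
        perm = np.array([2, 0, 1])
        h = GmlvqHyper(epochs=30, jitter_sd=0.0, seed=0)
        m1 = train_gmlvq(X, y, h)
        m2 = train_gmlvq(X[:, perm], y, h)
        np.testing.assert_allclose(m2.prototypes_, m1.prototypes_[:, perm], atol=1e-12)
        np.testing.assert_allclose(m2.lambda_, m1.lambda_[np.ix_(perm, perm)], atol=1e-12)

    def test_frozen_identity_metric_reduces_to_euclidean(self, rng):
        X, y = self.separable(rng)
        m = train_gmlvq(X, y, GmlvqHyper(alpha_omega=0.0, epochs=30))
        p = X.shape[1]
        np.testing.assert_allclose(m.lambda_, np.eye(p) / p, atol=1e-14)
        x = rng.normal(size=p)
        d = metric_distance(x, m.prototypes_[0], m.lambda_)
        assert d == pytest.approx(np.sum((x - m.prototypes_[0]) ** 2) / p)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ClassBalanceError):
            train_gmlvq(X, np.array(["sMCI"] * 6), GmlvqHyper(epochs=1))


class TestPrediction:
    def fitted(self, rng):
        X = rng.normal(size=(8, 2))
        X[4:, 0] += 5
        y = np.array(["sMCI"] * 4 + ["pMCI"] * 4)
        return train_gmlvq(X, y, GmlvqHyper(epochs=20))

    def test_prototype_coordinates_classify_to_their_class(self, rng):
        m = self.fitted(rng)
        assert m.predict(m.prototypes_[0][None])[0] == "sMCI"
        assert m.predict(m.prototypes_[1][None])[0] == "pMCI"

    def test_exact_tie_goes_progressive(self, rng):
        m = self.fitted(rng)
        # midpoint is equidistant under any metric
        mid = m.prototypes_.mean(axis=0)
        assert m.predict(mid[None])[0] == "pMCI"
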