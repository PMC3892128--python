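"""Tests for the closed-form ridge ELM: basis, hidden map, training
against an independent ridge oracle, prediction, and serialization."""

import time

import numpy as np
import pytest

from fmgelm import ConfigurationError
from fmgelm.elm import (
    ELMModel,
    HiddenBasis,
    hidden_map,
    load_model,
    one_hot_targets,
    predict,
    random_basis,
    save_model,
    solve_output_weights,
    train,
)


def _random_instance(seed, N, L, K=3, d=4):
    rng = np.random.default_rng(seed)
    H = rng.normal(size=(N, L))
    T = np.zeros((N, K))
    T[np.arange(N), rng.integers(0, K, N)] = 1.0
    return H, T


class TestRandomBasis:
    def test_deterministic_for_seed(self):
        b1 = random_basis(200, 8, seed=7)
        b2 = random_basis(200, 8, seed=7)
        assert np.array_equal(b1.A, b2.A) and np.array_equal(b1.b, b2.b)

    def test_entries_uniform_on_unit_interval(self):
        b = random_basis(500, 8, seed=0)
        assert b.A.min() >= -1 and b.A.max() <= 1
        assert b.b.min() >= -1 and b.b.max() <= 1

    def test_minimal_shape(self):
        b = random_basis(1, 1, seed=0)
        assert b.A.shape == (1, 1) and b.b.shape == (1,)


class TestHiddenMap:
    def test_sigmoid_at_zero_activation_is_half(self):
        basis = HiddenBasis(A=np.zeros((3, 8)), b=np.zeros(3))
        assert np.allclose(hidden_map(np.ones(8), basis), 0.5)

    def test_closed_form_sigmoid_value(self):
        A = np.zeros((1, 8))
        A[0, 0] = 1.0
        basis = HiddenBasis(A=A, b=np.zeros(1))
        x = np.zeros(8)
        x[0] = np.log(3.0)
        assert hidden_map(x, basis)[0] == pytest.approx(0.75)

    def test_outputs_strictly_inside_unit_interval(self):
        basis = random_basis(50, 8, seed=1)
        h = hidden_map(np.random.default_rng(0).normal(size=(20, 8)), basis)
        assert np.all(h > 0) and np.all(h < 1)

    def test_dimension_mismatch_rejected(self):
        basis = random_basis(5, 8, seed=0)
        with pytest.raises(ConfigurationError):
            hidden_map(np.ones(7), basis)


class TestClosedFormTraining:
    @pytest.mark.parametrize("seed,N,L", [(0, 12, 8), (1, 20, 10), (2, 8, 10),
                                          (3, 15, 15), (4, 30, 25)])
    def test_matches_independent_ridge_oracle(self, seed, N, L):
        """beta must minimize ||H beta - T||^2 + ||beta||^2 / C."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        H, T = _random_instance(seed, N, L)
        C = 2.0**7
        beta = solve_output_weights(H, T, C)
        oracle = sklearn.Ridge(alpha=1.0 / C, fit_intercept=False, solver="svd")
        oracle.fit(H, T)
        assert np.abs(beta - oracle.coef_.T).max() < 1e-8

    @pytest.mark.parametrize("seed,N,L", [(0, 10, 20), (1, 20, 10), (2, 25, 25)])
    def test_primal_and_dual_forms_agree(self, seed, N, L):
        H, T = _random_instance(seed, N, L)
        C = 2.0**7
        dual = H.T @ np.linalg.solve(np.eye(N) / C + H @ H.T, T)
        primal = np.linalg.solve(np.eye(L) / C + H.T @ H, H.T @ T)
        assert np.abs(dual - primal).max() < 1e-8
        assert np.abs(solve_output_weights(H, T, C) - primal).max() < 1e-8

    def test_identity_hidden_matrix_ridge_limit(self):
        # H = I, T = I: beta = (I/C + I)^{-1} -> I as C grows
        n = 5
        beta = solve_output_weights(np.eye(n), np.eye(n), C=1e12)
        assert np.abs(beta - np.eye(n)).max() < 1e-6

    def test_retraining_with_same_basis_is_identical(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(40, 8))
        y = rng.integers(1, 4, size=40)
        basis = random_basis(20, 8, seed=5)
        m1 = train(X, y, basis, C=2.0**7)
        m2 = train(X, y, basis, C=2.0**7)
        assert np.array_equal(m1.beta, m2.beta)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ConfigurationError):
            one_hot_targets([1, 2, 9], class_labels=[1, 2, 3])

    def test_training_900_samples_is_fast(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(900, 8))
        y = rng.integers(1, 7, size=900)
        basis = random_basis(200, 8, seed=0)
        t0 = time.perf_counter()
        train(X, y, basis, C=2.0**7)
        assert time.perf_counter() - t0 < 3.0


class TestPredict:
    def test_memorizes_separated_points(self):
        X = np.array([[0.0] * 8, [1.0] * 8])
        model = train(X, [1, 2], random_basis(20, 8, seed=0), C=2.0**7)
        lbl0, scores = predict(model, X[0])
        lbl1, _ = predict(model, X[1])
        assert (lbl0, lbl1) == (1, 2)
        assert scores.shape == (2,)  # one score per class

    def test_ties_break_toward_earliest_label(self):
        basis = HiddenBasis(A=np.zeros((4, 8)), b=np.zeros(4))
        model = ELMModel(
            basis=basis, beta=np.zeros((4, 3)), C=1.0, class_labels=(2, 5, 6)
        )
        lbl, _ = predict(model, np.ones(8))
        assert lbl == 2

    def test_separated_clusters_classified_perfectly(self):
        # 6 tight clusters of 50 samples in [0,1]^8 at the reference
        # hyperparameters must be memorized exactly
        rng = np.random.default_rng(0)
        centers = rng.uniform(0, 1, size=(6, 8))
        X = np.repeat(centers, 50, axis=0)
        y = np.repeat(np.arange(1, 7), 50)
        model = train(X, y, random_basis(200, 8, seed=1), C=2.0**7)
        preds, _ = predict(model, X)
        assert np.all(preds == y)

    def test_accuracy_plateaus_in_regularization_parameter(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(0, 1, size=(6, 8))
        X = np.vstack([c + rng.normal(0, 0.05, (30, 8)) for c in centers])
        y = np.repeat(np.arange(1, 7), 30)
        basis = random_basis(200, 8, seed=3)
        accs = []
        for k in range(5, 12):
            model = train(X, y, basis, C=2.0**k)
            preds, _ = predict(model, X)
            accs.append(np.mean(preds == y) * 100)
        assert max(accs) - min(accs) <= 2.0

    def test_accuracy_nondecreasing_in_hidden_nodes_until_plateau(self):
        rng = np.random.default_rng(0)
        centers = rng.uniform(0, 1, size=(6, 8))

        def clusters(seed, n=40, sd=0.35):
            r = np.random.default_rng(seed)
            X = np.vstack([c + r.normal(0, sd, (n, 8)) for c in centers])
            return X, np.repeat(np.arange(1, 7), n)

        Xtr, ytr = clusters(1)
        Xte, yte = clusters(2)
        medians = {}
        for L in (10, 50, 200):
            accs = []
            for s in range(9):
                model = train(Xtr, ytr, random_basis(L, 8, seed=s), C=2.0**7)
                preds, _ = predict(model, Xte)
                accs.append(np.mean(preds == yte) * 100)
            medians[L] = np.median(accs)
        assert medians[50] >= medians[10]
        # beyond the plateau only statistical flutter remains
        assert medians[200] >= medians[50] - 2.0


class TestSerialization:
    def test_round_trip_is_value_stable(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(60, 8))
        y = rng.integers(1, 4, size=60)
        from fmgelm.preprocess import fit_normalization

        norm = fit_normalization(X)
        model = train(X, y, random_basis(25, 8, seed=11), C=2.0**7, norm=norm)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.class_labels == model.class_labels
        assert back.C == model.C
        assert back.basis.seed == 11
        assert np.abs(back.basis.A - model.basis.A).max() < 1e-12
        assert np.abs(back.beta - model.beta).max() < 1e-12
        assert np.abs(back.norm.mins - norm.mins).max() < 1e-12
        preds_a, _ = predict(model, X)
        preds_b, _ = predict(back, X)
        assert np.array_equal(preds_a, preds_b)
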