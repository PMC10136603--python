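"""ELM closed form, shallow head adapters, and grid search."""

import numpy as np
import pytest

from eegcube.heads import (
    GridSearchSpec,
    elm_fit,
    elm_predict,
    fit_shallow,
    grid_search,
    predict_shallow,
)
from conftest import separable_toy


def ridge_oracle(model, x, y, n_classes):
    """Independent ridge solve of the ELM normal equations."""
    import scipy.linalg

    z = x @ model.input_weights.T + model.biases
    h = 1.0 / (1.0 + np.exp(-z))
    onehot = np.eye(n_classes)[y]
    return scipy.linalg.solve(
        h.T @ h + model.ridge * np.eye(h.shape[1]), h.T @ onehot
    )


class TestELMFit:
    def test_huge_ridge_shrinks_beta_to_zero(self, rng):
        x = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, size=40)
        model = elm_fit(x, y, hidden_width=30, ridge=1e12, seed=0)
        assert np.abs(model.beta).max() <= 1e-6

    def test_separable_toy_training_accuracy(self):
        x, y = separable_toy(n=200, separation=10.0)
        model = elm_fit(x, y, hidden_width=200, ridge=1e-3, seed=0)
        labels, _ = elm_predict(model, x)
        assert (labels == y).mean() == 1.0

    def test_beta_matches_ridge_oracle(self, rng):
        x = rng.normal(size=(50, 5))
        y = rng.integers(0, 3, size=50)
        model = elm_fit(x, y, hidden_width=20, ridge=1e-3, seed=4, n_classes=3)
        expected = ridge_oracle(model, x, y, 3)
        assert np.abs(model.beta - expected).max() < 1e-6

    def test_oracle_equivalence_over_random_instances(self, rng):
        for trial in range(100):
            n = int(rng.integers(5, 101))
            d = int(rng.integers(1, 21))
            hidden = int(rng.integers(1, 51))
            k = int(rng.integers(2, 4))
            n = max(n, k)
            x = rng.normal(size=(n, d))
            y = rng.integers(0, k, size=n)
            y[:k] = np.arange(k)  # every class present
            model = elm_fit(x, y, hidden_width=hidden, ridge=1e-2,
                            seed=trial, n_classes=k)
            expected = ridge_oracle(model, x, y, k)
            assert np.abs(model.beta - expected).max() < 1e-6

    def test_projection_frozen_and_seeded(self):
        x, y = separable_toy(n=40)
        a = elm_fit(x, y, hidden_width=10, seed=5)
        b = elm_fit(x, y, hidden_width=10, seed=5)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.biases, b.biases)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_fewer_samples_than_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            elm_fit(rng.normal(size=(2, 3)), np.array([0, 1]), n_classes=3)

    def test_zero_ridge_illconditioned_falls_back(self, rng):
        x = np.repeat(rng.normal(size=(5, 2)), 10, axis=0)  # rank-deficient H
        y = np.tile([0, 1, 0, 1, 0], 10)
        with pytest.warns(RuntimeWarning, match="pseudoinverse"):
            model = elm_fit(x, y, hidden_width=60, ridge=0.0, seed=0)
        assert np.all(np.isfinite(model.beta))

    def test_accuracy_non_decreasing_in_hidden_width(self):
        # statistical check across seeds on the separable toy
        accs = {50: [], 400: []}
        for seed in range(5):
            x, y = separable_toy(n=200, separation=10.0, seed=seed)
            for width in accs:
                model = elm_fit(x, y, hidden_width=width, ridge=1e-3, seed=seed)
                accs[width].append((elm_predict(model, x)[0] == y).mean())
        assert np.mean(accs[400]) >= np.mean(accs[50])


class TestELMPredict:
    def test_consistency_with_fit(self):
        x, y = separable_toy(n=100)
        model = elm_fit(x, y, hidden_width=100, seed=0)
        l1, _ = elm_predict(model, x)
        l2, _ = elm_predict(model, x)
        np.testing.assert_array_equal(l1, l2)

    def test_duplicate_rows_identical_scores(self, rng):
        x, y = separable_toy(n=50)
        model = elm_fit(x, y, hidden_width=30, seed=0)
        doubled = np.vstack([x[:1], x[:1]])
        _, scores = elm_predict(model, doubled)
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_zero_beta_ties_break_to_class_zero(self):
        x, y = separable_toy(n=50)
        model = elm_fit(x, y, hidden_width=30, seed=0)
        model.beta[...] = 0.0
        labels, scores = elm_predict(model, x)
        assert not scores.any()
        assert np.all(labels == 0)

    def test_dimension_mismatch_rejected(self, rng):
        x, y = separable_toy(n=50, d=2)
        model = elm_fit(x, y, hidden_width=10, seed=0)
        with pytest.raises(ValueError, match="dim"):
            elm_predict(model, rng.normal(size=(3, 5)))


class TestShallowHeads:
    def test_1nn_memorizes_training_set(self):
        x, y = separable_toy(n=60, separation=2.0)
        head = fit_shallow("knn", x, y, {"n_neighbors": 1})
        np.testing.assert_array_equal(predict_shallow(head, x), y)

    @pytest.mark.parametrize("kind", ["knn", "svm", "rf", "xgb"])
    def test_all_heads_solve_separable_toy(self, kind):
        x, y = separable_toy(n=200, separation=10.0)
        head = fit_shallow(kind, x, y, seed=0)
        assert (predict_shallow(head, x) == y).mean() == 1.0

    @pytest.mark.parametrize("kind", ["rf", "xgb", "svm", "knn"])
    def test_seeded_determinism(self, kind):
        x, y = separable_toy(n=100, separation=3.0)
        p1 = predict_shallow(fit_shallow(kind, x, y, seed=7), x)
        p2 = predict_shallow(fit_shallow(kind, x, y, seed=7), x)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_kind_rejected(self):
        x, y = separable_toy(n=20)
        with pytest.raises(ValueError, match="unknown head kind"):
            fit_shallow("mlpx", x, y)


class TestGridSearch:
    def test_single_cell_returned(self):
        x, y = separable_toy(n=100)
        res = grid_search(GridSearchSpec("knn", {"n_neighbors": [3]}, seed=0), x, y)
        assert res.best_params == {"n_neighbors": 3}
        assert len(res.table) == 1

    def test_knn_k_selection_matches_manual_evaluation(self):
        from sklearn.model_selection import train_test_split
        from sklearn.neighbors import KNeighborsClassifier

        x, y = separable_toy(n=200, separation=10.0, seed=1)
        spec = GridSearchSpec("knn", {"n_neighbors": [1, 51]}, seed=0)
        res = grid_search(spec, x, y)
        # independent evaluation of both cells on the same split
        xtr, xval, ytr, yval = train_test_split(
            x, y, test_size=spec.validation_fraction, stratify=y, random_state=0
        )
        scores = {
            k: KNeighborsClassifier(n_neighbors=k).fit(xtr, ytr).score(xval, yval)
            for k in (1, 51)
        }
        manual_best = max(scores, key=lambda k: scores[k])
        assert res.best_params["n_neighbors"] == manual_best == 1

    def test_tied_scores_return_first_declared(self):
        x, y = separable_toy(n=200, separation=10.0)
        res = grid_search(
            GridSearchSpec("knn", {"n_neighbors": [3, 5]}, seed=0), x, y
        )
        # both cells score 1.0 on a 10-sigma separable toy
        assert res.table[0][1] == res.table[1][1] == 1.0
        assert res.best_params == {"n_neighbors": 3}

    def test_failing_cell_recorded_as_null(self):
        x, y = separable_toy(n=100)
        res = grid_search(
            GridSearchSpec("svm", {"C": [-1.0, 1.0]}, seed=0), x, y
        )
        assert res.table[0][1] is None
        assert res.best_params == {"C": 1.0}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            GridSearchSpec("knn", {})
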