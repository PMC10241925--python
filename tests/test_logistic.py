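import json

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from boolfeat import expressions as ex
from boolfeat.exceptions import DegenerateDataError, SchemaError
from boolfeat.datasets import Dataset
from boolfeat.logistic import (
    Model,
    balanced_log_loss,
    class_weights,
    fit_logistic,
    fit_model,
    sigmoid,
)


class TestClassWeights:
    def test_balanced_classes_unit_weights(self):
        w = class_weights(np.array([0, 1, 0, 1]))
        np.testing.assert_allclose(w, 1.0)

    def test_formula(self):
        y = np.array([1, 1] + [0] * 8)
        w = class_weights(y)
        assert w[0] == pytest.approx(10 / 4)     # N/(2*N1) = 2.5
        assert w[-1] == pytest.approx(10 / 16)   # N/(2*N0) = 0.625

    def test_classes_contribute_equal_total_weight(self, rng):
        for _ in range(20):
            y = (rng.random(50) < rng.uniform(0.1, 0.9)).astype(int)
            if y.min() == y.max():
                continue
            w = class_weights(y)
            assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())

    def test_single_class_errors(self):
        with pytest.raises(DegenerateDataError):
            class_weights(np.ones(5, dtype=int))


class TestBalancedLogLoss:
    def test_coin_flip_is_ln2(self, rng):
        for prev in (0.1, 0.5, 0.9):
            y = (rng.random(200) < prev).astype(int)
            agg, _ = balanced_log_loss(y, np.full(200, 0.5), class_weights(y) if 0 < y.mean() < 1 else None)
            assert agg == pytest.approx(np.log(2))

    def test_perfect_predictions_clipped(self):
        y = np.array([1, 0])
        agg, per = balanced_log_loss(y, np.array([1.0, 0.0]))
        assert agg <= -np.log(1 - 1e-12) + 1e-15

    def test_hand_worked_instance(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([0.9, 0.2, 0.6, 0.4])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.6) + np.log(0.6)) / 4
        agg, per = balanced_log_loss(y, p)
        assert agg == pytest.approx(expected)
        assert per.sum() / 4 == pytest.approx(agg)

    def test_duplication_invariance(self, rng):
        y = (rng.random(30) < 0.3).astype(int)
        p = rng.random(30)
        w = rng.uniform(0.5, 2, 30)
        a1, _ = balanced_log_loss(y, p, w)
        a2, _ = balanced_log_loss(np.tile(y, 2), np.tile(p, 2), np.tile(w, 2))
        assert a1 == pytest.approx(a2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            balanced_log_loss(np.array([1, 0]), np.array([0.5]))


class TestFitLogistic:
    def test_null_signal_small_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5000, 2))
        y = (rng.random(5000) < 0.5).astype(int)
        beta, _ = fit_logistic(X, y, class_weights(y))
        assert np.all(np.abs(beta) <= 0.1)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 2))
        p = sigmoid(X @ np.array([2.0, -1.0]))
        y = (rng.random(5000) < p).astype(int)
        beta, b0 = fit_logistic(X, y, class_weights(y))
        np.testing.assert_allclose(beta, [2.0, -1.0], atol=0.15)
        assert abs(b0) < 0.15

    def test_separated_data_finite_and_confident(self):
        X = np.r_[np.full((20, 1), -1.0), np.full((20, 1), 1.0)]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        beta, b0 = fit_logistic(X, y)
        assert np.isfinite(beta).all()
        loss, _ = balanced_log_loss(y, sigmoid(X[:, 0] * beta[0] + b0))
        assert loss < 0.01

    def test_matches_sklearn_on_balanced_data(self):
        """Independent cross-check against an established solver."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 3))
        y = (sigmoid(X @ np.array([1.0, -0.5, 0.2])) > rng.random(400)).astype(int)
        beta, b0 = fit_logistic(X, y, np.ones(400), ridge=1e-6)
        ref = LogisticRegression(C=1e6, tol=1e-10).fit(X, y)
        np.testing.assert_allclose(beta, ref.coef_[0], atol=0.02)
        assert b0 == pytest.approx(ref.intercept_[0], abs=0.02)

    def test_weighted_equals_unweighted_when_balanced(self, rng):
        X = rng.normal(size=(200, 2))
        y = np.tile([0, 1], 100)
        b1 = fit_logistic(X, y, class_weights(y))
        b2 = fit_logistic(X, y, None)
        np.testing.assert_allclose(b1[0], b2[0], atol=1e-6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.array([[np.nan], [1.0]]), np.array([0, 1]))


class TestModel:
    def _model(self):
        rep = ex.Representation((ex.gt(0, 0.5), ex.feature(1)))
        return Model(representation=rep, beta=np.array([1.5, -0.5]), intercept=0.2,
                     decision_threshold=0.4, feature_names=["a", "b"])

    def test_zero_model_predicts_half(self):
        rep = ex.Representation((ex.feature(0),))
        m = Model(rep, beta=np.zeros(1), intercept=0.0)
        np.testing.assert_allclose(m.predict_proba(np.zeros((5, 1))), 0.5)

    def test_probability_monotone_in_intercept(self):
        rep = ex.Representation((ex.feature(0),))
        X = np.zeros((3, 1))
        probs = [Model(rep, np.zeros(1), b0).predict_proba(X)[0] for b0 in (-5, 0, 5, 50)]
        assert probs == sorted(probs) and probs[-1] > 1 - 1e-9

    def test_matches_per_row_computation(self, rng):
        m = self._model()
        X = rng.normal(size=(10, 2))
        for i in range(10):
            phi = np.array([float(X[i, 0] > 0.5), X[i, 1]])
            z = phi @ m.beta + m.intercept
            assert m.predict_proba(X)[i] == pytest.approx(1 / (1 + np.exp(-z)))

    def test_permuting_tree_coefficient_pairs_invariant(self, rng):
        m = self._model()
        swapped = Model(
            representation=ex.Representation(m.representation.trees[::-1]),
            beta=m.beta[::-1].copy(), intercept=m.intercept,
            decision_threshold=m.decision_threshold, feature_names=m.feature_names,
        )
        X = rng.normal(size=(20, 2))
        np.testing.assert_allclose(m.predict_proba(X), swapped.predict_proba(X))

    def test_name_based_column_binding(self, rng):
        m = self._model()
        X = rng.normal(size=(8, 2))
        ds = Dataset(X=X, y=None, feature_names=["a", "b"],
                     subject_ids=[str(i) for i in range(8)])
        permuted = Dataset(X=X[:, ::-1].copy(), y=None, feature_names=["b", "a"],
                           subject_ids=ds.subject_ids)
        np.testing.assert_allclose(m.predict_proba(ds), m.predict_proba(permuted))

    def test_schema_mismatch_errors(self, rng):
        m = self._model()
        ds = Dataset(X=rng.normal(size=(4, 2)), y=None, feature_names=["a", "c"],
                     subject_ids=list("wxyz"))
        with pytest.raises(SchemaError):
            m.predict_proba(ds)

    def test_json_round_trip_bit_exact(self, tmp_path):
        m = self._model()
        path = tmp_path / "model.json"
        m.to_json(path)
        back = Model.from_json(path)
        assert back.representation == m.representation
        assert back.beta.tolist() == m.beta.tolist()
        assert back.intercept == m.intercept
        assert back.decision_threshold == m.decision_threshold
        assert back.feature_names == m.feature_names


class TestFitModel:
    def test_record_consistency(self, small_dataset):
        rep = ex.Representation((ex.gt(0, 0.0),))
        model, record = fit_model(rep, small_dataset.X, small_dataset.y)
        assert record.size == 2
        assert record.balanced_loss == pytest.approx(
            record.per_case_losses.sum() / class_weights(small_dataset.y).sum()
        )
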