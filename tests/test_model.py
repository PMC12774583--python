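"""Classifier training, ROC-AUC semantics, cross-validation and feature
ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caddforge.features import FeatureMatrix
from caddforge.model import (
    ModelError,
    TrainedModel,
    cross_validate,
    roc_auc,
    subset_auc,
    top_features,
    train,
)


def _matrix(X, y=None, names=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        row_keys=pd.DataFrame(index=range(X.shape[0])),
        column_names=names or [f"f{j}" for j in range(X.shape[1])],
        X=X,
        y=None if y is None else np.asarray(y),
        imputation_stats={},
    )


def brute_force_auc(labels, scores):
    """O(n^2) all-pairs Mann-Whitney statistic with half-credit ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestTrain:
    def test_separable_direction_gets_positive_weight(self):
        X = np.concatenate([np.zeros(50), np.ones(50)])[:, None]
        y = (X[:, 0] > 0.5).astype(int)
        model = train(_matrix(X, y))
        assert model.weights[0] > 0

    def test_single_class_is_an_error(self):
        X = np.ones((10, 1))
        with pytest.raises(ModelError):
            train(_matrix(X, np.ones(10, dtype=int)))

    def test_bad_l2_is_an_error(self):
        X = np.arange(10, dtype=float)[:, None]
        y = (X[:, 0] > 4).astype(int)
        with pytest.raises(ModelError):
            train(_matrix(X, y), l2=-1.0)

    def test_stronger_penalty_never_grows_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 3))
        y = (X @ np.array([1.5, -1.0, 0.2]) + rng.logistic(size=500) > 0).astype(int)
        # smaller C = stronger L2 penalty in this parameterization
        weak = train(_matrix(X, y), l2=1.0)
        strong = train(_matrix(X, y), l2=0.5)
        assert np.linalg.norm(strong.weights) <= np.linalg.norm(weak.weights) + 1e-9

    def test_planted_coefficients_rank_correctly(self):
        rng = np.random.default_rng(7)
        beta = np.array([2.0, -1.0, 0.0, 0.5])
        X = rng.normal(size=(20_000, 4))
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        y = (rng.random(20_000) < p).astype(int)
        model = train(_matrix(X, y))
        mags = np.abs(model.weights)
        assert mags[0] > mags[1] > mags[3] > mags[2]
        assert np.argmin(mags) == 2       # the planted zero

    def test_column_permutation_permutes_weights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 4))
        y = (X @ np.array([1.0, -0.5, 0.3, 0.0]) > 0).astype(int)
        base = train(_matrix(X, y))
        perm = [2, 0, 3, 1]
        permuted = train(_matrix(X[:, perm], y))
        assert np.allclose(permuted.weights, base.weights[perm], atol=1e-6)

    def test_json_round_trip(self, tmp_path):
        X = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
        y = (X[:, 0] > 0.5).astype(int)
        model = train(_matrix(X, y))
        model.imputation_stats = {"f0": 1.5}
        path = tmp_path / "model.json"
        model.to_json(path)
        again = TrainedModel.from_json(path)
        assert np.allclose(again.weights, model.weights)
        assert again.imputation_stats == {"f0": 1.5}
        assert again.l2 == model.l2


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_label_inversion_symmetry(self):
        labels = np.array([0, 1, 0, 1, 1])
        scores = np.array([0.3, 0.4, 0.4, 0.9, 0.1])
        assert roc_auc(1 - labels, scores) == pytest.approx(
            1.0 - roc_auc(labels, scores)
        )

    def test_single_class_is_undefined(self):
        assert roc_auc([1, 1, 1], [1.0, 2.0, 3.0]) is None

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 201))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            assert roc_auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores), abs=1e-12
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=50)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.normal(size=50)
        transformed = np.exp(3.0 * scores) + 7.0
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc(labels, transformed), abs=1e-12
        )


class TestCrossValidate:
    @staticmethod
    def _gaussian_data(n, beta=1.5, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.normal(loc=y[:, None] * beta, scale=1.0, size=(n, 1))
        return _matrix(X, y)

    def test_same_seed_same_folds(self):
        m = self._gaussian_data(300)
        a = cross_validate(m, k=5, seed=9)
        b = cross_validate(m, k=5, seed=9)
        assert a.fold_auc == b.fold_auc
        assert np.array_equal(a.oof_scores, b.oof_scores)

    def test_mean_is_average_of_folds(self):
        m = self._gaussian_data(200)
        rep = cross_validate(m, k=4, seed=1)
        assert rep.mean_auc == pytest.approx(np.mean(rep.fold_auc))
        assert len(rep.fold_auc) == 4

    def test_matches_closed_form_bayes_auc(self):
        # one Gaussian feature, class means 0 and beta, unit SD:
        # the Bayes AUC is Phi(beta/sqrt(2))
        from scipy.stats import norm

        beta = 1.0
        m = self._gaussian_data(20_000, beta=beta, seed=4)
        rep = cross_validate(m, k=5, seed=4)
        assert rep.mean_auc == pytest.approx(norm.cdf(beta / np.sqrt(2)), abs=0.02)

    def test_too_few_per_class_is_an_error(self):
        X = np.arange(6, dtype=float)[:, None]
        y = np.array([0, 0, 0, 0, 0, 1])
        with pytest.raises(ModelError):
            cross_validate(_matrix(X, y), k=5, seed=0)


class TestSubsetAuc:
    def test_full_subset_equals_overall(self):
        m = TestCrossValidate._gaussian_data(400, seed=6)
        rep = cross_validate(m, k=5, seed=6)
        table = subset_auc(m.y, rep.oof_scores, {"all": np.ones(400, dtype=bool)})
        assert table.loc[0, "auc"] == pytest.approx(
            roc_auc(m.y, rep.oof_scores)
        )

    def test_uninformative_subset_is_near_half(self):
        rng = np.random.default_rng(8)
        n = 4000
        y = rng.integers(0, 2, size=n)
        X = rng.normal(loc=y[:, None] * 2.0, size=(n, 1))
        half = np.zeros(n, dtype=bool)
        half[: n // 2] = True
        # shuffle the feature within the first half: no signal remains there
        X[half, 0] = rng.permutation(X[half, 0])
        m = _matrix(X, y)
        rep = cross_validate(m, k=5, seed=8)
        table = subset_auc(m.y, rep.oof_scores, {"shuffled": half})
        assert 0.45 < table.loc[0, "auc"] < 0.55

    def test_single_class_subset_reports_counts(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.9, 0.8])
        mask = np.array([True, True, False, False])
        table = subset_auc(y, scores, {"only0": mask})
        assert np.isnan(table.loc[0, "auc"])
        assert table.loc[0, "n_variants"] == 2


class TestTopFeatures:
    def _model(self, weights, names=None):
        w = np.asarray(weights, dtype=float)
        return TrainedModel(
            column_names=names or [f"f{j}" for j in range(len(w))],
            weights=w,
            intercept=0.0,
            l2=0.1,
            max_iter=100,
            converged=True,
        )

    def test_sorted_by_magnitude(self):
        model = self._model([0.1, -2.0, 1.0])
        assert top_features(model, k=2) == [("f1", -2.0), ("f2", 1.0)]

    def test_k_larger_than_m_returns_all(self):
        model = self._model([0.5, -0.1])
        assert len(top_features(model, k=10)) == 2

    def test_exact_tie_breaks_by_column_order(self):
        model = self._model([1.0, -1.0, 0.5])
        assert [n for n, _ in top_features(model, k=2)] == ["f0", "f1"]
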