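"""L2-penalized logistic classification of proxy-neutral vs proxy-deleterious
variants, with stratified cross-validated ROC-AUC reporting.

The classifier is scikit-learn's LogisticRegression with lbfgs: the
regularization knob follows that parameterization, so ``l2 = 0.1`` means
``C = 0.1`` (a strong penalty). Class 1 is the simulated
(proxy-deleterious) class throughout, so larger decision values mean
"more deleterious-like". Features are used as encoded, without
standardization, unless ``standardize`` is set; the choice is recorded in
the model metadata.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix


class ModelError(ValueError):
    pass


@dataclass
class TrainedModel:
    column_names: list[str]
    weights: np.ndarray
    intercept: float
    l2: float
    max_iter: int
    converged: bool
    standardize: bool = False
    feature_means: np.ndarray | None = None
    feature_scales: np.ndarray | None = None
    imputation_stats: dict[str, float] | None = None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor w.x + b (monotone in the class-1 probability)."""
        if X.shape[1] != len(self.column_names):
            raise ModelError(
                f"matrix has {X.shape[1]} columns, model expects {len(self.column_names)}"
            )
        if self.standardize:
            X = (X - self.feature_means) / self.feature_scales
        return X @ self.weights + self.intercept

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "format": "caddforge-model-v1",
            "column_names": self.column_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "l2": self.l2,
            "max_iter": self.max_iter,
            "converged": self.converged,
            "solver": "lbfgs",
            "standardize": self.standardize,
            "feature_means": None
            if self.feature_means is None
            else self.feature_means.tolist(),
            "feature_scales": None
            if self.feature_scales is None
            else self.feature_scales.tolist(),
            "imputation_stats": self.imputation_stats,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TrainedModel":
        with open(path) as fh:
            p = json.load(fh)
        if p.get("format") != "caddforge-model-v1":
            raise ModelError(f"{path}: not a caddforge model artifact")
        return cls(
            column_names=p["column_names"],
            weights=np.asarray(p["weights"], dtype=float),
            intercept=float(p["intercept"]),
            l2=p["l2"],
            max_iter=p["max_iter"],
            converged=p["converged"],
            standardize=p["standardize"],
            feature_means=None
            if p["feature_means"] is None
            else np.asarray(p["feature_means"], dtype=float),
            feature_scales=None
            if p["feature_scales"] is None
            else np.asarray(p["feature_scales"], dtype=float),
            imputation_stats=p.get("imputation_stats"),
        )


def _fit(X: np.ndarray, y: np.ndarray, l2: float, max_iter: int):
    # default penalty is ridge (L2); C is the inverse regularization strength
    clf = LogisticRegression(C=l2, max_iter=max_iter, solver="lbfgs", tol=1e-4)
    clf.fit(X, y)
    return clf


def train(
    matrix: FeatureMatrix,
    l2: float = 0.1,
    max_iter: int = 100,
    standardize: bool = False,
) -> TrainedModel:
    """Fit the penalized logistic classifier on the full training matrix."""
    if l2 <= 0:
        raise ModelError(f"l2 strength must be > 0, got {l2}")
    if matrix.y is None:
        raise ModelError("training needs class labels")
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ModelError("training data contains a single class")
    X = matrix.X
    means = scales = None
    if standardize:
        means = X.mean(axis=0)
        scales = X.std(axis=0)
        scales = np.where(scales > 0, scales, 1.0)
        X = (X - means) / scales
    clf = _fit(X, y, l2, max_iter)
    return TrainedModel(
        column_names=list(matrix.column_names),
        weights=clf.coef_[0].astype(float),
        intercept=float(clf.intercept_[0]),
        l2=l2,
        max_iter=max_iter,
        converged=bool(clf.n_iter_[0] < max_iter),
        standardize=standardize,
        feature_means=means,
        feature_scales=scales,
        imputation_stats=matrix.imputation_stats,
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """ROC-AUC = P(score1 > score0) + 0.5 P(score1 == score0); None when a
    class is absent."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CVReport:
    k: int
    seed: int
    fold_auc: list[float]
    oof_scores: np.ndarray       # out-of-fold decision values, input order

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#fold\tauc\n")
            for i, a in enumerate(self.fold_auc, start=1):
                fh.write(f"{i}\t{a:.6f}\n")
            fh.write(f"mean\t{self.mean_auc:.6f}\n")


def cross_validate(
    matrix: FeatureMatrix,
    k: int = 5,
    seed: int = 0,
    l2: float = 0.1,
    max_iter: int = 100,
    standardize: bool = False,
) -> CVReport:
    """Stratified k-fold CV; per fold, train on k-1 parts and compute AUC on
    the held-out part. Fold assignment is reproducible from the seed."""
    if k < 2:
        raise ModelError(f"k must be >= 2, got {k}")
    if matrix.y is None:
        raise ModelError("cross-validation needs class labels")
    y = matrix.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ModelError(
            f"smallest class has {counts.min()} rows, too few for {k} stratified folds"
        )
    X = matrix.X
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auc: list[float] = []
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in skf.split(X, y):
        Xtr, ytr = X[train_idx], y[train_idx]
        means = scales = None
        if standardize:
            means = Xtr.mean(axis=0)
            scales = Xtr.std(axis=0)
            scales = np.where(scales > 0, scales, 1.0)
            Xtr = (Xtr - means) / scales
        clf = _fit(Xtr, ytr, l2, max_iter)
        Xte = X[test_idx]
        if standardize:
            Xte = (Xte - means) / scales
        s = Xte @ clf.coef_[0] + clf.intercept_[0]
        oof[test_idx] = s
        auc = roc_auc(y[test_idx], s)
        if auc is None:
            raise ModelError("a fold lost one class entirely")
        fold_auc.append(auc)
    return CVReport(k=k, seed=seed, fold_auc=fold_auc, oof_scores=oof)


def subset_auc(
    labels: np.ndarray,
    oof_scores: np.ndarray,
    subsets: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Out-of-fold AUC restricted to each named variant subset.

    Subsets missing a class get AUC NaN with their counts still recorded.
    """
    rows = []
    labels = np.asarray(labels)
    for name, mask in subsets.items():
        mask = np.asarray(mask, dtype=bool)
        n1 = int((labels[mask] == 1).sum())
        n0 = int((labels[mask] == 0).sum())
        auc = (
            roc_auc(labels[mask], oof_scores[mask]) if n1 and n0 else None
        )
        rows.append(
            {
                "subset": name,
                "auc": np.nan if auc is None else auc,
                "n_variants": n0 + n1,
                "n_derived": n0,
                "n_simulated": n1,
            }
        )
    return pd.DataFrame(rows)


def top_features(model: TrainedModel, k: int = 10) -> list[tuple[str, float]]:
    """Features ranked by |weight| descending; ties break by column order."""
    order = sorted(
        range(len(model.weights)),
        key=lambda j: (-abs(model.weights[j]), j),
    )
    return [(model.column_names[j], float(model.weights[j])) for j in order[:k]]
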