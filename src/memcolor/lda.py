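"""Shrinkage-regularized linear discriminant analysis with train-only z-scoring.

Region patterns often have more voxels (100 after bilateral collapse)
than training samples per fold, so the pooled within-class covariance is
regularized by convex shrinkage toward the scaled identity,
``(1 - lam) * S + lam * (tr(S)/p) * I``.  ``lam`` defaults to the
Ledoit-Wolf estimate; ``lam = 1`` reduces exactly to a nearest-class-mean
classifier, which the tests use as a closed-form oracle.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.covariance import ledoit_wolf

log = logging.getLogger("memcolor")


def zscore_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize each voxel using training statistics only.

    Returns the normalized train and test arrays plus a boolean flag per
    voxel marking zero-variance (constant) training voxels, which are
    mapped to 0 in both sets rather than dividing by zero.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training samples to z-score")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("z-scoring: %d constant voxel(s) mapped to 0", constant.sum())
    safe_sd = np.where(constant, 1.0, sd)
    train_z = (train - mean) / safe_sd
    test_z = (test - mean) / safe_sd
    train_z[:, constant] = 0.0
    test_z[:, constant] = 0.0
    return train_z, test_z, constant


class ShrinkageLDA:
    """Linear discriminant classifier with equal priors.

    Deterministic: classes are sorted by label and score ties resolve to
    the first (lowest) label.
    """

    def __init__(self, shrinkage: float | str = "auto"):
        if isinstance(shrinkage, str):
            if shrinkage != "auto":
                raise ValueError("shrinkage must be a float in [0, 1] or 'auto'")
        elif not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage must be a float in [0, 1] or 'auto'")
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        n, p = X.shape
        means = np.empty((len(self.classes_), p))
        centered = np.empty_like(X)
        for i, c in enumerate(self.classes_):
            rows = y == c
            if not rows.any():
                raise ValueError(f"class {c!r} has no training samples")
            means[i] = X[rows].mean(axis=0)
            centered[rows] = X[rows] - means[i]
        self.means_ = means

        dof = n - len(self.classes_)
        cov = centered.T @ centered / dof if dof > 0 else np.zeros((p, p))
        if self.shrinkage == "auto":
            if dof > 1 and np.trace(cov) > 0:
                _, lam = ledoit_wolf(centered, assume_centered=True)
            else:
                lam = 1.0
        else:
            lam = float(self.shrinkage)
        self.shrinkage_ = lam
        mu = np.trace(cov) / p
        if mu <= 0:
            mu = 1.0  # degenerate: no within-class scatter at all
        cov_reg = (1.0 - lam) * cov + lam * mu * np.eye(p)
        coef = np.linalg.solve(cov_reg, means.T).T
        self.coef_ = coef
        self.intercept_ = -0.5 * np.einsum("ij,ij->i", coef, means)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
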