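"""Kernel extreme learning machine (KELM).

A single-hidden-layer network whose output weights have the kernel ridge
closed form ``beta = (Omega + I/C)^{-1} T`` with train kernel matrix
``Omega[i, j] = K(x_i, x_j)`` and one-hot targets T; prediction scores a
point by ``K(x, X_train) beta`` and takes the argmax class. The kernel is
a Gaussian RBF parameterized as ``K(u, v) = exp(-||u - v||^2 / gamma^2)``.

Features are z-scored internally with training statistics only. The
default kernel width is sqrt(n_features) (so the squared width matches the
expected squared distance scale of standardized features) and the default
regularization factor is C = 32.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

__all__ = ["rbf_kernel", "KELMClassifier", "kelm_train", "kelm_predict"]

DEFAULT_REG_C = 32.0


def rbf_kernel(X1, X2, gamma: float) -> np.ndarray:
    """K[i, j] = exp(-||x1_i - x2_j||^2 / gamma^2)."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimensions do not match")
    return np.exp(-cdist(X1, X2, "sqeuclidean") / gamma ** 2)


class KELMClassifier(ClassifierMixin, BaseEstimator):
    """Kernel extreme learning machine classifier.

    Parameters
    ----------
    gamma : float or None
        Kernel width; None selects sqrt(n_features) after standardization.
    reg_C : float
        Regularization factor C of the ridge term I/C.

    Attributes
    ----------
    classes_ : ndarray
        Class labels in sorted order; argmax ties resolve to the first.
    beta_ : ndarray of shape (n_train, n_classes)
        Output weights solving (Omega + I/C) beta = T.
    """

    def __init__(self, gamma: float | None = None, reg_C: float = DEFAULT_REG_C):
        self.gamma = gamma
        self.reg_C = reg_C

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.reg_C <= 0:
            raise ValueError(f"reg_C must be positive, got {self.reg_C}")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        self.n_features_in_ = X.shape[1]
        self.feature_means_ = X.mean(axis=0)
        sds = X.std(axis=0)
        self.feature_sds_ = np.where(sds > 0, sds, 1.0)
        Z = (X - self.feature_means_) / self.feature_sds_
        self.gamma_ = float(self.gamma) if self.gamma is not None \
            else float(np.sqrt(X.shape[1]))
        if self.gamma_ <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma_}")
        n = Z.shape[0]
        T = np.zeros((n, len(self.classes_)))
        T[np.arange(n), y_idx] = 1.0
        omega = rbf_kernel(Z, Z, self.gamma_)
        A = omega + np.eye(n) / self.reg_C
        self.beta_ = cho_solve(cho_factor(A, lower=True), T)
        self.X_fit_ = Z
        return self

    def decision_function(self, X):
        check_is_fitted(self, "beta_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Z = (X - self.feature_means_) / self.feature_sds_
        return rbf_kernel(Z, self.X_fit_, self.gamma_) @ self.beta_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def save(self, path) -> None:
        """Serialize the fitted model (weights, kernel, scaling) as JSON."""
        check_is_fitted(self, "beta_")
        payload = {
            "schema_version": 1,
            "gamma": self.gamma, "reg_C": self.reg_C,
            "gamma_": self.gamma_,
            "classes_": np.asarray(self.classes_).tolist(),
            "beta_": self.beta_.tolist(),
            "X_fit_": self.X_fit_.tolist(),
            "feature_means_": self.feature_means_.tolist(),
            "feature_sds_": self.feature_sds_.tolist(),
        }
        import json
        from pathlib import Path
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "KELMClassifier":
        import json
        from pathlib import Path
        d = json.loads(Path(path).read_text())
        model = cls(gamma=d["gamma"], reg_C=d["reg_C"])
        model.gamma_ = d["gamma_"]
        model.classes_ = np.asarray(d["classes_"])
        model.beta_ = np.asarray(d["beta_"], dtype=float)
        model.X_fit_ = np.asarray(d["X_fit_"], dtype=float)
        model.feature_means_ = np.asarray(d["feature_means_"], dtype=float)
        model.feature_sds_ = np.asarray(d["feature_sds_"], dtype=float)
        model.n_features_in_ = model.X_fit_.shape[1]
        return model


def kelm_train(X, y, reg_C: float = DEFAULT_REG_C,
               gamma: float | None = None) -> KELMClassifier:
    """Functional wrapper: fit a :class:`KELMClassifier`."""
    return KELMClassifier(gamma=gamma, reg_C=reg_C).fit(X, y)


def kelm_predict(model: KELMClassifier, X):
    """Functional wrapper: (labels, scores) for fitted model on X."""
    scores = model.decision_function(X)
    return model.classes_[np.argmax(scores, axis=1)], scores
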