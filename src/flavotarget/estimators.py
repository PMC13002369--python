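"""Small scikit-learn-compatible estimators for zoo families that have no
direct scikit-learn equivalent: componentwise logit boosting (glmBoost),
PLS-scores + logistic (plsRglm), and forward-AIC stepwise logistic GLM.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))


class ComponentwiseLogitBoost(BaseEstimator, ClassifierMixin):
    """Gradient boosting for logistic loss with componentwise linear base
    learners: at each step the single (standardized) feature whose least
    squares fit to the current gradient reduces loss most is updated. The
    result is a sparse linear model; ``coef_`` is on the standardized scale.
    """

    def __init__(self, n_steps: int = 100, learning_rate: float = 0.1):
        self.n_steps = n_steps
        self.learning_rate = learning_rate

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        self.classes_ = np.unique(y.astype(int))
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 1e-12, scale, 1.0)
        Xs = (X - self.mean_) / self.scale_
        col_ss = (Xs**2).sum(axis=0)
        col_ss = np.where(col_ss > 1e-12, col_ss, np.inf)

        prev = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        intercept = float(np.log(prev / (1 - prev)))
        coef = np.zeros(d)
        F = np.full(n, intercept)
        for _ in range(int(self.n_steps)):
            r = y - _sigmoid(F)  # negative gradient of the log loss
            c = Xs.T @ r / col_ss
            gain = c**2 * col_ss
            c0 = r.mean()
            if n * c0**2 >= gain.max(initial=0.0):
                intercept += self.learning_rate * c0
                F += self.learning_rate * c0
            else:
                j = int(np.argmax(gain))
                coef[j] += self.learning_rate * c[j]
                F += self.learning_rate * c[j] * Xs[:, j]
        self.coef_ = coef.reshape(1, -1)
        self.intercept_ = np.array([intercept])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        Xs = (np.asarray(X, float) - self.mean_) / self.scale_
        return self.intercept_[0] + Xs @ self.coef_[0]

    def predict_proba(self, X):
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


class PLSLogisticRegression(BaseEstimator, ClassifierMixin):
    """Partial-least-squares score extraction followed by a logistic model
    on the latent components (a pragmatic plsRglm analogue)."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        k = max(1, min(self.n_components, X.shape[1], X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=k, scale=True)
        self.pls_.fit(X, y.astype(float))
        scores = self.pls_.transform(X)
        self.logit_ = LogisticRegression(max_iter=1000)
        self.logit_.fit(scores, y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pls_")
        return self.logit_.predict_proba(self.pls_.transform(np.asarray(X, float)))

    def predict(self, X):
        return self.logit_.predict(self.pls_.transform(np.asarray(X, float)))


class StepwiseLogisticRegression(BaseEstimator, ClassifierMixin):
    """Forward stepwise logistic regression selected by AIC.

    Starts from the intercept-only model and greedily adds the feature that
    lowers AIC = 2k - 2 logL most, stopping when no addition improves AIC or
    ``max_features`` is reached. ``features_`` holds the included column
    indices in inclusion order.
    """

    def __init__(self, max_features: int | None = 8, direction: str = "forward"):
        self.max_features = max_features
        self.direction = direction

    @staticmethod
    def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def _fit_subset(self, X, y, cols):
        if cols:
            lr = LogisticRegression(C=float("inf"), max_iter=2000)
            lr.fit(X[:, cols], y)
            ll = self._log_likelihood(y, lr.predict_proba(X[:, cols])[:, 1])
            return lr, ll
        prev = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        ll = self._log_likelihood(y, np.full(y.shape, prev))
        return None, ll

    def fit(self, X, y):
        if self.direction != "forward":
            raise ValueError("only forward stepwise selection is supported")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        n, d = X.shape
        limit = d if self.max_features is None else min(self.max_features, d)
        included: list[int] = []
        _, ll = self._fit_subset(X, y, included)
        best_aic = 2 * 1 - 2 * ll
        best_model = None
        while len(included) < limit:
            trial_best = None
            for j in range(d):
                if j in included:
                    continue
                model, ll_j = self._fit_subset(X, y, included + [j])
                aic = 2 * (len(included) + 2) - 2 * ll_j
                if trial_best is None or aic < trial_best[0] - 1e-12:
                    trial_best = (aic, j, model)
            if trial_best is None or trial_best[0] >= best_aic - 1e-9:
                break
            best_aic, j, best_model = trial_best
            included.append(j)
        self.features_ = included
        self.model_ = best_model
        self.prevalence_ = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        # full-width coefficient vector (zeros for excluded features)
        coef = np.zeros(d)
        if best_model is not None:
            coef[included] = best_model.coef_[0]
        self.coef_ = coef.reshape(1, -1)
        self.feature_std_ = X.std(axis=0)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "features_")
        X = np.asarray(X, dtype=float)
        if self.model_ is None:
            p = np.full(X.shape[0], self.prevalence_)
        else:
            p = self.model_.predict_proba(X[:, self.features_])[:, 1]
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
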