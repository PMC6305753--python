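"""scikit-learn style estimators for the phylogeny-regularized sparse GLM.

:class:`SICSRegressor` / :class:`SICSClassifier` fit one penalized model at a
fixed (lambda1, lambda2, alpha); :class:`SICSRegressorCV` /
:class:`SICSClassifierCV` tune the triple by k-fold cross-validation.  All
compose with sklearn pipelines and model selection; the module-level
functions in :mod:`phylosparse.solver` and
:mod:`phylosparse.model_selection` do the actual work.

``X`` passed to ``fit``/``predict`` is on the original (normalized,
transformed) abundance scale; standardization is handled internally and the
fitted ``coef_`` is reported on the original scale (``coef_std_`` on the
standardized scale).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import model_selection, phylo, solver

__all__ = [
    "SICSRegressor",
    "SICSClassifier",
    "SICSRegressorCV",
    "SICSClassifierCV",
]


class _BaseSICS(BaseEstimator):
    _family = "linear"

    def __init__(self, lambda1=0.1, lambda2=0.0, alpha=1.0, gamma=None,
                 structure=None, distances=None, tol=1e-4, max_iter=1000):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.alpha = alpha
        self.gamma = gamma
        self.structure = structure
        self.distances = distances
        self.tol = tol
        self.max_iter = max_iter

    def _structure_matrix(self, p: int):
        if self.lambda2 == 0:
            return None
        if self.structure is not None:
            S = np.asarray(self.structure, dtype=float)
            if S.shape != (p, p):
                raise ValueError(
                    f"structure shape {S.shape} does not match p={p}"
                )
            return S
        if self.distances is not None:
            C = phylo.correlation_matrix(self.distances, self.alpha)
            return phylo.inverse_correlation(C, alpha=self.alpha).Omega
        raise ValueError(
            "lambda2 > 0 requires either a structure matrix or a distance "
            "matrix (with alpha)"
        )

    def _fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=self._family == "linear")
        design = solver.standardize(X)
        gamma = self.gamma if self.gamma is not None \
            else solver.GAMMA_DEFAULT[self._family]
        spec = solver.PenaltySpec(
            lambda1=self.lambda1, gamma=gamma, lambda2=self.lambda2,
            structure=self._structure_matrix(X.shape[1]),
        )
        fit = solver.fit(design, y, self._family, spec, tol=self.tol,
                         max_sweeps=self.max_iter)
        self.fit_ = fit
        self.coef_ = fit.beta_orig
        self.coef_std_ = fit.beta_std
        self.intercept_ = fit.intercept_orig
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.n_features_in_ = X.shape[1]
        return self


class SICSRegressor(RegressorMixin, _BaseSICS):
    """Phylogeny-regularized sparse linear regression (MCP + tree penalty).

    Parameters
    ----------
    lambda1 : float
        Sparsity penalty strength.
    lambda2 : float
        Smoothness (quadratic structure) penalty strength.
    alpha : float
        Evolutionary-rate parameter of the phylogeny-induced correlation
        (used only when ``distances`` is given and ``structure`` is not).
    gamma : float, optional
        MCP concavity; defaults to 3 for regression.
    structure : ndarray, optional
        Explicit symmetric PSD penalty matrix (overrides ``distances``).
    distances : PatristicDistanceMatrix or ndarray, optional
        Patristic distances from which the inverse-correlation structure is
        built at ``alpha``.

    Attributes
    ----------
    coef_ : ndarray
        Original-scale coefficients; ``coef_std_`` holds the
        standardized-scale ones.
    """

    _family = "linear"

    def fit(self, X, y):
        return self._fit(X, y)

    def predict(self, X):
        check_is_fitted(self, "fit_")
        X = check_array(X)
        return solver.predict(self.fit_, X)


class SICSClassifier(ClassifierMixin, _BaseSICS):
    """Phylogeny-regularized sparse logistic regression.

    Same parameters as :class:`SICSRegressor`; ``gamma`` defaults to 30.
    """

    _family = "logistic"

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification requires exactly 2 classes")
        y01 = (y == self.classes_[1]).astype(float)
        return self._fit(X, y01)

    def predict_proba(self, X):
        check_is_fitted(self, "fit_")
        X = check_array(X)
        p1 = solver.predict(self.fit_, X)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        check_is_fitted(self, "fit_")
        X = check_array(X)
        p1 = solver.predict(self.fit_, X)
        return np.log(p1 / (1.0 - p1))

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


class _BaseSICSCV(BaseEstimator):
    _family = "linear"

    def __init__(self, distances=None, alpha_values=None, lambda2_values=None,
                 n_lambda1=100, lambda1_min_ratio=None, structure="omega",
                 laplacian_sparsity=0.9, gamma=None, cv=5, random_state=0,
                 tol=1e-4):
        self.distances = distances
        self.alpha_values = alpha_values
        self.lambda2_values = lambda2_values
        self.n_lambda1 = n_lambda1
        self.lambda1_min_ratio = lambda1_min_ratio
        self.structure = structure
        self.laplacian_sparsity = laplacian_sparsity
        self.gamma = gamma
        self.cv = cv
        self.random_state = random_state
        self.tol = tol

    def _grid(self):
        base = model_selection.default_grid(self.n_lambda1,
                                            self.lambda1_min_ratio)
        if self.alpha_values is not None:
            base.alpha_values = np.asarray(self.alpha_values, dtype=float)
        if self.lambda2_values is not None:
            base.lambda2_values = np.asarray(self.lambda2_values, dtype=float)
        return base

    def _fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=self._family == "linear")
        res = model_selection.cross_validate(
            X, y, D=self.distances, family=self._family, grid=self._grid(),
            k=self.cv, seed=self.random_state, gamma=self.gamma,
            structure=self.structure,
            laplacian_sparsity=self.laplacian_sparsity, tol=self.tol,
        )
        self.cv_result_ = res
        self.cv_results_ = res.table
        self.alpha_ = res.best["alpha"]
        self.lambda2_ = res.best["lambda2"]
        self.lambda1_ = res.best["lambda1"]
        self.best_score_ = res.best["criterion"]
        self.fit_ = res.fit
        self.coef_ = res.fit.beta_orig
        self.coef_std_ = res.fit.beta_std
        self.intercept_ = res.fit.intercept_orig
        self.n_features_in_ = X.shape[1]
        return self


class SICSRegressorCV(RegressorMixin, _BaseSICSCV):
    """Cross-validated tuning of (lambda1, lambda2, alpha), linear family.

    ``alpha_values`` / ``lambda2_values`` default to {0} U {2^-5 ... 2^5};
    PMSE is the CV criterion.  After tuning, the final model is refit on all
    samples at the selected triple.
    """

    _family = "linear"

    def fit(self, X, y):
        return self._fit(X, y)

    def predict(self, X):
        check_is_fitted(self, "fit_")
        X = check_array(X)
        return solver.predict(self.fit_, X)


class SICSClassifierCV(ClassifierMixin, _BaseSICSCV):
    """Cross-validated tuning for the logistic family (AUC criterion)."""

    _family = "logistic"

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification requires exactly 2 classes")
        return self._fit(X, (y == self.classes_[1]).astype(float))

    def predict_proba(self, X):
        check_is_fitted(self, "fit_")
        X = check_array(X)
        p1 = solver.predict(self.fit_, X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
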