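"""Gamma GLM with the inverse (canonical) link, as a scikit-learn estimator.

Tweet proportions and cosine similarities are positive, continuous and
right-skewed with roughly constant coefficient of variation, so the model
family is Gamma with variance ``phi * mu^2`` and link ``g(mu) = 1/mu``.
Note the sign reversal the inverse link induces: a *positive* coefficient
on the linear-predictor scale moves ``1/Y`` up, i.e. moves ``Y`` *down*.
Effects are therefore also reported on the response scale downstream.

Fitting is maximum likelihood via iteratively reweighted least squares
(IRLS, delegated to statsmodels), tolerance 1e-8 on the deviance, at most
100 iterations.  The dispersion is the Pearson chi-square estimate and
Wald inference uses the expected information; a cluster-robust covariance
(by group) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import IdentifiabilityError, SupportError

_GAMMA_INVERSE = sm.families.Gamma(link=sm.families.links.InversePower())


@dataclass
class GlmFit:
    """Named-coefficient view of a fitted Gamma/inverse GLM."""

    coefficients: dict[str, float]
    covariance: pd.DataFrame
    dispersion: float
    deviance: float
    n_iterations: int
    converged: bool
    names: list[str] = field(default_factory=list)

    def se(self, name: str) -> float:
        return float(np.sqrt(self.covariance.loc[name, name]))


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    bad: list[str] = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


class GammaInverseGLM(RegressorMixin, BaseEstimator):
    """Gamma-family GLM with inverse link.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend a constant column.  Design matrices that already include a
        constant (as the panel builders do) should pass False.
    tol : float, default 1e-8
        IRLS convergence tolerance.
    max_iter : int, default 100
        IRLS iteration cap.
    cluster : optional column name or array
        If given, report a cluster-robust covariance instead of the
        model-based one.

    Attributes
    ----------
    coef_ : ndarray of slope coefficients (excludes the intercept)
    intercept_ : float (0.0 when fit_intercept=False)
    params_ : full coefficient vector in design order
    cov_ : DataFrame, covariance of ``params_``
    dispersion_ : float, Pearson-based Gamma dispersion estimate
    deviance_ : float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 100, cluster=None):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.cluster = cluster

    # ------------------------------------------------------------------ #

    def _design(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            names = [f"x{j}" for j in range(arr.shape[1])]
        if self.fit_intercept:
            arr = np.column_stack([np.ones(len(arr)), arr])
            names = ["const"] + names
        return arr, names

    def fit(self, X, y):
        arr, names = self._design(X)
        y = np.asarray(y, dtype=float)
        if arr.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if not np.all(np.isfinite(arr)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in X or y")
        if np.any(y <= 0):
            raise SupportError(
                f"{int((y <= 0).sum())} response values are <= 0, outside Gamma support"
            )
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            bad = _collinear_columns(arr, names)
            raise IdentifiabilityError(
                f"design matrix is rank deficient; collinear columns: {bad}"
            )

        if np.ptp(y) == 0.0:
            # constant response: IRLS is degenerate (zero dispersion); the
            # MLE fits the single observed value exactly
            params, *_ = np.linalg.lstsq(arr, np.full(len(y), 1.0 / y[0]), rcond=None)
            self.params_ = params
            self.param_names_ = names
            self.intercept_ = float(params[0]) if self.fit_intercept else 0.0
            self.coef_ = params[1:] if self.fit_intercept else params.copy()
            self.cov_ = pd.DataFrame(np.zeros((len(names), len(names))),
                                     index=names, columns=names)
            self.dispersion_ = 0.0
            self.deviance_ = 0.0
            self.n_iter_ = 0
            self.converged_ = True
            self.n_features_in_ = arr.shape[1] - int(self.fit_intercept)
            self._results = None
            return self

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*InversePower link.*")
            model = sm.GLM(y, arr, family=_GAMMA_INVERSE)
            if self.cluster is not None:
                groups = np.asarray(self.cluster)
                res = model.fit(tol=self.tol, maxiter=self.max_iter,
                                cov_type="cluster", cov_kwds={"groups": groups})
            else:
                res = model.fit(tol=self.tol, maxiter=self.max_iter)

        self.params_ = np.asarray(res.params, dtype=float)
        self.param_names_ = names
        self.intercept_ = float(self.params_[0]) if self.fit_intercept else 0.0
        self.coef_ = self.params_[1:] if self.fit_intercept else self.params_.copy()
        self.cov_ = pd.DataFrame(res.cov_params(), index=names, columns=names)
        self.dispersion_ = float(res.scale)
        self.deviance_ = float(res.deviance)
        self.n_iter_ = int(len(res.fit_history["deviance"]) - 1)
        self.converged_ = bool(res.converged)
        self.n_features_in_ = arr.shape[1] - int(self.fit_intercept)
        self._results = res
        return self

    def linear_predictor(self, X) -> np.ndarray:
        arr, _ = self._design(X)
        return arr @ self.params_

    def predict(self, X) -> np.ndarray:
        """Response-scale mean, mu = 1 / (X beta)."""
        return 1.0 / self.linear_predictor(X)

    def glm_fit(self) -> GlmFit:
        return GlmFit(
            coefficients=dict(zip(self.param_names_, self.params_)),
            covariance=self.cov_,
            dispersion=self.dispersion_,
            deviance=self.deviance_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            names=list(self.param_names_),
        )


def fit_gamma_inverse(design, y, tol: float = 1e-8, max_iter: int = 100) -> GlmFit:
    """Fit ``1/E[y] = X beta`` by IRLS; ``design`` must already contain any
    constant column.  Returns the named-coefficient :class:`GlmFit`."""
    est = GammaInverseGLM(fit_intercept=False, tol=tol, max_iter=max_iter).fit(design, y)
    return est.glm_fit()
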