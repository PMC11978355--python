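"""scikit-learn style estimators over the local linear Poisson machinery.

``LocalLinearPoissonRegressor`` fits one kernel-weighted local linear Poisson
model per training observation (optionally selecting bandwidths by MLCV grid
search first) and predicts by refitting at query points or by evaluating the
nearest stored fit.  ``PoissonGLMRegressor`` is the global log-linear Poisson
baseline fitted with the same Newton-Raphson loop.  Both follow the sklearn
estimator contract (``get_params``/``set_params``, fitted attributes with a
trailing underscore, ``score`` as D-squared, the fraction of Poisson deviance
explained) and compose with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import bandwidth as _bandwidth
from . import fitting as _fitting
from .kernels import KernelSpec
from .likelihood import CountDataset
from .model import (
    LocalLinearPoissonModel,
    fitted_means,
    in_sample_loglik,
    poisson_deviance,
    predict_model,
)

__all__ = ["LocalLinearPoissonRegressor", "PoissonGLMRegressor"]


def _d_squared(y, mu) -> float:
    y = np.asarray(y, dtype=float)
    null = poisson_deviance(y, np.full_like(y, y.mean()))
    dev = poisson_deviance(y, mu)
    return 1.0 - dev / null if null > 0 else 0.0


def _check_count_y(X, y):
    X, y = check_X_y(X, y, y_numeric=True)
    return X, y


class PoissonGLMRegressor(RegressorMixin, BaseEstimator):
    """Global Poisson GLM with log link, fitted by safeguarded Newton-Raphson.

    Parameters
    ----------
    epsilon : float, default=1e-6
        Stop when the L2 norm of the parameter change is at most this.
    max_iter : int, default=100
    safeguard : bool, default=True
        Step-halving on likelihood decrease or overflow.
    ridge : float, default=1e-10
        Relative diagonal stabilizer for near-singular curvature.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (p,)
    loglik_ : float
    n_iter_ : int
    converged_ : bool
    fisher_ : ndarray of shape (p + 1, p + 1)
    """

    def __init__(self, epsilon: float = 1e-6, max_iter: int = 100, safeguard: bool = True, ridge: float = 1e-10):
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.safeguard = safeguard
        self.ridge = ridge

    def _options(self) -> _fitting.FitOptions:
        return _fitting.FitOptions(
            epsilon=self.epsilon, max_iter=self.max_iter, safeguard=self.safeguard, ridge=self.ridge
        )

    def fit(self, X, y):
        X, y = _check_count_y(X, y)
        data = CountDataset(y=y, X=X)
        res = _fitting.fit_global(data, self._options())
        self.intercept_ = float(res.beta[0])
        self.coef_ = res.beta[1:].copy()
        self.loglik_ = res.loglik
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.fisher_ = res.fisher
        self.global_fit_ = res
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return np.exp(self.intercept_ + X @ self.coef_)

    def score(self, X, y, sample_weight=None):
        """D-squared: fraction of Poisson deviance explained."""
        return _d_squared(y, self.predict(X))


class LocalLinearPoissonRegressor(RegressorMixin, BaseEstimator):
    """Local linear multi-predictor Poisson regression.

    At every training observation the log-mean is approximated by a
    first-order expansion and estimated by maximizing the kernel-weighted
    Poisson likelihood; per-predictor bandwidths are either given or selected
    by leave-one-out maximum likelihood cross-validation on a grid.

    Parameters
    ----------
    bandwidths : array-like of shape (p,) or None, default=None
        Fixed per-predictor bandwidths.  ``None`` requires ``bandwidth_grid``.
    bandwidth_grid : list or None, default=None
        Per-predictor 1-D grids (``selection_mode="per_predictor"``) or a
        list of candidate vectors (``"joint"``).
    selection_mode : {"per_predictor", "joint"}, default="per_predictor"
    kernel : {"gaussian", "epanechnikov"}, default="gaussian"
    strategy : {"refit", "nearest_fit"}, default="refit"
        ``predict`` refits at each query point, or evaluates the stored fit
        with the nearest anchor (bandwidth-scaled distance).
    fit_global_baseline : bool, default=True
        Also fit the global Poisson GLM for comparison.
    epsilon, max_iter, safeguard, ridge :
        Newton-Raphson controls, as in :class:`PoissonGLMRegressor`.

    Attributes
    ----------
    bandwidths_ : ndarray of shape (p,)
        Bandwidths actually used.
    fits_ : list of LocalFit
        One local fit per training observation.
    model_ : LocalLinearPoissonModel
    global_ : GlobalFit or None
    mlcv_result_ : MLCVResult or None
        Present when bandwidths were selected from a grid.

    Examples
    --------
    >>> from locpois.synthetic import SimulationScenario, simulate
    >>> data, truth = simulate(SimulationScenario(n=60, seed=5))
    >>> reg = LocalLinearPoissonRegressor(bandwidths=[0.6, 0.6]).fit(data.X, data.y)
    >>> reg.predict(data.X[:2]).shape
    (2,)
    """

    def __init__(
        self,
        bandwidths=None,
        bandwidth_grid=None,
        selection_mode: str = "per_predictor",
        kernel: str = "gaussian",
        strategy: str = "refit",
        fit_global_baseline: bool = True,
        epsilon: float = 1e-6,
        max_iter: int = 100,
        safeguard: bool = True,
        ridge: float = 1e-10,
    ):
        self.bandwidths = bandwidths
        self.bandwidth_grid = bandwidth_grid
        self.selection_mode = selection_mode
        self.kernel = kernel
        self.strategy = strategy
        self.fit_global_baseline = fit_global_baseline
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.safeguard = safeguard
        self.ridge = ridge

    def _options(self) -> _fitting.FitOptions:
        return _fitting.FitOptions(
            epsilon=self.epsilon, max_iter=self.max_iter, safeguard=self.safeguard, ridge=self.ridge
        )

    def fit(self, X, y):
        X, y = _check_count_y(X, y)
        data = CountDataset(y=y, X=X)
        opts = self._options()
        self.mlcv_result_ = None
        if self.bandwidths is not None:
            h = np.atleast_1d(np.asarray(self.bandwidths, dtype=float))
        elif self.bandwidth_grid is not None:
            result = _bandwidth.select_bandwidth(
                data, self.bandwidth_grid, opts, mode=self.selection_mode, family=self.kernel
            )
            self.mlcv_result_ = result
            h = result.best
        else:
            raise ValueError("either bandwidths or bandwidth_grid must be given")
        spec = KernelSpec(family=self.kernel, bandwidths=h)
        fits = _fitting.fit_at_observations(data, spec, opts)
        global_fit = _fitting.fit_global(data, opts) if self.fit_global_baseline else None
        self.model_ = LocalLinearPoissonModel(
            data=data, spec=spec, fits=fits, options=opts, global_fit=global_fit
        )
        self.bandwidths_ = h
        self.fits_ = fits
        self.global_ = global_fit
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return predict_model(self.model_, X, strategy=self.strategy)

    def fitted_means(self) -> np.ndarray:
        """In-sample fitted means ``exp(beta0_i)`` at the training points."""
        check_is_fitted(self, "model_")
        return fitted_means(self.model_)

    def comparison_loglik(self) -> dict:
        """In-sample Poisson log-likelihood of the local model and the baseline."""
        check_is_fitted(self, "model_")
        out = {"local": in_sample_loglik(self.model_, "local")}
        if self.model_.global_fit is not None:
            out["global"] = in_sample_loglik(self.model_, "global")
        return out

    def score(self, X, y, sample_weight=None):
        """D-squared: fraction of Poisson deviance explained by predictions."""
        return _d_squared(y, self.predict(X))
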