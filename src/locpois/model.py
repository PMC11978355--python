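"""Assembled local linear Poisson models: evaluation, prediction, comparison.

A fitted model is the collection of per-observation local fits plus the
training data, kernel specification and fit options, optionally with the
global (parametric) Poisson GLM baseline alongside.  The local mean estimate
at a query point x from the fit anchored at x0 is

    mhat(x) = exp( beta0 + sum_j beta1j (x_j - x0_j) ),

valid inside the window ``x0_j +/- h_j``; evaluation outside the window emits
a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .errors import DegenerateNeighborhoodError, FitError, OutOfWindowWarning
from .fitting import FitOptions, GlobalFit, LocalFit, fit_local
from .kernels import KernelSpec
from .likelihood import CountDataset

__all__ = [
    "LocalLinearPoissonModel",
    "evaluate_local_model",
    "predict_model",
    "fitted_means",
    "in_sample_loglik",
    "poisson_deviance",
]


@dataclass(frozen=True)
class LocalLinearPoissonModel:
    """All local fits at the observation points plus training context."""

    data: CountDataset
    spec: KernelSpec
    fits: list
    options: FitOptions
    global_fit: GlobalFit | None = None

    def __post_init__(self):
        if len(self.fits) != self.data.n:
            raise ValueError(
                f"{len(self.fits)} fits for {self.data.n} observations; must be one-to-one"
            )
        for fit in self.fits:
            half = 0.5 * (fit.window[:, 1] - fit.window[:, 0])
            if not np.allclose(half, self.spec.bandwidths):
                raise ValueError("fit window half-widths do not match spec bandwidths")

    @property
    def n_converged(self) -> int:
        return sum(f.converged for f in self.fits)


def evaluate_local_model(fit: LocalFit, x, round_mode: str = "none") -> float:
    """Mean estimate from one stored local fit at a query point.

    Parameters
    ----------
    fit : LocalFit
        A converged local fit.
    x : array-like of shape (p,)
        Query point on the raw predictor scale.
    round_mode : {"none", "nearest"}
        ``"nearest"`` rounds the mean to the nearest integer count.

    Warns
    -----
    OutOfWindowWarning
        When the query lies outside the fit's validity window.
    """
    if not fit.converged:
        raise FitError("cannot evaluate a non-converged local fit")
    if round_mode not in ("none", "nearest"):
        raise ValueError(f"round_mode must be 'none' or 'nearest', got {round_mode!r}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    beta = fit.beta.beta
    eta = float(beta[0] + beta[1:] @ (x - fit.x0))
    if np.any(x < fit.window[:, 0]) or np.any(x > fit.window[:, 1]):
        warnings.warn(
            f"query point {x.tolist()} lies outside the validity window of the "
            f"local fit at x0={fit.x0.tolist()}",
            OutOfWindowWarning,
            stacklevel=2,
        )
    mean = float(np.exp(eta))
    return float(np.rint(mean)) if round_mode == "nearest" else mean


def predict_model(
    model: LocalLinearPoissonModel, Xnew, strategy: str = "refit"
) -> np.ndarray:
    """Predicted Poisson means at query points.

    ``strategy="refit"`` fits a fresh local model at each query point using
    the training data (statistically correct for arbitrary points);
    ``strategy="nearest_fit"`` evaluates the stored fit whose anchor x0 is
    closest in bandwidth-scaled Euclidean distance (ties to the lowest point
    index).  Refit failures yield NaN entries; the batch continues.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.data.p:
        raise ValueError(f"expected {model.data.p} predictor columns, got {Xnew.shape[1]}")
    out = np.empty(Xnew.shape[0])
    if strategy == "refit":
        for k, x in enumerate(Xnew):
            try:
                fit = fit_local(model.data, x, model.spec, model.options)
                out[k] = np.exp(fit.beta.beta[0])
            except (DegenerateNeighborhoodError, FitError) as exc:
                warnings.warn(f"refit failed at query row {k}: {exc}", stacklevel=2)
                out[k] = np.nan
    elif strategy == "nearest_fit":
        anchors = np.stack([f.x0 for f in model.fits])
        h = model.spec.bandwidths
        for k, x in enumerate(Xnew):
            d = np.sum(((anchors - x) / h) ** 2, axis=1)
            i = int(np.argmin(d))  # argmin takes the lowest index on ties
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OutOfWindowWarning)
                out[k] = evaluate_local_model(model.fits[i], x)
    else:
        raise ValueError(f"strategy must be 'refit' or 'nearest_fit', got {strategy!r}")
    return out


def fitted_means(model: LocalLinearPoissonModel) -> np.ndarray:
    """In-sample fitted means: ``exp(beta0)`` of the fit anchored at each row."""
    return np.array([np.exp(f.beta.beta[0]) for f in model.fits])


def in_sample_loglik(model: LocalLinearPoissonModel, which: str = "local") -> float:
    """Summed Poisson log-density of y at the fitted means.

    Reported for both the local model and the global baseline so the two can
    be compared in the same format.
    """
    if which == "local":
        mu = fitted_means(model)
    elif which == "global":
        if model.global_fit is None:
            raise ValueError("model carries no global baseline fit")
        mu = model.global_fit.mean(model.data.X)
    else:
        raise ValueError(f"which must be 'local' or 'global', got {which!r}")
    return float(np.sum(poisson.logpmf(model.data.y, mu)))


def poisson_deviance(y, mu) -> float:
    """Poisson deviance ``2 sum[ y ln(y/mu) - (y - mu) ]`` (y ln y term 0 at y=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))
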