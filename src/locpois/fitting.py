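"""Newton-Raphson maximization of the local and global Poisson likelihood.

The update is ``beta^(m+1) = beta^(m) - H^-1 g``; iteration stops when the
norm of the parameter change drops to ``epsilon`` or below.  Initialization is
ordinary least squares of the raw counts on the raw predictors, re-expressed
in the coordinates centered at x0; because OLS works on the count scale the
initial linear predictor can sit far above the log-scale optimum, so a
step-halving safeguard (on by default) rejects steps that decrease the
likelihood or overflow ``exp(eta)``, and a log-mean fallback initializer takes
over when the OLS start is unusable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateNeighborhoodError, FitError, InitializationError
from .kernels import KernelSpec
from .likelihood import (
    CountDataset,
    LocalDesign,
    LocalParams,
    build_local_design,
    fisher_information,
    local_hessian,
    local_loglik,
    local_score,
)

__all__ = [
    "FitOptions",
    "LocalFit",
    "GlobalFit",
    "ols_init",
    "fallback_init",
    "newton_raphson",
    "fit_local",
    "fit_at_observations",
    "fit_global",
    "dispersion_check",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)

_MAX_HALVINGS = 30
# slack for "non-decreasing" likelihood comparisons near machine precision
_LL_SLACK = 1e-9


@dataclass(frozen=True)
class FitOptions:
    """Newton-Raphson controls.

    Attributes
    ----------
    epsilon : float
        Convergence threshold on the L2 norm of the parameter change.
    max_iter : int
        Maximum Newton iterations.
    safeguard : bool
        Step-halving when the likelihood decreases or ``exp(eta)`` overflows.
        The plain textbook update is recovered with ``safeguard=False``.
    ridge : float
        Relative ridge added to the diagonal of ``-H`` before solving,
        stabilizing near-singular curvature; 0 disables it.
    """

    epsilon: float = 1e-6
    max_iter: int = 100
    safeguard: bool = True
    ridge: float = 1e-10

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.ridge < 0:
            raise ValueError(f"ridge must be >= 0, got {self.ridge}")


@dataclass(frozen=True)
class LocalFit:
    """A converged (or flagged) local fit at one evaluation point.

    ``window`` is the per-predictor validity interval ``(x0_j - h_j, x0_j + h_j)``
    inside which the first-order expansion is considered applicable.
    """

    x0: np.ndarray
    beta: LocalParams
    converged: bool
    n_iter: int
    loglik: float
    fisher: np.ndarray
    window: np.ndarray
    effective_weight: float
    score_norm: float = np.nan
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.converged and np.all(np.isfinite(self.beta.beta))


@dataclass(frozen=True)
class GlobalFit:
    """The global (parametric) Poisson GLM fit on the uncentered design."""

    beta: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    fisher: np.ndarray
    score_norm: float = np.nan

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.beta[0] + X @ self.beta[1:]

    def mean(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.linear_predictor(X))


def ols_init(data: CountDataset, x0) -> LocalParams:
    """OLS of the raw counts on the raw predictors, re-centered at ``x0``.

    The raw fit ``(b0, b1, ..., bp)`` becomes the centered start
    ``(b0 + sum_j b_j x0_j, b1, ..., bp)``: slopes are unchanged and the
    centered intercept is the raw fitted value at x0.

    Raises
    ------
    InitializationError
        If the raw design (intercept plus predictors) is rank deficient;
        use :func:`fallback_init` instead.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    Xs = np.column_stack([np.ones(data.n), data.X])
    b, _, rank, _ = np.linalg.lstsq(Xs, data.y.astype(float), rcond=None)
    if rank < Xs.shape[1]:
        raise InitializationError(
            "raw design is rank deficient; OLS initialization is undefined "
            "(use the fallback log-mean initializer)"
        )
    beta = b.copy()
    beta[0] = b[0] + b[1:] @ x0
    return LocalParams(beta=beta, x0=x0)


def fallback_init(design: LocalDesign) -> LocalParams:
    """Log weighted-mean start: ``beta = (ln(max(ybar_w, 1)), 0, ..., 0)``."""
    sw = design.w.sum()
    ybar = float(design.w @ design.y / sw) if sw > 0 else float(np.mean(design.y))
    beta = np.zeros(design.p + 1)
    beta[0] = np.log(max(ybar, 1.0))
    return LocalParams(beta=beta, x0=design.x0)


def _solve_step(H: np.ndarray, g: np.ndarray, ridge: float) -> np.ndarray:
    A = -H
    if ridge > 0:
        A = A + np.eye(A.shape[0]) * (ridge * np.trace(A) / A.shape[0])
    try:
        return np.linalg.solve(A, g)
    except np.linalg.LinAlgError:
        raise FitError("singular curvature matrix even after ridge regularization") from None


def newton_raphson(design: LocalDesign, init: LocalParams, opts: FitOptions | None = None) -> LocalFit:
    """Maximize the weighted local log-likelihood by Newton-Raphson.

    Stops at the first iteration whose accepted parameter change has L2 norm
    at most ``opts.epsilon``; a fit that exhausts ``max_iter`` is returned with
    ``converged=False``.  With the safeguard on, the log-likelihood is
    non-decreasing across accepted steps.
    """
    opts = opts or FitOptions()
    beta = np.array(init.beta, dtype=float)
    params = LocalParams(beta=beta, x0=design.x0)
    ll = local_loglik(design, params)
    if not np.isfinite(ll):
        raise FitError(
            "initial parameters give a non-finite local log-likelihood; "
            "use a different initializer"
        )
    converged = False
    n_iter = 0
    message = ""
    for m in range(opts.max_iter):
        g = local_score(design, params)
        H = local_hessian(design, params)
        step = _solve_step(H, g, opts.ridge)
        t = 1.0
        accepted = False
        if opts.safeguard:
            for _ in range(_MAX_HALVINGS):
                cand = LocalParams(beta=beta + t * step, x0=design.x0)
                llc = local_loglik(design, cand)
                if np.isfinite(llc) and llc >= ll - _LL_SLACK * max(1.0, abs(ll)):
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                message = "step-halving exhausted without an acceptable step"
                break
        else:
            cand = LocalParams(beta=beta + step, x0=design.x0)
            llc = local_loglik(design, cand)
            if not np.isfinite(llc):
                message = "divergence: exp(eta) overflowed with safeguard off"
                break
        delta = float(np.linalg.norm(t * step))
        beta = cand.beta
        params = cand
        ll = llc
        n_iter = m + 1
        if delta <= opts.epsilon:
            converged = True
            break
    else:
        message = f"max_iter={opts.max_iter} reached without convergence"
    score_norm = float(np.max(np.abs(local_score(design, params)))) if np.all(np.isfinite(beta)) else np.inf
    return LocalFit(
        x0=design.x0,
        beta=params,
        converged=converged,
        n_iter=n_iter,
        loglik=ll,
        fisher=fisher_information(design, params),
        window=np.column_stack([design.x0, design.x0]),  # placeholder; fit_local sets real window
        effective_weight=float(design.w.sum()),
        score_norm=score_norm,
        message=message,
    )


def _initial_params(data: CountDataset, design: LocalDesign) -> LocalParams:
    # OLS works on the count scale, so for large counts its linear predictor can
    # sit far above the log-scale optimum (exp(eta) astronomically large); start
    # from whichever of the OLS and log-mean candidates has the higher likelihood
    fallback = fallback_init(design)
    try:
        ols = ols_init(data, design.x0)
    except InitializationError:
        return fallback
    ll_ols = local_loglik(design, ols)
    ll_fb = local_loglik(design, fallback)
    if not np.isfinite(ll_ols):
        return fallback
    return ols if ll_ols >= ll_fb else fallback


def fit_local(data: CountDataset, x0, spec: KernelSpec, opts: FitOptions | None = None) -> LocalFit:
    """Fit the local linear Poisson model at one evaluation point.

    Composes design construction, OLS (or fallback) initialization and
    Newton-Raphson, and records the validity window ``x0_j +/- h_j``.
    """
    opts = opts or FitOptions()
    design = build_local_design(data, x0, spec)
    w = design.w
    if w.sum() < 1e-2 * w.max() * design.n:
        raise DegenerateNeighborhoodError(
            f"effective sample at x0={design.x0.tolist()} is negligible "
            f"(sum of weights {w.sum():.3g} vs max weight {w.max():.3g} over n={design.n})"
        )
    init = _initial_params(data, design)
    fit = newton_raphson(design, init, opts)
    window = np.column_stack(
        [design.x0 - spec.bandwidths, design.x0 + spec.bandwidths]
    )
    return replace(fit, window=window)


def fit_at_observations(
    data: CountDataset, spec: KernelSpec, opts: FitOptions | None = None
) -> list[LocalFit]:
    """One local fit per observation row (x0 = each observed predictor vector).

    Per-point failures are collected as flagged ``LocalFit`` entries with NaN
    coefficients rather than aborting the batch.
    """
    opts = opts or FitOptions()
    fits: list[LocalFit] = []
    for i in range(data.n):
        x0 = data.X[i]
        try:
            fits.append(fit_local(data, x0, spec, opts))
        except (DegenerateNeighborhoodError, FitError) as exc:
            logger.warning("local fit failed at observation %d: %s", i, exc)
            nanbeta = LocalParams(beta=np.full(data.p + 1, np.nan), x0=np.asarray(x0, float))
            fits.append(
                LocalFit(
                    x0=np.asarray(x0, dtype=float),
                    beta=nanbeta,
                    converged=False,
                    n_iter=0,
                    loglik=np.nan,
                    fisher=np.full((data.p + 1, data.p + 1), np.nan),
                    window=np.column_stack(
                        [x0 - spec.bandwidths, x0 + spec.bandwidths]
                    ),
                    effective_weight=0.0,
                    message=str(exc),
                )
            )
    return fits


def fit_global(data: CountDataset, opts: FitOptions | None = None) -> GlobalFit:
    """Poisson GLM on the uncentered design with unit weights.

    Same Newton-Raphson machinery and stopping rule as the local fits;
    equivalent to a local fit with constant weights centered at the origin.
    """
    opts = opts or FitOptions()
    design = LocalDesign(
        Xc=np.column_stack([np.ones(data.n), data.X]),
        w=np.ones(data.n),
        y=data.y,
        x0=np.zeros(data.p),
    )
    init = _initial_params(data, design)
    fit = newton_raphson(design, init, opts)
    return GlobalFit(
        beta=fit.beta.beta,
        converged=fit.converged,
        n_iter=fit.n_iter,
        loglik=fit.loglik,
        fisher=fit.fisher,
        score_norm=fit.score_norm,
    )


def dispersion_check(data: CountDataset):
    """Variance-to-mean ratio of the counts plus a descriptive table.

    Under equidispersion (the Poisson assumption) the ratio is near one.
    Returns ``(ratio, table)`` where the table has one row per column with
    mean, min, max and sample (n-1 denominator) standard deviation.
    """
    from .io import describe  # local import to avoid a cycle

    mean = float(np.mean(data.y))
    var = float(np.var(data.y, ddof=1))
    ratio = var / mean if mean > 0 else np.nan
    return ratio, describe(data)


def fits_to_frame(fits: list[LocalFit]):
    """Coefficient table, one row per evaluation point (Table-style layout)."""
    import pandas as pd

    rows = []
    for k, fit in enumerate(fits):
        p = fit.x0.size
        row = {"point_id": k}
        for j in range(p):
            row[f"x0_{j + 1}"] = fit.x0[j]
        row["beta0"] = fit.beta.beta[0]
        for j in range(p):
            row[f"beta{j + 1}"] = fit.beta.beta[j + 1]
        row["converged"] = fit.converged
        row["n_iter"] = fit.n_iter
        row["loglik"] = fit.loglik
        rows.append(row)
    return pd.DataFrame(rows)
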