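"""Local linear design construction and the kernel-weighted Poisson likelihood.

At an evaluation point ``x0`` the unknown log-mean ``m(x)`` is replaced by its
first-order Taylor expansion

    m(x_i) ~= beta_0(x0) + sum_j beta_1j(x0) (x_ij - x0_j),

so the centered design row is ``[1, x_i1 - x0_1, ..., x_ip - x0_p]`` and the
parameter vector has length p + 1 (one intercept; per-predictor intercepts are
not identifiable, only their sum enters the linear predictor).  The local
log-likelihood weights each observation's Poisson log-density by its product
kernel weight:

    l(beta; x0) = sum_i w_i [ y_i eta_i - exp(eta_i) - ln(y_i!) ],

with ``eta_i`` the centered linear predictor.  Analytic derivatives:

    score   g = Xc' W (y - mu),        mu = exp(eta), W = diag(w)
    Hessian H = -Xc' diag(w mu) Xc
    Fisher  I = -H

The kernel weights enter the curvature matrix: Newton-Raphson on (g, H) then
solves exactly the weighted score equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import DataValidationError, DegenerateNeighborhoodError
from .kernels import KernelSpec, product_kernel_weights

__all__ = [
    "CountDataset",
    "LocalDesign",
    "LocalParams",
    "build_local_design",
    "linear_predictor",
    "local_loglik",
    "local_score",
    "local_hessian",
    "fisher_information",
]

# exp(eta) overflows double precision just above this; treated as divergence
_ETA_MAX = 700.0


@dataclass(frozen=True)
class CountDataset:
    """A count response paired with numeric predictors.

    Attributes
    ----------
    y : ndarray of shape (n,)
        Non-negative integer counts.
    X : ndarray of shape (n, p)
        Real predictor matrix, no missing values.
    names : tuple of str
        Predictor labels, length p.
    """

    y: np.ndarray
    X: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        y = np.atleast_1d(np.asarray(self.y))
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.ndim != 1 or X.ndim != 2 or y.size != X.shape[0]:
            raise DataValidationError(
                f"shape mismatch: y has {y.size} rows, X has shape {X.shape}"
            )
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise DataValidationError("missing or non-finite values are not allowed")
        yf = y.astype(float)
        if np.any(yf < 0) or np.any(yf != np.rint(yf)):
            bad = int(np.flatnonzero((yf < 0) | (yf != np.rint(yf)))[0])
            raise DataValidationError(
                f"response must be non-negative integers; row {bad} has value {y[bad]!r}"
            )
        n, p = X.shape
        if n <= p + 1:
            raise DataValidationError(f"need n > p + 1 rows, got n={n}, p={p}")
        names = tuple(self.names) if self.names else tuple(f"x{j + 1}" for j in range(p))
        if len(names) != p:
            raise DataValidationError(f"got {len(names)} names for {p} predictors")
        object.__setattr__(self, "y", y.astype(np.int64))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def drop_row(self, i: int) -> "CountDataset":
        """Return a copy with row ``i`` removed (leave-one-out helper)."""
        keep = np.arange(self.n) != i
        return CountDataset(self.y[keep], self.X[keep], self.names)


@dataclass(frozen=True)
class LocalDesign:
    """Centered design, kernel weights, and counts at one evaluation point.

    ``Xc`` has a leading all-ones column followed by the centered predictor
    columns ``x_ij - x0_j``.
    """

    Xc: np.ndarray
    w: np.ndarray
    y: np.ndarray
    x0: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.Xc.shape[1] - 1


@dataclass(frozen=True)
class LocalParams:
    """Local parameter vector ``(beta_0(x0), beta_11(x0), ..., beta_1p(x0))``.

    ``beta[0]`` is the log-mean at ``x0`` itself; ``beta[1 + j]`` estimates the
    partial derivative of the log-mean with respect to predictor j at ``x0``.
    """

    beta: np.ndarray
    x0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "x0", x0)


def build_local_design(data: CountDataset, x0, spec: KernelSpec) -> LocalDesign:
    """Centered local design and product-kernel weights at ``x0``.

    Raises
    ------
    DegenerateNeighborhoodError
        If every kernel weight is numerically zero (compact kernel, empty
        window around ``x0``).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    w = product_kernel_weights(data.X, x0, spec)
    if not np.any(w > 0):
        raise DegenerateNeighborhoodError(
            f"all kernel weights vanish at x0={x0.tolist()}; "
            "no observation falls in the kernel support"
        )
    Xc = np.column_stack([np.ones(data.n), data.X - x0])
    return LocalDesign(Xc=Xc, w=w, y=data.y, x0=x0)


def linear_predictor(design: LocalDesign, params: LocalParams) -> np.ndarray:
    """Centered linear predictor ``eta_i = Xc_i . beta``."""
    return design.Xc @ params.beta


def local_loglik(design: LocalDesign, params: LocalParams) -> float:
    """Kernel-weighted Poisson log-likelihood.

    Returns ``-inf`` when ``exp(eta)`` overflows, signalling divergence to the
    fitter's safeguard.  ``ln(y!)`` is computed via the log-gamma function.
    """
    eta = linear_predictor(design, params)
    active = design.w > 0
    if np.any(eta[active] > _ETA_MAX):
        return -np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        terms = design.y * eta - np.exp(eta) - gammaln(design.y + 1.0)
        val = float(np.sum(design.w * terms))
    return val if np.isfinite(val) else -np.inf


def local_score(design: LocalDesign, params: LocalParams) -> np.ndarray:
    """Gradient of the weighted log-likelihood: ``Xc' W (y - exp(eta))``."""
    eta = linear_predictor(design, params)
    return design.Xc.T @ (design.w * (design.y - np.exp(eta)))


def local_hessian(design: LocalDesign, params: LocalParams) -> np.ndarray:
    """Hessian ``-Xc' V Xc`` with ``V = diag(w_i exp(eta_i))``.

    Symmetric negative semidefinite; negative definite whenever ``Xc`` has
    full column rank under the positive weights.
    """
    eta = linear_predictor(design, params)
    v = design.w * np.exp(eta)
    return -(design.Xc * v[:, None]).T @ design.Xc


def fisher_information(design: LocalDesign, params: LocalParams) -> np.ndarray:
    """Fisher information ``I = -H = Xc' V Xc`` (positive semidefinite)."""
    return -local_hessian(design, params)
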