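"""Symmetric density kernels and product-kernel observation weights.

A kernel ``K`` is a symmetric probability density; the scaled kernel is the
density convention ``K_h(t) = K(t/h) / h`` with bandwidth ``h > 0``.  For a
multi-predictor problem the weight attached to observation ``x_i`` relative to
an evaluation point ``x0`` is the product kernel

    w_i = prod_j K_{h_j}(x_ij - x0_j),

one univariate factor per predictor, each with its own bandwidth.  Weight
*ratios* drive local likelihood estimation; no renormalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "KERNEL_FAMILIES",
    "KernelSpec",
    "kernel_density",
    "scaled_kernel",
    "product_kernel_weights",
]

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gaussian(u: np.ndarray) -> np.ndarray:
    return _INV_SQRT_2PI * np.exp(-0.5 * np.square(u))


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - np.square(u)), 0.0)


_KERNELS = {"gaussian": _gaussian, "epanechnikov": _epanechnikov}

#: Supported kernel family names.
KERNEL_FAMILIES = tuple(sorted(_KERNELS))


def kernel_density(family: str, u):
    """Evaluate the kernel density ``K(u)``.

    Parameters
    ----------
    family : str
        One of :data:`KERNEL_FAMILIES`.
    u : float or array-like
        Point(s) at which to evaluate the density.

    Returns
    -------
    float or ndarray
        ``K(u) >= 0``, symmetric about zero, integrating to one.
    """
    try:
        fn = _KERNELS[family]
    except KeyError:
        raise ConfigurationError(
            f"unknown kernel family {family!r}; choose one of {KERNEL_FAMILIES}"
        ) from None
    out = fn(np.asarray(u, dtype=float))
    return float(out) if np.isscalar(u) or np.ndim(u) == 0 else out


def scaled_kernel(family: str, h: float, t):
    """Bandwidth-scaled kernel ``K_h(t) = K(t/h) / h``.

    Raises
    ------
    ValueError
        If ``h <= 0``.
    """
    if not h > 0:
        raise ValueError(f"bandwidth must be positive, got h={h}")
    return kernel_density(family, np.asarray(t, dtype=float) / h) / h


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus one positive bandwidth per predictor.

    Attributes
    ----------
    family : str
        Kernel family name (``"gaussian"`` by default; the always-positive
        Gaussian weights keep the local likelihood well defined at any x0).
    bandwidths : ndarray of shape (p,)
        Per-predictor bandwidths ``h_j > 0``, in the units of each predictor.
    """

    family: str = "gaussian"
    bandwidths: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        if self.family not in _KERNELS:
            raise ConfigurationError(
                f"unknown kernel family {self.family!r}; choose one of {KERNEL_FAMILIES}"
            )
        h = np.atleast_1d(np.asarray(self.bandwidths, dtype=float))
        if h.ndim != 1 or h.size == 0:
            raise ConfigurationError("bandwidths must be a non-empty 1-D vector")
        if not np.all(h > 0):
            raise ConfigurationError(f"all bandwidths must be positive, got {h}")
        object.__setattr__(self, "bandwidths", h)

    @property
    def p(self) -> int:
        return self.bandwidths.size


def product_kernel_weights(X: np.ndarray, x0: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Product-kernel weights of each row of ``X`` around ``x0``.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Predictor matrix.
    x0 : ndarray of shape (p,)
        Evaluation point.
    spec : KernelSpec
        Kernel family and the p bandwidths.

    Returns
    -------
    ndarray of shape (n,)
        ``w_i = prod_j K_{h_j}(x_ij - x0_j) >= 0``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if X.shape[1] != x0.size or x0.size != spec.p:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, x0 has {x0.size}, "
            f"spec has {spec.p} bandwidths"
        )
    w = np.ones(X.shape[0])
    for j in range(x0.size):
        w *= scaled_kernel(spec.family, spec.bandwidths[j], X[:, j] - x0[j])
    return w
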