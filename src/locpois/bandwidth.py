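"""Bandwidth selection by leave-one-out maximum likelihood cross-validation.

For a candidate bandwidth vector h the criterion is the leave-one-out
predictive log-likelihood

    MLCV(h) = sum_i [ mhat_{-i}(x_i) y_i - exp(mhat_{-i}(x_i)) - ln(y_i!) ],

where ``mhat_{-i}(x_i)`` is the centered intercept of the local fit at
``x0 = x_i`` computed on the dataset with row i deleted — the only value the
local parameterization defines at x0 itself.  The bandwidth maximizing MLCV
over a grid is selected.  Leave-one-out fits that fail (degenerate
neighbourhoods under compact kernels at small h, non-convergence) are dropped
from the sum with a recorded count; a grid point with more than 20% failures
is marked invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import DegenerateNeighborhoodError, FitError, SelectionError
from .fitting import FitOptions, fit_local
from .kernels import KernelSpec
from .likelihood import CountDataset

__all__ = ["MLCVResult", "loo_estimate", "mlcv", "select_bandwidth"]

logger = logging.getLogger(__name__)

#: fraction of failed leave-one-out fits above which a grid point is invalid
MAX_FAILURE_FRACTION = 0.2


@dataclass(frozen=True)
class MLCVResult:
    """Grid of evaluated bandwidth vectors, their MLCV values, and the argmax.

    ``best`` attains the maximum MLCV among valid grid points with the fewest
    leave-one-out failures; ties break to the first occurrence in grid order.
    """

    grid: list
    mlcv: np.ndarray
    n_failed: np.ndarray
    valid: np.ndarray
    best: np.ndarray
    best_mlcv: float

    def to_frame(self):
        import pandas as pd

        p = len(self.grid[0])
        rows = []
        for h, v, f, ok in zip(self.grid, self.mlcv, self.n_failed, self.valid):
            row = {f"h{j + 1}": h[j] for j in range(p)}
            row.update(mlcv=v, n_failed=int(f), valid=bool(ok))
            rows.append(row)
        return pd.DataFrame(rows)


def loo_estimate(data: CountDataset, i: int, spec: KernelSpec, opts: FitOptions | None = None) -> float:
    """Leave-one-out log-mean estimate ``mhat_{-i}(x_i)``.

    Defined by explicit row deletion: the local model is fitted at
    ``x0 = x_i`` on the dataset without row i, and the centered intercept of
    that fit is returned.

    Raises
    ------
    FitError
        If the leave-one-out fit does not converge.
    DegenerateNeighborhoodError
        If no remaining observation carries weight at ``x_i``.
    """
    reduced = data.drop_row(i)
    fit = fit_local(reduced, data.X[i], spec, opts)
    if not fit.converged:
        raise FitError(f"leave-one-out fit at row {i} did not converge: {fit.message}")
    return float(fit.beta.beta[0])


def _mlcv_terms(data: CountDataset, spec: KernelSpec, opts: FitOptions | None):
    total = 0.0
    n_failed = 0
    for i in range(data.n):
        try:
            m = loo_estimate(data, i, spec, opts)
        except (FitError, DegenerateNeighborhoodError) as exc:
            logger.debug("LOO failure at row %d for h=%s: %s", i, spec.bandwidths, exc)
            n_failed += 1
            continue
        yi = float(data.y[i])
        total += m * yi - np.exp(m) - float(gammaln(yi + 1.0))
    return total, n_failed


def mlcv(data: CountDataset, spec: KernelSpec, opts: FitOptions | None = None) -> float:
    """Leave-one-out predictive log-likelihood at bandwidths ``spec.bandwidths``.

    Raises
    ------
    SelectionError
        If more than 20% of the leave-one-out fits fail.
    """
    total, n_failed = _mlcv_terms(data, spec, opts)
    if n_failed > MAX_FAILURE_FRACTION * data.n:
        raise SelectionError(
            f"{n_failed}/{data.n} leave-one-out fits failed at h={spec.bandwidths.tolist()}; "
            "grid point is invalid"
        )
    return total


def _evaluate_grid(data, vectors, family, opts):
    values, failures, valid = [], [], []
    for h in vectors:
        spec = KernelSpec(family=family, bandwidths=np.asarray(h, dtype=float))
        total, n_failed = _mlcv_terms(data, spec, opts)
        ok = n_failed <= MAX_FAILURE_FRACTION * data.n
        values.append(total if ok else np.nan)
        failures.append(n_failed)
        valid.append(ok)
    return np.asarray(values), np.asarray(failures), np.asarray(valid)


def _pick_best(vectors, values, failures, valid):
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise SelectionError("every bandwidth grid point is invalid")
    fmin = failures[idx].min()
    cand = idx[failures[idx] == fmin]
    best = cand[int(np.argmax(values[cand]))]  # argmax keeps the first on ties
    return int(best)


def select_bandwidth(
    data: CountDataset,
    grid,
    opts: FitOptions | None = None,
    mode: str = "per_predictor",
    family: str = "gaussian",
) -> MLCVResult:
    """Grid search for the MLCV-maximizing bandwidth vector.

    Parameters
    ----------
    data : CountDataset
    grid :
        ``mode="joint"``: a list of length-p bandwidth vectors, all evaluated.
        ``mode="per_predictor"``: a list of p one-dimensional grids; each
        coordinate is scanned in turn holding the others at their current
        best (starting from the middle of each grid), in a single pass —
        mirroring per-predictor bandwidth tables.
    opts : FitOptions, optional
    mode : {"per_predictor", "joint"}
    family : str
        Kernel family for every candidate.

    Returns
    -------
    MLCVResult
    """
    if mode not in ("joint", "per_predictor"):
        raise SelectionError(f"unknown selection mode {mode!r}")
    grid = [np.atleast_1d(np.asarray(g, dtype=float)) for g in grid]
    if len(grid) == 0 or any(g.size == 0 for g in grid):
        raise SelectionError("bandwidth grid must be non-empty")

    if mode == "joint":
        vectors = [g for g in grid]
        values, failures, valid = _evaluate_grid(data, vectors, family, opts)
        best = _pick_best(vectors, values, failures, valid)
        return MLCVResult(
            grid=vectors,
            mlcv=values,
            n_failed=failures,
            valid=valid,
            best=vectors[best].copy(),
            best_mlcv=float(values[best]),
        )

    # per_predictor: coordinate-wise scan, one pass
    p = len(grid)
    current = np.array([g[g.size // 2] for g in grid])
    all_vectors: list[np.ndarray] = []
    all_values: list[float] = []
    all_failures: list[int] = []
    all_valid: list[bool] = []
    for j in range(p):
        vectors = []
        for hj in grid[j]:
            h = current.copy()
            h[j] = hj
            vectors.append(h)
        values, failures, valid = _evaluate_grid(data, vectors, family, opts)
        best_j = _pick_best(vectors, values, failures, valid)
        current = vectors[best_j].copy()
        all_vectors.extend(vectors)
        all_values.extend(values.tolist())
        all_failures.extend(failures.tolist())
        all_valid.extend(valid.tolist())
    values = np.asarray(all_values)
    failures = np.asarray(all_failures)
    valid = np.asarray(all_valid)
    # MLCV of the final vector: it was evaluated during the last coordinate scan
    final_idx = next(
        k for k in range(len(all_vectors) - 1, -1, -1) if np.array_equal(all_vectors[k], current)
    )
    return MLCVResult(
        grid=all_vectors,
        mlcv=values,
        n_failed=failures,
        valid=valid,
        best=current,
        best_mlcv=float(values[final_idx]),
    )
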