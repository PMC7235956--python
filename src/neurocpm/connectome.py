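"""Functional connectome construction from node time series.

Given a T x K matrix of node time series (one representative time series per
network node), this module estimates the K x K connectivity matrix — partial
temporal correlation by default, plain Pearson correlation as a variant —
applies the Fisher r-to-z transform, and converts between the symmetric
matrix form and the flat edge-vector form (row-major upper triangle, i < j)
used by the prediction stages.

Partial correlations are obtained from the inverse of the (optionally
ridge-regularized) correlation matrix of the columns:

    p_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj),   Omega = inv(R + rho*I)

where R is the column correlation matrix.  The small ridge rho (default
0.01) keeps the inversion well conditioned for node counts in the hundreds;
rho = 0 gives the unregularized estimator.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from neurocpm.errors import InvalidInputError, NumericalError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RIDGE",
    "connectome_from_timeseries",
    "edge_pairs",
    "fisher_z",
    "from_edge_vector",
    "n_edges",
    "partial_correlation",
    "pearson_correlation",
    "to_edge_vector",
]

DEFAULT_RIDGE = 0.01

#: |r| at or beyond this is clamped before the Fisher transform so that
#: duplicated signals yield large finite z instead of +/-inf.
_R_CLAMP = 1.0 - 1e-7


def _as_timeseries(data: np.ndarray) -> np.ndarray:
    ts = np.asarray(data, dtype=float)
    if ts.ndim != 2:
        raise InvalidInputError(f"time series must be 2-D (T x K), got shape {ts.shape}")
    t, k = ts.shape
    if t < 2 or k < 2:
        raise InvalidInputError(f"need at least 2 timepoints and 2 nodes, got T={t}, K={k}")
    if not np.all(np.isfinite(ts)):
        raise InvalidInputError("time series contain non-finite values")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise InvalidInputError(
            f"columns {constant.tolist()} are constant (zero variance); "
            "remove or repair these nodes before computing connectivity"
        )
    return ts


def _standardize(ts: np.ndarray) -> np.ndarray:
    centered = ts - ts.mean(axis=0)
    return centered / centered.std(axis=0)


def pearson_correlation(data: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of node time series.

    Parameters
    ----------
    data
        T x K array, one column per node.

    Returns
    -------
    K x K symmetric matrix with zero diagonal.
    """
    ts = _as_timeseries(data)
    if ts.shape[0] < 3:
        raise InvalidInputError("Pearson connectivity needs at least 3 timepoints")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return r


def partial_correlation(data: np.ndarray, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Pairwise partial correlation of node time series.

    The correlation between each pair of columns after removing the linear
    influence of every other column, computed from the inverse of the
    (ridge-regularized) column correlation matrix.  Columns are demeaned and
    variance-normalized first, so ``ridge`` is on the scale of the unit
    diagonal: the matrix inverted is ``R + ridge * I``.

    Parameters
    ----------
    data
        T x K array, one column per node.
    ridge
        Nonnegative regularization strength; 0 disables regularization.

    Returns
    -------
    K x K symmetric matrix with zero diagonal and entries in (-1, 1).
    """
    ts = _as_timeseries(data)
    if ts.shape[0] <= 2:
        raise InvalidInputError("partial correlation needs more than 2 timepoints")
    if ridge < 0:
        raise InvalidInputError(f"ridge must be nonnegative, got {ridge}")
    z = _standardize(ts)
    corr = (z.T @ z) / z.shape[0]
    reg = corr + ridge * np.eye(corr.shape[0])
    try:
        omega = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "regularized correlation matrix is singular; increase the ridge "
            f"parameter (current ridge={ridge})"
        ) from exc
    d = np.sqrt(np.diag(omega))
    p = -omega / np.outer(d, d)
    p = np.clip((p + p.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(p, 0.0)
    return p


def fisher_z(r):
    """Fisher r-to-z transform, z = artanh(r), elementwise.

    Values with ``|r| >= 1 - 1e-7`` are clamped to that bound before the
    transform (the clamp is logged); ``|r| > 1`` is an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise InvalidInputError("correlations must satisfy |r| <= 1")
    n_clamped = int(np.count_nonzero(np.abs(arr) > _R_CLAMP))
    if n_clamped:
        logger.info("fisher_z: clamped %d value(s) with |r| >= %g", n_clamped, _R_CLAMP)
        arr = np.clip(arr, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(arr)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(z)
    return z


def connectome_from_timeseries(
    data: np.ndarray, method: str = "partial", ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """Full connectivity estimate: correlation by ``method``, then Fisher z.

    ``method`` is ``"partial"`` (default) or ``"pearson"``.  The diagonal is
    zero both before and after the transform.
    """
    if method == "partial":
        r = partial_correlation(data, ridge=ridge)
    elif method == "pearson":
        r = pearson_correlation(data)
    else:
        raise InvalidInputError(f"unknown connectivity method {method!r}")
    return fisher_z(r)


def n_edges(k: int) -> int:
    """Number of distinct node pairs (upper-triangle edges) for K nodes."""
    if k < 1:
        raise InvalidInputError(f"node count must be positive, got {k}")
    return k * (k - 1) // 2


def edge_pairs(k: int) -> list[tuple[int, int]]:
    """Node-index pairs (i, j), i < j, in the fixed row-major edge order."""
    iu = np.triu_indices(k, 1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def _k_from_edges(e: int) -> int:
    k = (1 + math.isqrt(1 + 8 * e)) // 2
    if k * (k - 1) // 2 != e:
        raise InvalidInputError(f"vector length {e} is not K*(K-1)/2 for any integer K")
    return k


def to_edge_vector(matrix: np.ndarray) -> np.ndarray:
    """Flatten a symmetric K x K matrix to its upper triangle (i < j, row-major)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise InvalidInputError("matrix is not symmetric within 1e-10")
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu].copy()


def from_edge_vector(vector: np.ndarray, k: int | None = None) -> np.ndarray:
    """Rebuild the symmetric K x K matrix (zero diagonal) from an edge vector."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1:
        raise InvalidInputError(f"edge vector must be 1-D, got shape {v.shape}")
    inferred = _k_from_edges(v.size)
    if k is not None and k != inferred:
        raise InvalidInputError(f"vector of length {v.size} implies K={inferred}, not K={k}")
    k = inferred
    m = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    m[iu] = v
    return m + m.T
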