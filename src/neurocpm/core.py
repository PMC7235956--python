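"""Core CPM building blocks: edge selection, summary scores, linear model.

The CPM procedure correlates every edge with the behavioral score in the
training sample, keeps edges with p below a significance threshold split by
sign into a positive and a negative predictive network, sums each subject's
selected edge weights into a per-network summary score, and fits an
ordinary-least-squares line from summary score to behavior.  Selection can
optionally be covariate-adjusted (partial correlation of edge and behavior
given the covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from neurocpm.errors import InvalidInputError

__all__ = [
    "CPMModel",
    "EdgeSelection",
    "correlate_edges",
    "correlate_edges_adjusted",
    "critical_r",
    "fit_linear_model",
    "predict",
    "select_edges",
    "summary_score",
]

TAILS = ("positive", "negative")


@dataclass
class EdgeSelection:
    """Result of edge-wise feature selection at a p threshold.

    ``positive_mask`` marks edges with r > 0 and p < threshold, and
    ``negative_mask`` those with r < 0 and p < threshold; the masks are
    disjoint because an edge is either a positive or a negative predictor.
    Edges whose correlation is undefined (zero variance) are never selected.
    """

    r: np.ndarray
    p: np.ndarray
    threshold: float
    positive_mask: np.ndarray
    negative_mask: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(self.positive_mask.sum())

    @property
    def n_negative(self) -> int:
        return int(self.negative_mask.sum())

    def mask(self, tail: str) -> np.ndarray:
        if tail == "positive":
            return self.positive_mask
        if tail == "negative":
            return self.negative_mask
        raise InvalidInputError(f"tail must be 'positive' or 'negative', got {tail!r}")


@dataclass
class CPMModel:
    """Per-tail linear model: behavior ~ slope * summary_score + intercept.

    A fold where no edge survives selection yields constant (all-zero)
    summary scores; such a model is flagged ``degenerate`` and predicts the
    training-sample mean (slope 0).
    """

    tail: str
    mask: np.ndarray
    slope: float
    intercept: float
    n_train: int
    degenerate: bool = field(default=False)


def _check_edges_behavior(edges: np.ndarray, behavior: np.ndarray, min_n: int):
    x = np.asarray(edges, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError(f"edges must be an n x E matrix, got shape {x.shape}")
    if y.ndim != 1 or y.size != x.shape[0]:
        raise InvalidInputError(
            f"behavior must be length-{x.shape[0]} (one score per subject), got shape {y.shape}"
        )
    if x.shape[0] < min_n:
        raise InvalidInputError(f"need at least {min_n} subjects, got {x.shape[0]}")
    if np.ptp(y) == 0:
        raise InvalidInputError("behavior is constant; edge-behavior correlation undefined")
    return x, y


def _column_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``x`` with ``y``; NaN for constant columns."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    xnorm = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    ynorm = np.sqrt(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (xnorm * ynorm)
    r[xnorm == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p from the t statistic t = r * sqrt(df / (1 - r^2))."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return p


def correlate_edges(edges: np.ndarray, behavior: np.ndarray):
    """Pearson correlation of every edge with behavior, with two-sided p.

    Returns ``(r, p)``, each of length E.  p-values come from the exact-null
    t distribution with n - 2 degrees of freedom.  Constant edge columns get
    ``r = p = NaN`` and are never selected downstream.
    """
    x, y = _check_edges_behavior(edges, behavior, min_n=4)
    r = _column_correlations(x, y)
    return r, _p_from_r(r, x.shape[0] - 2)


def _covariate_basis(covariates: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of span{1, covariates}; raises on rank deficiency."""
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise InvalidInputError(f"covariates have {c.shape[0]} rows for {n} subjects")
    design = np.column_stack([np.ones(n), c])
    q, rr = np.linalg.qr(design)
    diag = np.abs(np.diag(rr))
    bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
    if bad.size:
        cols = [("intercept" if j == 0 else f"covariate {j - 1}") for j in bad.tolist()]
        raise InvalidInputError(f"covariate matrix is rank deficient; collinear columns: {cols}")
    return q


def correlate_edges_adjusted(edges, behavior, covariates):
    """Covariate-adjusted (partial) correlation of each edge with behavior.

    Edge and behavior are both residualized on the covariates (with
    intercept); the residuals are then correlated.  p-values use
    n - 2 - c degrees of freedom for c covariates.
    """
    x, y = _check_edges_behavior(edges, behavior, min_n=4)
    n = x.shape[0]
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != n and c.shape[1] == n:
        c = c.T
    n_cov = c.shape[1]
    if n <= n_cov + 3:
        raise InvalidInputError(f"need n > c + 3 subjects (n={n}, c={n_cov})")
    q = _covariate_basis(c, n)
    y_res = y - q @ (q.T @ y)
    if np.sqrt(y_res @ y_res) < 1e-10 * max(np.abs(y).max(), 1.0):
        raise InvalidInputError(
            "behavior is (numerically) fully explained by the covariates; "
            "residual behavior is constant"
        )
    x_res = x - q @ (q.T @ x)
    r = _column_correlations(x_res, y_res)
    return r, _p_from_r(r, n - 2 - n_cov)


def select_edges(r: np.ndarray, p: np.ndarray, threshold: float) -> EdgeSelection:
    """Split significant edges by correlation sign into the two networks."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape or r.ndim != 1:
        raise InvalidInputError("r and p must be 1-D vectors of equal length")
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError(f"threshold must lie in (0, 1), got {threshold}")
    with np.errstate(invalid="ignore"):
        sig = p < threshold
        pos = sig & (r > 0)
        neg = sig & (r < 0)
    return EdgeSelection(r=r, p=p, threshold=threshold, positive_mask=pos, negative_mask=neg)


def critical_r(threshold: float, df: int) -> float:
    """|r| above which the two-sided p falls below ``threshold`` at given df."""
    if df < 1:
        raise InvalidInputError(f"degrees of freedom must be >= 1, got {df}")
    t_crit = stats.t.isf(threshold / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def summary_score(edge_values: np.ndarray, mask: np.ndarray):
    """Sum of the selected edge weights (the single-subject summary value).

    Accepts a length-E vector (returns a scalar) or an n x E matrix
    (returns a length-n vector).  An empty mask gives 0.
    """
    v = np.asarray(edge_values, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if v.shape[-1] != m.size:
        raise InvalidInputError(f"mask length {m.size} does not match edge count {v.shape[-1]}")
    if v.ndim == 1:
        return float(v[m].sum())
    return v[:, m].sum(axis=1)


def fit_linear_model(scores: np.ndarray, behavior: np.ndarray, tail: str,
                     mask: np.ndarray | None = None) -> CPMModel:
    """OLS fit of behavior on the network summary score.

    Constant scores (typically an empty selection mask) give the degenerate
    intercept-only model: slope 0, intercept = mean training behavior.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if tail not in TAILS:
        raise InvalidInputError(f"tail must be one of {TAILS}, got {tail!r}")
    if s.ndim != 1 or s.shape != y.shape:
        raise InvalidInputError("scores and behavior must be 1-D and the same length")
    if s.size < 3:
        raise InvalidInputError(f"need at least 3 training subjects, got {s.size}")
    if mask is None:
        mask = np.zeros(0, dtype=bool)
    var = float(np.var(s))
    if var == 0.0:
        return CPMModel(tail=tail, mask=np.asarray(mask, bool), slope=0.0,
                        intercept=float(y.mean()), n_train=s.size, degenerate=True)
    slope = float(np.cov(s, y, bias=True)[0, 1] / var)
    intercept = float(y.mean() - slope * s.mean())
    return CPMModel(tail=tail, mask=np.asarray(mask, bool), slope=slope,
                    intercept=intercept, n_train=s.size)


def predict(model: CPMModel, score):
    """Predicted behavior for one or more summary scores."""
    s = np.asarray(score, dtype=float)
    out = model.slope * s + model.intercept
    if np.ndim(score) == 0:
        return float(out)
    return out
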