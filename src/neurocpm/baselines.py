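"""Multivariate elastic-net baseline over all edges.

A head-to-head comparison for CPM: instead of univariate selection plus a
one-predictor line, fit a penalized linear model on every edge at once,
with the same leave-one-family-out folds so comparisons are paired.  The
objective is the standard coordinate-descent elastic net

    (1 / 2n) * ||y - Xw||^2 + alpha * (l1_ratio * ||w||_1
                                       + (1 - l1_ratio) / 2 * ||w||^2)

with the fixed default hyperparameters alpha = 1.0, l1_ratio = 0.5 (no
hyperparameter search).  Features are standardized inside each training
fold only — test-fold rows never touch the scaler.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LinearRegression

from neurocpm.core import TAILS
from neurocpm.errors import InvalidInputError
from neurocpm.validation import PredictionResult, evaluate_predictions, make_family_folds

logger = logging.getLogger(__name__)

__all__ = ["ElasticNetSpec", "elastic_net_cv"]


@dataclass
class ElasticNetSpec:
    """Elastic-net hyperparameters and solver controls."""

    alpha: float = 1.0
    l1_ratio: float = 0.5
    standardize: bool = True
    max_iter: int = 10000
    tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.alpha < 0:
            raise InvalidInputError(f"alpha must be >= 0, got {self.alpha}")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise InvalidInputError(f"l1_ratio must lie in [0, 1], got {self.l1_ratio}")


def _fit_one(x_tr, y_tr, spec: ElasticNetSpec):
    if spec.alpha == 0.0:
        model = LinearRegression()
        model.fit(x_tr, y_tr)
        return model, True
    model = ElasticNet(alpha=spec.alpha, l1_ratio=spec.l1_ratio,
                       max_iter=spec.max_iter, tol=spec.tol,
                       random_state=spec.seed)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(x_tr, y_tr)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("elastic net did not converge in %d iterations", model.n_iter_)
    return model, converged


def elastic_net_cv(edges, behavior, family_ids,
                   spec: ElasticNetSpec | None = None) -> PredictionResult:
    """Leave-one-family-out elastic-net prediction over all edges.

    Returns a :class:`PredictionResult` whose ``predicted`` dict carries a
    single ``"elastic_net"`` entry plus aliases for both CPM tails, so the
    result object is interchangeable with the CPM one in reports.
    ``fold_edge_counts`` records the nonzero-coefficient count per fold.
    """
    spec = spec or ElasticNetSpec()
    spec.validate()
    x = np.asarray(edges, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.ndim != 2 or y.shape != (x.shape[0],):
        raise InvalidInputError("edges must be n x E and behavior length n")
    plan = make_family_folds(family_ids)
    predicted = np.full(y.size, np.nan)
    counts = []
    n_degenerate = 0
    for train, test in plan:
        y_tr = y[train]
        if np.ptp(y_tr) == 0:
            raise InvalidInputError("training behavior is constant in a fold; cannot fit")
        x_tr, x_te = x[train], x[test]
        if spec.standardize:
            mean = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mean) / sd
            x_te = (x_te - mean) / sd
        model, _ = _fit_one(x_tr, y_tr, spec)
        n_nonzero = int(np.count_nonzero(model.coef_))
        counts.append({"elastic_net": n_nonzero})
        if n_nonzero == 0:
            n_degenerate += 1
        predicted[test] = model.predict(x_te)
    r = evaluate_predictions(y, predicted)
    pred = {"elastic_net": predicted, "positive": predicted, "negative": predicted}
    return PredictionResult(actual=y, predicted=pred,
                            r={"elastic_net": r, "positive": r, "negative": r},
                            threshold=float("nan"), fold_edge_counts=counts,
                            n_degenerate={t: n_degenerate for t in ("elastic_net",) + TAILS})
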