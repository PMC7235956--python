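"""Leave-one-family-out cross-validation and permutation significance.

Feature selection and model fitting happen strictly inside each training
fold; every subject's prediction comes from a model that never saw any
member of their family.  Significance of the prediction correlation is
assessed by shuffling the correspondence between connectomes and behavior,
re-running the whole cross-validated pipeline per shuffle, and reporting the
empirical p-value: the proportion of null correlations greater than or equal
to the true one (ties count toward the numerator).

The fold geometry and the centered training-edge matrices do not depend on
the behavior vector, so they are computed once and reused across all
permutations; each permutation then costs one matrix-vector product and one
tiny OLS fit per fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from neurocpm.core import (
    EdgeSelection,
    TAILS,
    _covariate_basis,
    critical_r,
)
from neurocpm.errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "PermutationResult",
    "PredictionResult",
    "evaluate_predictions",
    "make_family_folds",
    "permutation_test",
    "run_cpm_cv",
]


@dataclass
class FoldPlan:
    """One fold per family: (train indices, test indices), test sets partition the cohort."""

    families: list
    folds: list[tuple[np.ndarray, np.ndarray]]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


@dataclass
class PredictionResult:
    """Cross-validated predictions and their correlation with the actual scores."""

    actual: np.ndarray
    predicted: dict[str, np.ndarray]
    r: dict[str, float]
    threshold: float
    fold_edge_counts: list[dict[str, int]]
    n_degenerate: dict[str, int]

    def degenerate(self, tail: str) -> bool:
        """True when that tail's predictions are constant (r undefined)."""
        return bool(np.isnan(self.r[tail]))


@dataclass
class PermutationResult:
    """True prediction r per tail, the permutation null, and the empirical p."""

    r_true: dict[str, float]
    null_r: dict[str, np.ndarray]
    p: dict[str, float]
    n_perm: int
    n_valid: dict[str, int]
    seed: int | None
    smoothed: bool = field(default=False)


def make_family_folds(family_ids) -> FoldPlan:
    """Build the leave-one-family-out fold plan from per-subject family labels."""
    fam = np.asarray(family_ids)
    if fam.ndim != 1 or fam.size == 0:
        raise InvalidInputError("family_ids must be a nonempty 1-D array of labels")
    if fam.dtype.kind == "f" and np.isnan(fam.astype(float)).any():
        raise InvalidInputError("every subject needs a family label (NaN found)")
    labels = np.unique(fam)
    if labels.size < 2:
        raise InvalidInputError(
            "cross-validation needs at least 2 families; a single family leaves no training data"
        )
    all_idx = np.arange(fam.size)
    folds = []
    for lab in labels:
        test = all_idx[fam == lab]
        train = all_idx[fam != lab]
        folds.append((train, test))
    return FoldPlan(families=labels.tolist(), folds=folds)


class _FoldCache:
    __slots__ = ("train", "test", "x_train", "x_test", "x_sel", "col_norms",
                 "r_crit", "q", "n_train")

    def __init__(self, train, test, edges, threshold, covariates):
        self.train = train
        self.test = test
        self.x_train = edges[train]
        self.x_test = edges[test]
        self.n_train = train.size
        if covariates is not None:
            q = _covariate_basis(covariates[train], self.n_train)
            self.q = q
            x_sel = self.x_train - q @ (q.T @ self.x_train)
            df = self.n_train - 2 - covariates.shape[1]
        else:
            self.q = None
            x_sel = self.x_train - self.x_train.mean(axis=0)
            df = self.n_train - 2
        if df < 1:
            raise InvalidInputError(
                f"training fold of size {self.n_train} leaves no degrees of freedom"
            )
        self.x_sel = x_sel
        self.col_norms = np.sqrt(np.einsum("ij,ij->j", x_sel, x_sel))
        self.r_crit = critical_r(threshold, df)


class _CVEngine:
    """Precomputes everything y-independent so permutations are cheap."""

    def __init__(self, edges, family_ids, threshold, covariates=None,
                 fixed_selection: EdgeSelection | None = None):
        x = np.asarray(edges, dtype=float)
        if x.ndim != 2:
            raise InvalidInputError(f"edges must be an n x E matrix, got shape {x.shape}")
        fam = np.asarray(family_ids)
        if fam.size != x.shape[0]:
            raise InvalidInputError("family_ids length does not match the number of subjects")
        if not 0.0 < threshold < 1.0:
            raise InvalidInputError(f"threshold must lie in (0, 1), got {threshold}")
        self.n, self.n_edges = x.shape
        self.threshold = threshold
        self.plan = make_family_folds(fam)
        cov = None
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != self.n and cov.shape[1] == self.n:
                cov = cov.T
        self.covariates = cov
        self.fixed_selection = fixed_selection
        self.folds = [
            _FoldCache(train, test, x, threshold, cov) for train, test in self.plan
        ]

    def predict(self, y: np.ndarray, collect: bool = False):
        """Cross-validated predictions for behavior vector ``y``, per tail."""
        predicted = {t: np.full(self.n, np.nan) for t in TAILS}
        counts = [] if collect else None
        n_degen = {t: 0 for t in TAILS}
        fixed = self.fixed_selection
        for fc in self.folds:
            ytr = y[fc.train]
            if fixed is not None:
                idx = {"positive": np.flatnonzero(fixed.positive_mask),
                       "negative": np.flatnonzero(fixed.negative_mask)}
            else:
                if fc.q is not None:
                    yr = ytr - fc.q @ (fc.q.T @ ytr)
                else:
                    yr = ytr - ytr.mean()
                ynorm = np.sqrt(yr @ yr)
                if ynorm == 0.0:
                    idx = {"positive": np.empty(0, int), "negative": np.empty(0, int)}
                else:
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r = (fc.x_sel.T @ yr) / (fc.col_norms * ynorm)
                    idx = {"positive": np.flatnonzero(r > fc.r_crit),
                           "negative": np.flatnonzero(r < -fc.r_crit)}
            if collect:
                counts.append({t: int(idx[t].size) for t in TAILS})
            for tail in TAILS:
                cols = idx[tail]
                if cols.size:
                    s_tr = fc.x_train[:, cols].sum(axis=1)
                else:
                    s_tr = np.zeros(fc.n_train)
                var = float(np.var(s_tr))
                if var == 0.0:
                    n_degen[tail] += 1
                    predicted[tail][fc.test] = ytr.mean()
                    continue
                slope = float(np.cov(s_tr, ytr, bias=True)[0, 1] / var)
                intercept = float(ytr.mean() - slope * s_tr.mean())
                s_te = fc.x_test[:, cols].sum(axis=1) if cols.size else np.zeros(fc.test.size)
                predicted[tail][fc.test] = slope * s_te + intercept
        return predicted, counts, n_degen


def evaluate_predictions(actual, predicted) -> float:
    """Pearson r between actual and predicted scores; NaN when either is constant."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise InvalidInputError("actual and predicted must be 1-D vectors of equal length")
    if a.size < 3:
        raise InvalidInputError("need at least 3 subjects to evaluate predictions")
    ac = a - a.mean()
    pc = p - p.mean()
    denom = np.sqrt((ac @ ac) * (pc @ pc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((ac @ pc) / denom, -1.0, 1.0))


def run_cpm_cv(edges, behavior, family_ids, threshold: float = 0.01,
               covariates=None, fixed_selection: EdgeSelection | None = None,
               _engine: _CVEngine | None = None) -> PredictionResult:
    """Cross-validated CPM prediction with leave-one-family-out folds.

    Parameters
    ----------
    edges
        n x E matrix of edge weights (Fisher-z units), one row per subject.
    behavior
        Length-n behavioral scores.
    family_ids
        Length-n family labels; each distinct label becomes one test fold.
    threshold
        Edge-selection significance level (two-sided p), default 0.01.
    covariates
        Optional n x c matrix; selection then uses covariate-adjusted
        (partial) correlations with n - 2 - c degrees of freedom.
    fixed_selection
        Pre-computed edge masks reused in every fold.  This disables
        within-fold selection and exists to demonstrate the feature-selection
        leakage bug; do not use it for real analyses.
    """
    y = np.asarray(behavior, dtype=float)
    engine = _engine or _CVEngine(edges, family_ids, threshold,
                                  covariates=covariates, fixed_selection=fixed_selection)
    if y.size != engine.n:
        raise InvalidInputError("behavior length does not match the number of subjects")
    if np.ptp(y) == 0:
        raise InvalidInputError("behavior is constant; nothing to predict")
    predicted, counts, n_degen = engine.predict(y, collect=True)
    r = {t: evaluate_predictions(y, predicted[t]) for t in TAILS}
    for t in TAILS:
        if n_degen[t]:
            logger.info("tail %s: %d degenerate fold(s) (no selected edges)", t, n_degen[t])
    return PredictionResult(actual=y, predicted=predicted, r=r, threshold=engine.threshold,
                            fold_edge_counts=counts, n_degenerate=n_degen)


def permutation_test(edges, behavior, family_ids, threshold: float = 0.01,
                     n_perm: int = 5000, seed: int | None = None,
                     covariates=None, smoothed: bool = False,
                     fixed_selection: EdgeSelection | None = None) -> PermutationResult:
    """Permutation significance of the cross-validated prediction correlation.

    The behavior vector is shuffled uniformly across all subjects ``n_perm``
    times and the full cross-validated pipeline is re-run per shuffle.  The
    empirical p per tail is #{null r >= true r} / m over the m permutations
    whose null r is defined; permutations with constant predictions are
    excluded from numerator and denominator and logged.  With
    ``smoothed=True`` the estimate (count + 1) / (m + 1) is reported instead.
    """
    if n_perm < 1:
        raise InvalidInputError(f"n_perm must be >= 1, got {n_perm}")
    y = np.asarray(behavior, dtype=float)
    engine = _CVEngine(edges, family_ids, threshold, covariates=covariates,
                       fixed_selection=fixed_selection)
    true = run_cpm_cv(edges, y, family_ids, threshold, covariates=covariates,
                      fixed_selection=fixed_selection, _engine=engine)
    rng = np.random.default_rng(seed)
    null = {t: np.full(n_perm, np.nan) for t in TAILS}
    for i in range(n_perm):
        y_perm = y[rng.permutation(engine.n)]
        predicted, _, _ = engine.predict(y_perm)
        for t in TAILS:
            null[t][i] = evaluate_predictions(y_perm, predicted[t])
    p, n_valid, null_valid = {}, {}, {}
    for t in TAILS:
        valid = null[t][~np.isnan(null[t])]
        n_dropped = n_perm - valid.size
        if n_dropped:
            logger.info("tail %s: %d permutation(s) with undefined r excluded", t, n_dropped)
        null_valid[t] = valid
        n_valid[t] = int(valid.size)
        if np.isnan(true.r[t]) or valid.size == 0:
            p[t] = float("nan")
        else:
            count = int((valid >= true.r[t]).sum())
            p[t] = (count + 1) / (valid.size + 1) if smoothed else count / valid.size
    return PermutationResult(r_true=dict(true.r), null_r=null_valid, p=p,
                             n_perm=n_perm, n_valid=n_valid, seed=seed, smoothed=smoothed)
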