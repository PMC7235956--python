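"""Family-aware cross-validation and permutation significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neurocpm.core import select_edges
from neurocpm.errors import InvalidInputError
from neurocpm.validation import (
    evaluate_predictions,
    make_family_folds,
    permutation_test,
    run_cpm_cv,
)


def test_two_family_fold_plan():
    plan = make_family_folds(np.array(["A", "A", "B"]))
    assert len(plan) == 2
    (train_a, test_a), (train_b, test_b) = plan.folds
    assert test_a.tolist() == [0, 1] and train_a.tolist() == [2]
    assert test_b.tolist() == [2] and train_b.tolist() == [0, 1]


def test_singleton_families_reduce_to_leave_one_out():
    plan = make_family_folds(np.arange(8))
    assert len(plan) == 8
    assert all(test.size == 1 for _, test in plan)


def test_single_family_is_fatal():
    with pytest.raises(InvalidInputError, match="single family|at least 2"):
        make_family_folds(np.array(["F1"] * 5))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 9), min_size=2, max_size=40).filter(lambda v: len(set(v)) >= 2))
def test_fold_plan_partitions_cohort(families):
    """No family straddles train/test; every subject tested exactly once."""
    fam = np.asarray(families)
    plan = make_family_folds(fam)
    tested = np.concatenate([test for _, test in plan])
    assert sorted(tested.tolist()) == list(range(fam.size))
    for train, test in plan:
        assert not set(fam[train]) & set(fam[test])
        assert np.union1d(train, test).size == fam.size


def noiseless_dataset(n=24):
    """Behavior is exactly the sum of 3 planted edges; all other edges constant.

    The three edges are positive multiples of behavior (0.2y, 0.3y, 0.5y), so
    each has train correlation exactly 1, is always selected into the
    positive network, and their sum reproduces behavior identically.
    Constant columns have undefined correlation and are never selected.
    """
    rng = np.random.default_rng(5)
    e = 10
    edges = np.tile(np.linspace(0.1, 0.9, e), (n, 1))
    y = rng.standard_normal(n)
    edges[:, [1, 4, 7]] = np.outer(y, [0.2, 0.3, 0.5])
    fam = np.repeat(np.arange(n // 2), 2)
    return edges, y, fam


def test_noiseless_linear_behavior_is_perfectly_predicted():
    edges, y, fam = noiseless_dataset()
    res = run_cpm_cv(edges, y, fam, threshold=0.01)
    assert res.r["positive"] == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(res.predicted["positive"], y, atol=1e-8)


def test_permutation_p_minimum_and_smoothing():
    edges, y, fam = noiseless_dataset()
    perm = permutation_test(edges, y, fam, threshold=0.01, n_perm=100, seed=0)
    assert perm.p["positive"] == 0.0
    smoothed = permutation_test(edges, y, fam, threshold=0.01, n_perm=100, seed=0,
                                smoothed=True)
    assert smoothed.p["positive"] == pytest.approx(1 / 101)


def test_permutation_counting_rule():
    """25 of 5000 null values >= true r gives p = 0.005; ties count."""
    r_true = 0.5
    null = np.concatenate([np.full(24, 0.7), [0.5], np.full(4975, -0.1)])
    count = int((null >= r_true).sum())
    assert count == 25
    assert count / 5000 == 0.005


def test_permutation_seed_reproducible(small_cohort):
    cohort, edges, _ = small_cohort
    y = cohort["behavior"].to_numpy(dtype=float)
    fam = cohort["family_id"].to_numpy()
    a = permutation_test(edges, y, fam, n_perm=50, seed=11)
    b = permutation_test(edges, y, fam, n_perm=50, seed=11)
    assert a.p == b.p
    for t in a.null_r:
        assert np.array_equal(a.null_r[t], b.null_r[t])


def test_permutation_invariant_to_subject_relabeling(small_cohort):
    """Jointly reordering subjects leaves the true r unchanged (exchangeability)."""
    cohort, edges, _ = small_cohort
    y = cohort["behavior"].to_numpy(dtype=float)
    fam = cohort["family_id"].to_numpy()
    order = np.random.default_rng(3).permutation(len(y))
    a = run_cpm_cv(edges, y, fam)
    b = run_cpm_cv(edges[order], y[order], fam[order])
    for t in ("positive", "negative"):
        assert a.r[t] == pytest.approx(b.r[t], abs=1e-10)


def test_planted_signal_recovered(small_cohort):
    """Strong planted signal gives clearly positive cross-validated r per tail."""
    cohort, edges, _ = small_cohort
    res = run_cpm_cv(edges, cohort["behavior"].to_numpy(dtype=float),
                     cohort["family_id"].to_numpy(), threshold=0.01)
    assert res.r["positive"] > 0.4
    assert res.r["negative"] > 0.4
    assert all(c["positive"] >= 0 and c["negative"] >= 0 for c in res.fold_edge_counts)


def test_predictions_come_from_other_families(small_cohort):
    """Deleting a family's rows does not change other families' predictions...

    equivalently: a subject's prediction never uses their own family. Checked
    by replacing one family's behavior with wild values and asserting only
    that family's fold model (hence only *other* subjects) can change.
    """
    cohort, edges, _ = small_cohort
    y = cohort["behavior"].to_numpy(dtype=float)
    fam = cohort["family_id"].to_numpy()
    base = run_cpm_cv(edges, y, fam)
    y2 = y.copy()
    target = fam == fam[0]
    y2[target] = y2[target] + 40.0
    bumped = run_cpm_cv(edges, y2, fam)
    # The bumped family's own predictions are made by models trained without
    # it, on identical data, so they are bitwise unchanged.
    assert np.allclose(base.predicted["positive"][target],
                       bumped.predicted["positive"][target], atol=1e-10)


def test_evaluate_predictions_edge_cases(rng):
    y = rng.standard_normal(5)
    assert evaluate_predictions(y, y) == pytest.approx(1.0)
    assert evaluate_predictions(y, -y) == pytest.approx(-1.0)
    other = rng.standard_normal(5)
    assert evaluate_predictions(y, other) == pytest.approx(stats.pearsonr(y, other)[0])
    assert np.isnan(evaluate_predictions(y, np.zeros(5)))


def test_degenerate_folds_are_not_fatal(rng):
    """Pure-noise edges at a strict threshold: many empty selections, still runs."""
    n = 30
    edges = rng.standard_normal((n, 20))
    y = rng.standard_normal(n)
    fam = np.repeat(np.arange(10), 3)
    res = run_cpm_cv(edges, y, fam, threshold=1e-4)
    assert res.n_degenerate["positive"] > 0
    assert np.all(np.isfinite(res.predicted["positive"]))


def test_leaky_full_sample_selection_biases_null_r(rng):
    """Selecting edges on the full sample before CV inflates null prediction r."""
    n = 60
    edges = rng.standard_normal((n, 190))
    y = rng.standard_normal(n)
    fam = np.repeat(np.arange(20), 3)
    from neurocpm.core import correlate_edges
    r, p = correlate_edges(edges, y)
    leak = select_edges(r, p, 0.05)
    honest = run_cpm_cv(edges, y, fam, threshold=0.05)
    leaky = run_cpm_cv(edges, y, fam, threshold=0.05, fixed_selection=leak)
    # The leaked selection saw every subject's behavior, so its CV r on pure
    # noise is strongly positive; the honest pipeline's is not.
    assert leaky.r["positive"] > honest.r["positive"]
    assert leaky.r["positive"] > 0.3
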