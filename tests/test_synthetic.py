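"""Synthetic cohort, planted-signal edge data, and Gaussian time series."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocpm.errors import InvalidInputError, InvalidSpecError
from neurocpm.synthetic import (
    SignalSpec,
    SyntheticCohortSpec,
    calibrate_beta,
    generate_cohort,
    generate_edge_data,
    generate_time_series,
)


def test_equal_family_sizes_partition():
    spec = SyntheticCohortSpec(n_subjects=6, n_families=3,
                               family_size_distribution={2: 1.0}, seed=0)
    cohort = generate_cohort(spec)
    sizes = cohort.groupby("family_id").size()
    assert sizes.tolist() == [2, 2, 2]
    assert cohort["subject_id"].is_unique
    assert len(cohort) == 6


def test_family_sizes_sum_even_with_awkward_distribution():
    spec = SyntheticCohortSpec(n_subjects=11, n_families=4,
                               family_size_distribution={2: 0.5, 4: 0.5}, seed=3)
    cohort = generate_cohort(spec)
    assert len(cohort) == 11
    assert cohort["family_id"].nunique() == 4


def test_cohort_determinism():
    spec = SyntheticCohortSpec(n_subjects=50, n_families=17, seed=42)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(SyntheticCohortSpec(n_subjects=50, n_families=17, seed=43))
    assert not a["behavior"].equals(c["behavior"])


def test_behavior_moments_match_spec():
    """Large-sample mean/SD of the latent scores match the requested ones."""
    spec = SyntheticCohortSpec(n_subjects=10_000, n_families=5000,
                               behavior_mean=32.0, behavior_sd=6.0, seed=5)
    cohort = generate_cohort(spec)
    latent = cohort["behavior_latent"]
    assert abs(latent.mean() - 32.0) < 0.2
    assert abs(latent.std() - 6.0) < 0.2
    assert cohort["behavior"].between(0, 48).all()
    assert (cohort["behavior"] == cohort["behavior"].round()).all()


def test_invalid_cohort_specs_rejected():
    with pytest.raises(InvalidSpecError):
        generate_cohort(SyntheticCohortSpec(n_subjects=3, n_families=5))
    with pytest.raises(InvalidSpecError):
        generate_cohort(SyntheticCohortSpec(behavior_sd=0.0))


def test_edge_matrix_shape_and_ground_truth(small_cohort):
    cohort, edges, truth = small_cohort
    e = 20 * 19 // 2
    assert edges.shape == (60, e)
    assert truth.positive_edge_indices.size == 8
    assert truth.negative_edge_indices.size == 8
    assert not set(truth.positive_edge_indices) & set(truth.negative_edge_indices)
    assert np.all(truth.beta_per_edge[truth.positive_edge_indices] > 0)
    assert np.all(truth.beta_per_edge[truth.negative_edge_indices] < 0)


def test_edge_data_determinism(small_cohort):
    cohort, edges, _ = small_cohort
    again, _ = generate_edge_data(cohort, SignalSpec(
        n_nodes=20, n_positive_edges=8, n_negative_edges=8,
        beta=0.25, noise_sd=0.3, seed=7))
    assert np.array_equal(edges, again)


def test_null_edges_selection_calibrated():
    """beta = 0: per-edge p-values reject at their nominal rate."""
    spec = SyntheticCohortSpec(n_subjects=100, n_families=50, seed=9)
    cohort = generate_cohort(spec)
    # K=46 gives E=1035 >= 1000 edges for a tight binomial band
    edges, _ = generate_edge_data(cohort, SignalSpec(
        n_nodes=46, n_positive_edges=0, n_negative_edges=0, beta=0.0, seed=9))
    from neurocpm.core import correlate_edges
    _, p = correlate_edges(edges, cohort["behavior"].to_numpy(dtype=float))
    alpha, e = 0.05, p.size
    band = 2.576 * np.sqrt(alpha * (1 - alpha) / e)
    assert abs((p < alpha).mean() - alpha) < band


def test_null_correlations_follow_t_distribution():
    """beta = 0, no family effect: edge-behavior r matches the null t law (KS)."""
    rejections = 0
    for rep in range(10):
        spec = SyntheticCohortSpec(n_subjects=80, n_families=40, seed=100 + rep)
        cohort = generate_cohort(spec)
        edges, _ = generate_edge_data(cohort, SignalSpec(
            n_nodes=40, n_positive_edges=0, n_negative_edges=0,
            beta=0.0, family_effect_sd=0.0, seed=100 + rep))
        from neurocpm.core import correlate_edges
        r, _ = correlate_edges(edges, cohort["behavior"].to_numpy(dtype=float))
        n = len(cohort)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        if stats.kstest(t, "t", args=(n - 2,)).pvalue < 0.01:
            rejections += 1
    assert rejections <= 2  # at the 1% level, 10 replicates rarely reject


def test_strong_signal_edges_all_positively_correlated():
    """beta = 5 * noise_sd: every planted positive edge has sample r > 0."""
    spec = SyntheticCohortSpec(n_subjects=200, n_families=100, seed=21)
    cohort = generate_cohort(spec)
    edges, truth = generate_edge_data(cohort, SignalSpec(
        n_nodes=20, n_positive_edges=10, n_negative_edges=10,
        beta=1.5, noise_sd=0.3, seed=21))
    y = cohort["behavior"].to_numpy(dtype=float)
    for e in truth.positive_edge_indices:
        assert stats.pearsonr(edges[:, e], y)[0] > 0
    for e in truth.negative_edge_indices:
        assert stats.pearsonr(edges[:, e], y)[0] < 0


def test_single_subject_edge_matrix():
    cohort = generate_cohort(SyntheticCohortSpec(
        n_subjects=1, n_families=1, family_size_distribution={1: 1.0}, seed=2))
    edges, _ = generate_edge_data(cohort, SignalSpec(n_nodes=5, n_positive_edges=2,
                                                     n_negative_edges=2, seed=2))
    assert edges.shape == (1, 10)


def test_too_many_signal_edges_rejected(small_cohort):
    cohort = small_cohort[0]
    with pytest.raises(InvalidSpecError, match="exceed"):
        generate_edge_data(cohort, SignalSpec(n_nodes=5, n_positive_edges=8,
                                              n_negative_edges=8))


def test_family_effect_is_shared_within_family():
    spec = SyntheticCohortSpec(n_subjects=30, n_families=10,
                               family_size_distribution={3: 1.0}, seed=4)
    cohort = generate_cohort(spec)
    base_spec = dict(n_nodes=10, n_positive_edges=0, n_negative_edges=0,
                     beta=0.0, noise_sd=0.3, seed=4)
    plain, _ = generate_edge_data(cohort, SignalSpec(**base_spec))
    shifted, _ = generate_edge_data(cohort, SignalSpec(family_effect_sd=0.5, **base_spec))
    delta = shifted - plain
    # The added offset is constant across a subject's edges and across a family.
    assert np.allclose(delta.std(axis=1), 0.0, atol=1e-12)
    for _, grp in cohort.groupby("family_id"):
        idx = grp.index.to_numpy()
        assert np.allclose(delta[idx, 0], delta[idx[0], 0], atol=1e-12)


def test_time_series_identity_precision_is_uncorrelated():
    ts = generate_time_series(5, 50_000, np.eye(5), seed=8)
    r = np.corrcoef(ts, rowvar=False)
    off = r[~np.eye(5, dtype=bool)]
    assert np.all(np.abs(off) < 0.03)


def test_time_series_tridiagonal_precision_closed_form():
    """Sample partial correlations match -P_ij / sqrt(P_ii P_jj)."""
    k = 5
    prec = np.diag(np.full(k, 2.0)) + np.diag(np.full(k - 1, -0.7), 1) \
        + np.diag(np.full(k - 1, -0.7), -1)
    ts = generate_time_series(k, 100_000, prec, seed=13)
    from neurocpm.connectome import partial_correlation
    got = partial_correlation(ts, ridge=0.0)
    d = np.sqrt(np.diag(prec))
    want = -prec / np.outer(d, d)
    np.fill_diagonal(want, 0.0)
    assert np.allclose(got, want, atol=0.05)


def test_time_series_determinism_and_pd_check():
    a = generate_time_series(4, 100, np.eye(4), seed=3)
    b = generate_time_series(4, 100, np.eye(4), seed=3)
    assert np.array_equal(a, b)
    with pytest.raises(InvalidInputError, match="positive definite"):
        generate_time_series(2, 10, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=0)
    with pytest.raises(InvalidInputError, match="symmetric"):
        generate_time_series(2, 10, np.array([[1.0, 0.5], [0.2, 1.0]]), seed=0)


def test_calibrate_beta_monotone_and_positive():
    b1 = calibrate_beta(0.2, 200, 30, 1225)
    b2 = calibrate_beta(0.4, 200, 30, 1225)
    assert 0 < b1 < b2
    with pytest.raises(InvalidInputError):
        calibrate_beta(1.5, 200, 30, 1225)
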