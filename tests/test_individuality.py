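"""Rank/bias transform, weighted PCA and the shuffle/permutation tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import roamind as rm
from roamind.individuality import bootstrap_variance_test, shuffle_ranks


# ---------------------------------------------------------------- ranking


@pytest.mark.parametrize(
    "values, expected",
    [
        ([0.1, 0.3, 0.3, 0.9], [1.0, 2.5, 2.5, 4.0]),  # tie -> mean position
        ([0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5]),
        ([0.4] * 5, [3.0] * 5),  # all tied at the middle position
    ],
)
def test_fractional_ranks(values, expected):
    ranks = rm.rank_individuals(np.asarray(values)[:, None])
    np.testing.assert_allclose(ranks.ravel(), expected)


def test_ranking_is_within_experiment():
    vals = np.array([0.1, 0.9, 0.2, 0.8])[:, None]
    exps = np.array([0, 0, 1, 1])
    ranks = rm.rank_individuals(vals, exps)
    np.testing.assert_allclose(ranks.ravel(), [1, 2, 1, 2])


def test_ranking_rejects_singleton_experiment_and_missing_bins():
    with pytest.raises(ValueError, match="fewer than 2"):
        rm.rank_individuals(np.ones((3, 2)), [0, 0, 1])
    bad = np.ones((3, 2))
    bad[1, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        rm.rank_individuals(bad)


@pytest.mark.parametrize(
    "n, ranks, expected",
    [
        (4, [1, 2.5, 2.5, 4], [-0.75, 0.0, 0.0, 0.75]),
        (5, [5, 1, 3, 2, 4], [0.8, -0.8, 0.0, -0.4, 0.4]),  # extremes +-(1-1/n)
    ],
)
def test_bias_formula(n, ranks, expected):
    b = rm.bias(np.asarray(ranks, dtype=float)[:, None])
    np.testing.assert_allclose(b.ravel(), expected)


def test_bias_of_median_rank_is_zero():
    n = 7
    b = rm.bias(np.full((n, 1), (n + 1) / 2))
    # the formula puts the median rank exactly at zero bias only after
    # within-experiment rescaling; with all ranks at the median, all biases 0
    np.testing.assert_allclose(b, 0.0, atol=1e-15)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    n=st.integers(3, 30),
    k=st.integers(1, 8),
    seed=st.integers(0, 10_000),
    n_exp=st.integers(1, 3),
)
def test_per_bin_mean_bias_is_zero(n, k, seed, n_exp):
    """Per experiment and bin the mean bias vanishes, ties included."""
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 4, size=(n, k)) / 4.0  # force ties
    exps = np.arange(n) % n_exp
    if np.min(np.bincount(exps)) < 2:
        exps = np.zeros(n, dtype=int)
    b = rm.bias(rm.rank_individuals(vals, exps), exps)
    for e in np.unique(exps):
        np.testing.assert_allclose(b[exps == e].mean(axis=0), 0.0, atol=1e-12)


def test_bias_transform_composes_with_sklearn():
    from sklearn.pipeline import Pipeline

    X = np.random.default_rng(0).random((20, 5))
    pipe = Pipeline(
        [("bias", rm.BiasTransform()), ("pca", rm.WeightedPCA())]
    )
    scores = pipe.fit_transform(X)
    assert scores.shape == (20, 5)


# ------------------------------------------------------------ weighted PCA


def _svd_oracle(B):
    """Independent route: SVD of the bias matrix, no covariance formed."""
    _, s, vt = np.linalg.svd(B / np.sqrt(B.shape[0]), full_matrices=True)
    evals = np.zeros(B.shape[1])
    evals[: s.size] = s**2
    return evals, vt


def test_equal_weight_pca_matches_svd_oracle(rng):
    B = rng.normal(size=(6, 4))
    model = rm.weighted_pca(B)
    evals, vt = _svd_oracle(B)
    np.testing.assert_allclose(model.explained_variance_, evals, atol=1e-10)
    for k in range(4):
        cos = abs(model.components_[k] @ vt[k])
        if evals[k] > 1e-12:
            assert cos > 1 - 1e-10


def test_antipodal_pair_single_component():
    b = np.array([1.0, -2.0, 0.5])
    model = rm.weighted_pca(np.vstack([b, -b]))
    assert abs(model.components_[0] @ (b / np.linalg.norm(b))) > 1 - 1e-12
    assert model.explained_variance_ratio_[0] == pytest.approx(1.0)


def test_reconstruction_identity(rng):
    B = rng.normal(size=(15, 8))
    conds = rng.integers(0, 2, 15)
    model = rm.weighted_pca(B, conds)
    T = model.transform(B)
    np.testing.assert_allclose(T @ model.components_, B, atol=1e-10)
    # Parseval: weighted score variances sum to total weighted bias variance
    w = model.weights_
    total = ((w[:, None] * B**2).sum()) / w.sum()
    assert model.explained_variance_.sum() == pytest.approx(total)


def test_equal_condition_sizes_equal_unweighted(rng):
    B = rng.normal(size=(20, 6))
    conds = np.repeat([0, 1], 10)
    wm = rm.weighted_pca(B, conds)
    um = rm.weighted_pca(B)
    for k in range(6):
        assert abs(wm.components_[k] @ um.components_[k]) > 1 - 1e-8


def test_weighting_rescues_small_condition(rng):
    """A 10-individual condition's dominant pattern survives weighting but is
    swamped in unweighted PCA by a 1000-individual condition."""
    k = 20
    u = np.zeros(k)
    u[:10] = 1 / np.sqrt(10)
    v = np.zeros(k)
    v[10:] = 1 / np.sqrt(10)
    w = np.zeros(k)
    w[::2] = 1 / np.sqrt(10)
    w -= (w @ u) * u + (w @ v) * v
    w /= np.linalg.norm(w)
    small = rng.normal(scale=2.0, size=(10, 1)) * u + rng.normal(scale=0.05, size=(10, k))
    big = (
        rng.normal(scale=1.0, size=(1000, 1)) * v
        + rng.normal(scale=0.5, size=(1000, 1)) * w
        + rng.normal(scale=0.1, size=(1000, k))
    )
    B = np.vstack([small, big])
    conds = np.array(["small"] * 10 + ["big"] * 1000)
    wm = rm.weighted_pca(B, conds)
    top2 = wm.components_[:2]
    assert max(abs(top2 @ u)) > 0.9 and max(abs(top2 @ v)) > 0.9
    um = rm.weighted_pca(B)
    assert max(abs(um.components_[:2] @ u)) < 0.9


def test_pca_validation():
    with pytest.raises(ValueError):
        rm.weighted_pca(np.ones((1, 5)))


# ------------------------------------------------------------- shuffling


def test_shuffle_preserves_per_bin_multisets(rng):
    vals = rng.random((12, 6))
    exps = np.arange(12) % 2
    ranks = rm.rank_individuals(vals, exps)
    shuffled = shuffle_ranks(ranks, exps, rng=0)
    for e in (0, 1):
        np.testing.assert_allclose(
            np.sort(shuffled[exps == e], axis=0), np.sort(ranks[exps == e], axis=0)
        )


def test_shuffle_reproducible_and_distinct(rng):
    ranks = rm.rank_individuals(rng.random((10, 5)))
    a = shuffle_ranks(ranks, rng=42)
    b = shuffle_ranks(ranks, rng=42)
    c = shuffle_ranks(ranks, rng=43)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_shuffle_collapses_planted_variance(planted_cohort):
    matrix, labels, _ = planted_cohort
    exps = labels["experiment_id"].to_numpy()
    ranks = rm.rank_individuals(matrix, exps)
    B = rm.bias(ranks, exps)
    real = rm.weighted_pca(B).explained_variance_ratio_[0]
    Bs = rm.bias(shuffle_ranks(ranks, exps, rng=0), exps)
    null = rm.weighted_pca(Bs).explained_variance_ratio_[0]
    assert real > 0.3
    assert null < 3.0 / matrix.shape[1]  # near 1/50 of total


def test_pc_significance_detects_planted_structure(planted_cohort):
    matrix, labels, _ = planted_cohort
    exps = labels["experiment_id"].to_numpy()
    sig = rm.pc_significance(matrix, exps, n_reps=50, seed=0, n_components=3)
    assert sig["exceedance_own_space"].iloc[0] == 0.0
    assert sig["exceedance_original_space"].iloc[0] == 0.0
    assert bool(sig["significant_own_space"].iloc[0])
    with pytest.raises(ValueError):
        rm.pc_significance(matrix, exps, n_reps=0)


# ------------------------------------------------- variances and indices


def test_score_variance_matches_brute_force():
    scores = np.array([1.0, 2.0, 2.0, 5.0, 10.0])[:, None]
    v = rm.score_variance(scores, dim=0)
    assert v == pytest.approx(np.mean((scores - scores.mean()) ** 2))
    assert rm.score_variance(np.zeros((4, 2)), dim=1) == 0.0
    with pytest.raises(ValueError):
        rm.score_variance(scores, ids=[], dim=0)


def test_variance_permutation_test_properties(rng):
    scores = rng.normal(size=(40, 1))
    a, b = np.arange(20), np.arange(20, 40)
    p = rm.variance_permutation_test(scores, a, b, n_perm=200, seed=0)
    assert p >= 1 / 201
    assert p > 0.05  # same distribution: no evidence
    # identical variances by construction -> p near 1
    scores2 = np.concatenate([scores[:20], scores[rng.permutation(20)]])
    p2 = rm.variance_permutation_test(scores2, a, b, n_perm=200, seed=0)
    assert p2 > 0.5
    with pytest.raises(ValueError, match="overlap"):
        rm.variance_permutation_test(scores, [0, 1, 2], [2, 3, 4])
    assert bootstrap_variance_test is rm.variance_permutation_test


def test_variance_permutation_test_power(rng):
    a_vals = rng.normal(scale=1.0, size=50)
    b_vals = rng.normal(scale=3.0, size=50)  # variances 1 vs 9
    scores = np.concatenate([a_vals, b_vals])[:, None]
    p = rm.variance_permutation_test(
        scores, np.arange(50), np.arange(50, 100), n_perm=500, seed=1
    )
    assert p < 0.05


def test_consistency_index_hand_cases():
    # 50 bins; medians per bin are 0.5 for an odd cohort around it
    n_bins = 50
    base = np.full(n_bins, 0.5)
    up = np.full(n_bins, 0.65)
    down = np.full(n_bins, 0.35)
    mixed = np.where(np.arange(n_bins) < 40, 0.6, 0.4)
    cohort = np.vstack([base, up, down, mixed, np.full(n_bins, 0.45)])
    idx = rm.consistency_index(cohort)
    # 'up' is above the per-bin median everywhere -> +log2(50/0.5)
    assert idx[1] == pytest.approx(np.log2(50 / 0.5))
    assert idx[3] == pytest.approx(2.0)  # 40 above / 10 below -> log2(4)


def test_consistency_index_balanced_and_tied():
    vals = np.tile([0.2, 0.5, 0.8], (50, 1)).T
    idx = rm.consistency_index(vals)
    with pytest.warns(UserWarning, match="tied"):
        tied = rm.consistency_index(np.vstack([vals, np.full(50, 0.5)]))
    assert tied[3] == 0.0
    # balanced individual: 25 above, 25 below
    half = np.concatenate([np.full(25, 0.9), np.full(25, 0.1)])
    cohort = np.vstack([half, np.full(50, 0.5), 1 - half])
    assert rm.consistency_index(cohort)[0] == pytest.approx(0.0)


def test_consistency_index_antisymmetry(rng):
    vals = rng.random((9, 50))
    med = np.median(vals, axis=0)
    reflected = 2 * med - vals
    np.testing.assert_allclose(
        rm.consistency_index(reflected), -rm.consistency_index(vals), atol=1e-12
    )


def test_extreme_individuals():
    scores = np.arange(20)[::-1].astype(float)  # sorted descending
    top, bottom = rm.extreme_individuals(scores, fraction=0.15)
    assert len(top) == 3 and len(bottom) == 3
    np.testing.assert_array_equal(top, [0, 1, 2])
    np.testing.assert_array_equal(bottom, [19, 18, 17])
    with pytest.raises(ValueError):
        rm.extreme_individuals(scores, fraction=0.5)


def test_consistency_pc1_correlation_edges():
    x = np.arange(10.0)
    assert rm.consistency_pc1_correlation(x, x) == pytest.approx(1.0)
    assert rm.consistency_pc1_correlation(x, -x) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        rm.consistency_pc1_correlation(np.ones(10), x)


def test_planted_cohort_coefficient_recovery(planted_cohort):
    """PC1 scores track the planted coefficients of a single archetype."""
    matrix, labels, coeffs = planted_cohort
    exps = labels["experiment_id"].to_numpy()
    B = rm.bias(rm.rank_individuals(matrix, exps), exps)
    model = rm.weighted_pca(B)
    scores = model.transform(B)
    r = abs(stats.pearsonr(coeffs[:, 0], scores[:, 0]).statistic)
    assert r > 0.9
    arch = rm.make_archetypes(["homogeneous"])[0]
    assert abs(model.components_[0] @ arch) > 0.9
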