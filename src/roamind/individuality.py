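"""Rank/bias transform, weighted PCA and shuffle/permutation inference.

This is the unsupervised machinery that extracts "individuality dimensions"
from a cohort's roaming profiles. Within each experiment, individuals are
ranked per time bin by roaming fraction (fractional ranks for ties); ranks
are rescaled to biases in (-1, 1) centred on the experiment median; the bias
matrix is decomposed by PCA on a condition-weighted second-moment matrix, so
that conditions of very different sizes contribute equally. Because per-bin
mean bias is exactly zero by construction, no mean term is subtracted.

Significance of the components is assessed against shuffle nulls in which
ranks are permuted independently within each time bin (preserving per-bin
rank multisets), and differences in inter-individual score variance between
conditions are assessed by a permutation test.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "rank_individuals",
    "bias",
    "BiasTransform",
    "WeightedPCA",
    "weighted_pca",
    "shuffle_ranks",
    "pc_significance",
    "score_variance",
    "variance_permutation_test",
    "bootstrap_variance_test",
    "consistency_index",
    "extreme_individuals",
    "consistency_pc1_correlation",
]


def _as_groups(labels: Sequence, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError(f"labels must have length {n}, got shape {labels.shape}")
    return labels


def rank_individuals(
    roaming: np.ndarray,
    experiments: Sequence | None = None,
) -> np.ndarray:
    """Fractional ranks of individuals per time bin, within each experiment.

    Higher roaming fraction receives a higher rank; ties receive the mean of
    the positions they occupy (values (0.1, 0.3, 0.3, 0.9) rank as
    (1, 2.5, 2.5, 4)).

    Parameters
    ----------
    roaming : (n_individuals, n_bins) array
        Roaming fractions. Rows with any missing bin are rejected: drop or
        impute them before ranking.
    experiments : length-n labels, optional
        Experiment membership; ranking is within experiment. One pooled
        experiment if omitted.

    Returns
    -------
    ranks : (n_individuals, n_bins) array of fractional ranks in [1, n_i].
    """
    X = np.asarray(roaming, dtype=float)
    if X.ndim != 2:
        raise ValueError("roaming must be 2-D (individuals x bins)")
    if np.isnan(X).any():
        bad = np.unique(np.nonzero(np.isnan(X))[0])
        raise ValueError(
            f"missing roaming fractions for individuals {bad.tolist()}; "
            "exclude or impute before ranking"
        )
    n = X.shape[0]
    if experiments is None:
        experiments = np.zeros(n, dtype=int)
    experiments = _as_groups(experiments, n)

    ranks = np.empty_like(X)
    for exp in np.unique(experiments):
        idx = np.nonzero(experiments == exp)[0]
        if idx.size < 2:
            raise ValueError(f"experiment {exp!r} has fewer than 2 individuals")
        ranks[idx] = stats.rankdata(X[idx], method="average", axis=0)
    return ranks


def bias(ranks: np.ndarray, experiments: Sequence | None = None) -> np.ndarray:
    """Rescale within-experiment ranks to biases in (-1, 1).

    b = (2/n) (r - 1/2) - 1, with n the size of the individual's experiment.
    A bias of 0 corresponds to the experiment median; the extremes are
    +-(1 - 1/n). Per experiment and bin the mean bias is exactly zero
    (fractional ties included).
    """
    R = np.asarray(ranks, dtype=float)
    n = R.shape[0]
    if experiments is None:
        experiments = np.zeros(n, dtype=int)
    experiments = _as_groups(experiments, n)
    B = np.empty_like(R)
    for exp in np.unique(experiments):
        idx = np.nonzero(experiments == exp)[0]
        ni = idx.size
        B[idx] = (2.0 / ni) * (R[idx] - 0.5) - 1.0
    return B


class BiasTransform(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: roaming fractions -> bias matrix.

    Stateless apart from recorded experiment labels; ``transform`` ranks the
    rows of X within each experiment per column and rescales to (-1, 1).
    """

    def __init__(self, experiments: Sequence | None = None):
        self.experiments = experiments

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        ranks = rank_individuals(X, self.experiments)
        return bias(ranks, self.experiments)


def _condition_weights(conditions: Sequence | None, n: int) -> np.ndarray:
    if conditions is None:
        return np.full(n, 1.0 / n)
    conditions = _as_groups(conditions, n)
    w = np.empty(n)
    for c in np.unique(conditions):
        m = conditions == c
        w[m] = 1.0 / m.sum()
    return w


class WeightedPCA(BaseEstimator, TransformerMixin):
    """PCA of the bias matrix with inverse-condition-size weighting.

    Components are eigenvectors of M = sum_i w_i b_i b_i^T / sum_i w_i with
    w_i = 1 / (number of individuals sharing i's condition), so each
    condition contributes equal total weight regardless of its size. No mean
    is subtracted by default because per-bin mean bias is zero by
    construction; set ``center=True`` for sensitivity checks.

    Attributes (after ``fit``)
    --------------------------
    components_ : (n_bins, n_bins) array, rows are unit-norm PCs in
        descending eigenvalue order; sign fixed so each row's
        largest-magnitude entry is positive.
    explained_variance_ : eigenvalues (weighted score variance per PC).
    explained_variance_ratio_ : eigenvalues / total.
    weights_ : the per-individual weights used.
    """

    def __init__(self, center: bool = False):
        self.center = center

    def fit(self, X, y=None, conditions: Sequence | None = None):
        B = check_array(X, dtype=float)
        n, k = B.shape
        if n < 2:
            raise ValueError("weighted PCA needs at least 2 individuals")
        w = _condition_weights(conditions, n)
        self.weights_ = w
        if self.center:
            mean = (w[:, None] * B).sum(axis=0) / w.sum()
        else:
            mean = np.zeros(k)
        self.mean_ = mean
        Bc = B - mean
        M = (Bc.T * w) @ Bc / w.sum()
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        comps = evecs[:, order].T
        # sign convention: largest-|entry| of each component positive
        flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        flip[flip == 0] = 1.0
        comps = comps * flip[:, None]
        self.components_ = comps
        self.explained_variance_ = evals
        total = evals.sum()
        self.explained_variance_ratio_ = (
            evals / total if total > 0 else np.zeros_like(evals)
        )
        self.n_features_in_ = k
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        B = check_array(X, dtype=float)
        return (B - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)

    def inverse_transform(self, T) -> np.ndarray:
        check_is_fitted(self)
        return np.asarray(T) @ self.components_ + self.mean_


def weighted_pca(
    biases: np.ndarray, conditions: Sequence | None = None, center: bool = False
) -> WeightedPCA:
    """Fit a :class:`WeightedPCA` and return the fitted model."""
    return WeightedPCA(center=center).fit(biases, conditions=conditions)


def shuffle_ranks(
    ranks: np.ndarray,
    experiments: Sequence | None = None,
    rng: np.random.Generator | int | None = None,
    pooled: bool = False,
) -> np.ndarray:
    """Permute ranks independently within each time bin.

    By default the permutation is within each experiment, preserving every
    experiment's per-bin rank multiset; ``pooled=True`` permutes across the
    whole cohort instead.
    """
    R = np.asarray(ranks, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, k = R.shape
    if experiments is None or pooled:
        experiments = np.zeros(n, dtype=int)
    experiments = _as_groups(experiments, n)
    out = np.empty_like(R)
    for exp in np.unique(experiments):
        idx = np.nonzero(experiments == exp)[0]
        sub = R[idx]
        perm = np.argsort(rng.random((sub.shape[1], idx.size)), axis=1)
        out[idx] = sub[perm.T, np.arange(sub.shape[1])]
    return out


def pc_significance(
    roaming: np.ndarray,
    experiments: Sequence | None = None,
    conditions: Sequence | None = None,
    n_reps: int = 500,
    seed: int | None = None,
    n_components: int | None = None,
    alpha: float = 0.05,
    pooled_shuffle: bool = False,
) -> pd.DataFrame:
    """Shuffle-null exceedance rates for PC score variances, both modes.

    For each replicate, ranks are shuffled independently per bin (within
    experiment), biases recomputed, and the variance attributed to each PC
    measured two ways: ``own_space`` refits PCA on the shuffled data and
    takes the same-numbered eigenvalue; ``original_space`` projects the
    shuffled biases onto the original components and takes the weighted
    variance of the projections. The exceedance rate for PC k is the
    fraction of replicates whose null variance is >= the observed eigenvalue;
    a PC is significant when that rate is below ``alpha``.

    Returns a DataFrame with columns ``pc`` (1-based), ``observed_variance``,
    ``exceedance_own_space``, ``exceedance_original_space``,
    ``significant_own_space``, ``significant_original_space``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be a positive integer")
    X = np.asarray(roaming, dtype=float)
    ranks = rank_individuals(X, experiments)
    B = bias(ranks, experiments)
    model = weighted_pca(B, conditions)
    k = B.shape[1] if n_components is None else min(n_components, B.shape[1])
    observed = model.explained_variance_[:k]
    w = model.weights_
    wsum = w.sum()

    rng = np.random.default_rng(seed)
    exceed_own = np.zeros(k)
    exceed_orig = np.zeros(k)
    for _ in range(n_reps):
        Rs = shuffle_ranks(ranks, experiments, rng, pooled=pooled_shuffle)
        Bs = bias(Rs, experiments)
        null_model = weighted_pca(Bs, conditions)
        exceed_own += null_model.explained_variance_[:k] >= observed
        proj = Bs @ model.components_[:k].T
        var_orig = (w[:, None] * proj**2).sum(axis=0) / wsum
        exceed_orig += var_orig >= observed
    exceed_own /= n_reps
    exceed_orig /= n_reps
    return pd.DataFrame(
        {
            "pc": np.arange(1, k + 1),
            "observed_variance": observed,
            "exceedance_own_space": exceed_own,
            "exceedance_original_space": exceed_orig,
            "significant_own_space": exceed_own < alpha,
            "significant_original_space": exceed_orig < alpha,
        }
    )


def score_variance(
    scores: np.ndarray, ids: Sequence[int] | None = None, dim: int = 0
) -> float:
    """Population variance of PC scores along one dimension.

    Inter-individual variance of a (sub)population's scores is the dispersal
    parameter compared across conditions.
    """
    T = np.asarray(scores, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if ids is not None:
        ids = np.asarray(ids)
        if ids.size == 0:
            raise ValueError("empty subpopulation")
        T = T[ids]
    return float(np.var(T[:, dim]))


def variance_permutation_test(
    scores: np.ndarray,
    group_a: Sequence[int],
    group_b: Sequence[int],
    dim: int = 0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation test for a difference in score variance between groups.

    Statistic: |var_A - var_B| (two-sided). Individuals are pooled and
    reassigned to two groups of the original sizes; the p-value is
    (1 + #{perm >= observed}) / (1 + n_perm), so it is never zero.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 individuals")
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap")
    T = np.asarray(scores, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    va = T[a, dim]
    vb = T[b, dim]
    observed = abs(np.var(va) - np.var(vb))
    pooled = np.concatenate([va, vb])
    na = va.size
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(np.var(perm[:na]) - np.var(perm[na:]))
        if stat >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


# the figure legends call this procedure "bootstrapping"; same test
bootstrap_variance_test = variance_permutation_test


def consistency_index(
    roaming: np.ndarray, experiments: Sequence | None = None
) -> np.ndarray:
    """Per-individual log2 ratio of bins above vs below the population median.

    index_i = log2(A_i / B_i) with A_i the number of time bins in which
    individual i's roaming fraction exceeds the per-bin within-experiment
    median and B_i the number in which it is lower. Bins tied with the
    median count toward neither; a zero count is replaced by 0.5 to keep the
    index finite. Positive values mark individuals consistently above the
    median, negative consistently below.
    """
    X = np.asarray(roaming, dtype=float)
    n = X.shape[0]
    if experiments is None:
        experiments = np.zeros(n, dtype=int)
    experiments = _as_groups(experiments, n)
    index = np.empty(n)
    for exp in np.unique(experiments):
        idx = np.nonzero(experiments == exp)[0]
        sub = X[idx]
        med = np.median(sub, axis=0)
        above = (sub > med).sum(axis=1).astype(float)
        below = (sub < med).sum(axis=1).astype(float)
        tied_all = (above == 0) & (below == 0)
        if tied_all.any():
            warnings.warn(
                f"{int(tied_all.sum())} individual(s) tied with the median in "
                "every bin; consistency index set to 0"
            )
        above[above == 0] = 0.5
        below[below == 0] = 0.5
        vals = np.log2(above / below)
        vals[tied_all] = 0.0
        index[idx] = vals
    return index


def extreme_individuals(
    scores: np.ndarray, dim: int = 0, fraction: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the top and bottom ``fraction`` of individuals on one PC.

    Returns ``ceil(fraction * n)`` highest- and lowest-scoring indices; ties
    broken by stable original order.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie strictly between 0 and 0.5")
    T = np.asarray(scores, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    s = T[:, dim]
    n = s.size
    m = math.ceil(fraction * n)
    asc = np.argsort(s, kind="stable")
    bottom = asc[:m]
    desc = np.argsort(-s, kind="stable")
    top = desc[:m]
    return top, bottom


def consistency_pc1_correlation(index: np.ndarray, scores: np.ndarray) -> float:
    """|Pearson r| between the consistency index and one PC's scores.

    Absolute value because the sign of a principal component is a
    convention.
    """
    x = np.asarray(index, dtype=float)
    y = np.asarray(scores, dtype=float)
    if y.ndim > 1:
        y = y[:, 0]
    if x.shape != y.shape:
        raise ValueError("index and scores must have the same length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, _ = stats.pearsonr(x, y)
    return abs(float(r))
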