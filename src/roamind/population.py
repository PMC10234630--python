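"""Stage-level group comparisons: stage means, relative effects,
rank-sum tests with FDR correction, and size-matched comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StageSummary",
    "stage_means",
    "relative_effect",
    "compare_groups",
    "size_matched_compare",
]


@dataclass
class StageSummary:
    """Per-individual per-stage means with condition labels."""

    values: np.ndarray  # (n_individuals, n_stages)
    conditions: np.ndarray
    kind: str = "roaming_fraction"

    def condition_stats(self) -> pd.DataFrame:
        """Condition mean ± SEM per stage (defined individuals only)."""
        rows = []
        for c in np.unique(self.conditions):
            sub = self.values[self.conditions == c]
            for s in range(self.values.shape[1]):
                col = sub[:, s]
                col = col[~np.isnan(col)]
                rows.append(
                    {
                        "condition": c,
                        "stage": s,
                        "n": col.size,
                        "mean": col.mean() if col.size else np.nan,
                        "sem": stats.sem(col) if col.size > 1 else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def stage_means(
    fractions: np.ndarray,
    stage_of_bin: np.ndarray,
    conditions: Sequence | None = None,
    kind: str = "roaming_fraction",
) -> StageSummary:
    """Per-individual mean over each stage's bins (defined bins only).

    ``fractions`` is an (n_individuals, n_bins) matrix; ``stage_of_bin``
    assigns each column to a stage. Stages where an individual has no
    defined bin are flagged NaN.
    """
    X = np.asarray(fractions, dtype=float)
    stage_of_bin = np.asarray(stage_of_bin)
    if X.ndim != 2 or X.shape[1] != stage_of_bin.size:
        raise ValueError("fractions must be (n_individuals, n_bins)")
    stages = np.unique(stage_of_bin)
    out = np.full((X.shape[0], stages.size), np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for j, s in enumerate(stages):
            out[:, j] = np.nanmean(X[:, stage_of_bin == s], axis=1)
    conds = (
        np.asarray(conditions)
        if conditions is not None
        else np.repeat("all", X.shape[0])
    )
    return StageSummary(values=out, conditions=conds, kind=kind)


def relative_effect(treated: StageSummary, control: StageSummary) -> np.ndarray:
    """Per-stage ratio of condition means, treated / control.

    Stages where the control mean is zero are flagged NaN rather than
    producing infinities.
    """
    if treated.values.shape[1] != control.values.shape[1]:
        raise ValueError("summaries cover different stages")
    t = np.nanmean(treated.values, axis=0)
    c = np.nanmean(control.values, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t / c
    ratio[c == 0] = np.nan
    return ratio


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    fdr_q: float = 0.05,
    unit_labels: Sequence | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per unit (bin or stage), BH-corrected.

    ``values_a``/``values_b`` are (n_individuals, n_units); returns one row
    per unit with raw p, Benjamini-Hochberg adjusted p, -log10(adjusted p)
    and the rejection flag at ``fdr_q``.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 individuals")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups cover different units")
    n_units = A.shape[1]
    p = np.array([_ranksum_p(A[:, u], B[:, u]) for u in range(n_units)])
    ok = ~np.isnan(p)
    p_adj = np.full(n_units, np.nan)
    reject = np.zeros(n_units, dtype=bool)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=fdr_q, method="fdr_bh")
        p_adj[ok] = adj
        reject[ok] = rej
    with np.errstate(divide="ignore"):
        neg_log = -np.log10(p_adj)
    return pd.DataFrame(
        {
            "unit": unit_labels if unit_labels is not None else np.arange(n_units),
            "n_A": (~np.isnan(A)).sum(axis=0),
            "n_B": (~np.isnan(B)).sum(axis=0),
            "p": p,
            "p_adj": p_adj,
            "neg_log10_p_adj": neg_log,
            "reject": reject,
        }
    )


def size_matched_compare(
    values: np.ndarray,
    sizes: np.ndarray,
    groups: Sequence,
    group_a,
    group_b,
    n_windows: int = 20,
    width_frac: float = 0.10,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Group comparison within running size windows.

    Windows have centers evenly spanning the pooled size range and width
    ``width_frac`` x range; within each, individuals of the two groups
    falling in the window are compared by rank-sum. Windows with fewer than
    2 members per group are flagged (p NaN). The BH correction runs across
    the testable windows.
    """
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    groups = np.asarray(groups)
    lo, hi = np.nanmin(sizes), np.nanmax(sizes)
    if not hi > lo:
        raise ValueError("degenerate size range")
    w = width_frac * (hi - lo)
    centers = np.linspace(lo + w / 2, hi - w / 2, n_windows)
    rows = []
    for c in centers:
        in_win = (sizes >= c - w / 2) & (sizes <= c + w / 2)
        a = values[in_win & (groups == group_a)]
        b = values[in_win & (groups == group_b)]
        rows.append(
            {
                "center": c,
                "lo": c - w / 2,
                "hi": c + w / 2,
                "n_A": a.size,
                "n_B": b.size,
                "p": _ranksum_p(a, b) if a.size >= 2 and b.size >= 2 else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["p"].notna().to_numpy()
    df["p_adj"] = np.nan
    df["reject"] = False
    if ok.any():
        rej, adj, _, _ = multipletests(df.loc[ok, "p"], alpha=fdr_q, method="fdr_bh")
        df.loc[ok, "p_adj"] = adj
        df.loc[ok, "reject"] = rej
    with np.errstate(divide="ignore"):
        df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
    return df
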