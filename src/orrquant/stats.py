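"""Group comparisons and retina–cortex correlation matrices.

Group differences use the Kruskal–Wallis rank test followed by Dunn's
post hoc pairwise z tests (pooled rank means with the standard tie
correction), with Holm–Bonferroni step-down adjustment across all pairs of
one analysis family (one marker x layer).  Retina–cortex relationships are
summarised by both Pearson (linear) and Spearman (monotone) correlations
with pairwise deletion of missing values.

Dunn's z for groups i, j with pooled midranks:

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

where ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups of size t.
Two-sided p-values are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass
class GroupTestResult:
    """Kruskal–Wallis global test plus Dunn pairwise comparisons."""

    H: float
    df: int
    p_global: float
    pairwise: pd.DataFrame = field(repr=False)  # group_i, group_j, z, p_raw,
    #                                             p_adjusted, significant
    alpha: float = DEFAULT_ALPHA
    adjust_family: str = "all pairwise comparisons within one analysis"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman correlation of one metric pair."""

    pair: tuple[str, str]
    r_pearson: float
    p_pearson: float
    rho_spearman: float
    p_spearman: float
    n: int


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    return arrs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal–Wallis H (tie-corrected), degrees of freedom, and p-value."""
    arrs = _check_groups(groups)
    H, p = sps.kruskal(*arrs)
    return float(H), len(arrs) - 1, float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence | None = None,
    *,
    p_adjust: str = "holm",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Dunn pairwise z tests on pooled midranks, tie-corrected.

    Returns a frame with one row per pair: (group_i, group_j, z, p_raw,
    p_adjusted, significant).  ``p_adjust`` is any statsmodels
    multipletests method ('holm' default, 'none' to skip).
    """
    arrs = _check_groups(groups)
    if labels is None:
        labels = list(range(len(arrs)))
    if len(labels) != len(arrs):
        raise ValueError("labels must match the number of groups")

    pooled = np.concatenate(arrs)
    N = pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    ties = counts[counts > 1]
    T = float(np.sum(ties**3 - ties)) / (12.0 * (N - 1)) if ties.size else 0.0

    rank_means, sizes = [], []
    start = 0
    for a in arrs:
        rank_means.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size

    rows = []
    for i, j in combinations(range(len(arrs)), 2):
        var = (N * (N + 1) / 12.0 - T) * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (rank_means[i] - rank_means[j]) / np.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_i": labels[i], "group_j": labels[j],
                     "z": float(z), "p_raw": float(min(p, 1.0))})
    df = pd.DataFrame(rows)
    if p_adjust == "none":
        df["p_adjusted"] = df["p_raw"]
    else:
        df["p_adjusted"] = multipletests(df["p_raw"], method=p_adjust)[1]
    df["significant"] = df["p_adjusted"] < alpha
    return df


def group_comparison(
    groups: Sequence[Sequence[float]],
    labels: Sequence | None = None,
    *,
    alpha: float = DEFAULT_ALPHA,
) -> GroupTestResult:
    """Kruskal–Wallis followed by Holm-adjusted Dunn post hoc tests."""
    H, df, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups, labels, alpha=alpha)
    return GroupTestResult(H=H, df=df, p_global=p, pairwise=pairwise, alpha=alpha)


def significance_stars(p: float) -> str:
    """Conventional star rendering of a p-value (ns, *, **, ***, ****)."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def correlation_matrix(
    table: pd.DataFrame,
    cortical_cols: Sequence[str] = ("best_threshold_uA", "d_prime"),
    retinal_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson and Spearman correlations of retinal vs cortical metrics.

    Every (retinal metric, cortical metric) pair is correlated on its
    complete cases (pairwise deletion).  Pairs with fewer than 3 complete
    cases or zero variance in either column are reported with NaN
    coefficients.  Returns a tidy frame (retinal_metric, cortical_metric,
    r_pearson, p_pearson, rho_spearman, p_spearman, n).
    """
    if retinal_cols is None:
        retinal_cols = [
            c for c in table.columns
            if c not in cortical_cols and pd.api.types.is_numeric_dtype(table[c])
        ]
    missing = [c for c in list(cortical_cols) + list(retinal_cols)
               if c not in table.columns]
    if missing:
        raise ValueError(f"metric columns missing from table: {missing}")

    rows = []
    for rc in retinal_cols:
        for cc in cortical_cols:
            sub = table[[rc, cc]].dropna()
            n = len(sub)
            if n < 3 or sub[rc].nunique() < 2 or sub[cc].nunique() < 2:
                rows.append({"retinal_metric": rc, "cortical_metric": cc,
                             "r_pearson": np.nan, "p_pearson": np.nan,
                             "rho_spearman": np.nan, "p_spearman": np.nan,
                             "n": n})
                continue
            r, pr = sps.pearsonr(sub[rc], sub[cc])
            rho, ps = sps.spearmanr(sub[rc], sub[cc])
            rows.append({"retinal_metric": rc, "cortical_metric": cc,
                         "r_pearson": float(r), "p_pearson": float(pr),
                         "rho_spearman": float(rho), "p_spearman": float(ps),
                         "n": n})
    return pd.DataFrame(rows)
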