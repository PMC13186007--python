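"""Rank-test and correlation checks, cross-validated against brute-force
oracles that rank and apply the textbook formulas explicitly."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from orrquant import stats as S


# ---------------------------------------------------------------------------
# brute-force oracles (explicit midranks + textbook formulas)


def _midranks(values):
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), float)
    i = 0
    sv = np.asarray(values)[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_oracle(groups):
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = counts[counts > 1]
    correction = 1.0 - np.sum(ties**3 - ties) / (N**3 - N)
    return h / correction if correction > 0 else 0.0


def dunn_oracle(groups):
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = _midranks(pooled)
    means, sizes = [], []
    start = 0
    for g in groups:
        means.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    ties = counts[counts > 1]
    tcorr = np.sum(ties**3 - ties) / (12.0 * (N - 1)) if len(ties) else 0.0
    out = []
    for i, j in combinations(range(len(groups)), 2):
        var = (N * (N + 1) / 12.0 - tcorr) * (1 / sizes[i] + 1 / sizes[j])
        z = (means[i] - means[j]) / np.sqrt(var)
        out.append((i, j, z, 2 * sps.norm.sf(abs(z))))
    return out


# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        H, df, p = S.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert H == pytest.approx(7.2)
        assert df == 2

    def test_identical_groups_small_h(self):
        H, _, p = S.kruskal_wallis([[1, 2, 3], [2, 1, 3], [3, 2, 1]])
        assert H == pytest.approx(kw_oracle([[1, 2, 3], [2, 1, 3], [3, 2, 1]]))
        assert p > 0.5

    def test_matches_oracle_on_small_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            sizes = rng.integers(2, 5, size=rng.integers(2, 4))
            if sizes.sum() > 12:
                continue
            groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
            H, _, _ = S.kruskal_wallis(groups)
            assert H == pytest.approx(kw_oracle(groups), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            S.kruskal_wallis([[1, 2], []])


class TestDunnPosthoc:
    def test_matches_oracle_on_small_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            sizes = rng.integers(2, 5, size=3)
            if sizes.sum() > 12:
                continue
            groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
            df = S.dunn_posthoc(groups, p_adjust="none")
            for (i, j, z, p), (_, row) in zip(dunn_oracle(groups), df.iterrows()):
                assert row["z"] == pytest.approx(z, abs=1e-10)
                assert row["p_raw"] == pytest.approx(p, abs=1e-10)

    def test_well_separated_groups_all_significant(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(mu, 1, 40) for mu in (0.0, 10.0, 20.0)]
        df = S.dunn_posthoc(groups)
        assert df["significant"].all()

    def test_holm_step_down_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_holm_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 15) for m in (0, 0.5, 1.0, 1.5)]
        df = S.dunn_posthoc(groups)
        assert (df["p_adjusted"] >= df["p_raw"] - 1e-12).all()
        order = df.sort_values("p_raw")
        assert order["p_adjusted"].is_monotonic_increasing

    def test_type_i_error_control_under_null(self):
        # identical distributions: any adjusted significance is rare
        false_pos = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 12) for _ in range(3)]
            if S.dunn_posthoc(groups)["significant"].any():
                false_pos += 1
        assert false_pos / reps <= 0.05 + 0.06  # binomial slack at 40 reps


class TestGroupComparison:
    def test_combined_result_consistency(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 20) for m in (0, 1, 2)]
        res = S.group_comparison(groups, labels=["a", "b", "c"])
        assert res.df == 2
        assert len(res.pairwise) == 3
        assert set(res.pairwise["group_i"]).issubset({"a", "b"})


class TestCorrelationMatrix:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        t = pd.DataFrame({"orr": x, "best_threshold_uA": 2 * x + 1,
                          "d_prime": -x})
        out = S.correlation_matrix(t, retinal_cols=["orr"])
        row = out[(out["retinal_metric"] == "orr")
                  & (out["cortical_metric"] == "best_threshold_uA")].iloc[0]
        assert row["r_pearson"] == pytest.approx(1.0)
        assert row["rho_spearman"] == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        t = pd.DataFrame({"x": x, "best_threshold_uA": x**3,
                          "d_prime": np.ones(5)})
        out = S.correlation_matrix(t, retinal_cols=["x"])
        row = out[out["cortical_metric"] == "best_threshold_uA"].iloc[0]
        assert row["rho_spearman"] == pytest.approx(1.0)
        assert row["r_pearson"] < 1.0

    def test_zero_variance_reported_missing(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0],
                          "best_threshold_uA": [5.0, 5.0, 5.0],
                          "d_prime": [1.0, 2.0, 3.0]})
        out = S.correlation_matrix(t, retinal_cols=["x"])
        row = out[out["cortical_metric"] == "best_threshold_uA"].iloc[0]
        assert np.isnan(row["r_pearson"])

    def test_pairwise_deletion(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4, np.nan],
                          "best_threshold_uA": [1, 2, 3, 4, 5],
                          "d_prime": [5, 4, 3, 2, 1.0]})
        out = S.correlation_matrix(t, retinal_cols=["x"])
        assert out[out["cortical_metric"] == "best_threshold_uA"].iloc[0]["n"] == 4

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.integers(0, 5, 30).astype(float)  # ties likely
            y = rng.normal(size=30)
            rho = sps.spearmanr(x, y).statistic
            r_ranks = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
            assert rho == pytest.approx(r_ranks, abs=1e-12)

    def test_weak_negative_correlation_recovery(self):
        """A joint generator with target rho = -0.15 is recovered on average
        across seeds (the magnitude of the threshold-ORr association)."""
        rhos = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=400)
            y = -0.15 * x + np.sqrt(1 - 0.15**2) * rng.normal(size=400)
            rhos.append(sps.spearmanr(x, y).statistic)
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos) - (-0.15)) <= 2 * se + 0.01

    def test_significance_stars(self):
        assert S.significance_stars(0.3) == "ns"
        assert S.significance_stars(0.03) == "*"
        assert S.significance_stars(0.004) == "**"
        assert S.significance_stars(5e-4) == "***"
        assert S.significance_stars(5e-5) == "****"
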