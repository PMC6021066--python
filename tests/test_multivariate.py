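"""Pool-mean imputation, normalisation, PCA and component ANOVAs."""

import numpy as np
import pandas as pd
import pytest

from phenodelim import (
    anova_on_components,
    impute_pool_means,
    pca,
    pca_by_pool,
    zscore,
)


class TestImputePoolMeans:
    def test_fills_with_pool_mean(self):
        m = pd.DataFrame({"x": [2.0, np.nan, 4.0]})
        out = impute_pool_means(m, ["A", "A", "A"])
        assert out["x"].tolist() == [2.0, 3.0, 4.0]

    def test_no_missing_is_identity(self):
        m = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]})
        out = impute_pool_means(m, ["A", "B"])
        pd.testing.assert_frame_equal(out, m)

    def test_disjoint_missingness_matches_brute_force(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("xyz"))
        pools = ["A"] * 6 + ["B"] * 6
        m.iloc[0, 0] = np.nan
        m.iloc[7, 2] = np.nan
        out = impute_pool_means(m, pools)
        # brute force: per pool per column mean over observed cells
        expect = m.copy()
        for col in m.columns:
            for pool in ("A", "B"):
                idx = [i for i, p in enumerate(pools) if p == pool]
                obs = [m.iloc[i][col] for i in idx if np.isfinite(m.iloc[i][col])]
                for i in idx:
                    if not np.isfinite(expect.iloc[i][col]):
                        expect.iloc[i, expect.columns.get_loc(col)] = np.mean(obs)
        pd.testing.assert_frame_equal(out, expect)

    def test_idempotent(self):
        m = pd.DataFrame({"x": [2.0, np.nan, 4.0], "y": [np.nan, 1.0, 2.0]})
        pools = ["A", "A", "B"]
        once = impute_pool_means(m, pools)
        twice = impute_pool_means(once, pools)
        pd.testing.assert_frame_equal(once, twice)

    def test_wholly_missing_pool_gets_global_mean(self):
        m = pd.DataFrame({"x": [1.0, 3.0, np.nan, np.nan]})
        with pytest.warns(UserWarning, match="global mean"):
            out = impute_pool_means(m, ["A", "A", "B", "B"])
        assert out["x"].tolist() == [1.0, 3.0, 2.0, 2.0]


class TestZscore:
    def test_closed_form(self):
        out = zscore(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out["x"].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(5, 3, size=(10, 2)))
        pd.testing.assert_frame_equal(zscore(zscore(m)), zscore(m))

    def test_zero_variance_column_names_character(self):
        with pytest.raises(ValueError, match="flat"):
            zscore(pd.DataFrame({"flat": [1.0, 1.0], "ok": [1.0, 2.0]}))

    def test_columns_standardised(self):
        rng = np.random.default_rng(2)
        out = zscore(pd.DataFrame(rng.normal(10, 4, size=(20, 5))))
        assert np.abs(out.mean()).max() < 1e-10
        assert np.allclose(out.std(ddof=1), 1.0)


class TestPca:
    def test_perfectly_correlated_columns(self):
        x = np.arange(10.0)
        res = pca(zscore(pd.DataFrame({"a": x, "b": 2 * x + 1})))
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_correlation_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3)) @ rng.normal(size=(3, 3))
        Z = zscore(pd.DataFrame(X))
        res = pca(Z)
        corr = np.corrcoef(np.asarray(X), rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        assert np.allclose(res.variance_explained * corr.shape[0], eigval[order], atol=1e-10)
        for j in range(3):
            dot = abs(res.loadings.iloc[:, j] @ eigvec[:, order[j]])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(4)
        Z = zscore(pd.DataFrame(rng.normal(size=(15, 4))))
        res = pca(Z)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + Z.to_numpy().mean(0)
        assert np.allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_variance_shares_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(5)
        res = pca(zscore(pd.DataFrame(rng.normal(size=(30, 6)))))
        v = res.variance_explained
        assert v.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(v) <= 1e-12)

    def test_column_permutation_invariance_up_to_sign(self):
        rng = np.random.default_rng(6)
        Z = zscore(pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd")))
        res1 = pca(Z)
        res2 = pca(Z[["c", "a", "d", "b"]])
        assert np.allclose(res1.variance_explained, res2.variance_explained, atol=1e-10)
        for j in range(4):
            dot = abs(
                res1.scores.iloc[:, j] @ res2.scores.iloc[:, j]
            ) / (np.linalg.norm(res1.scores.iloc[:, j]) * np.linalg.norm(res2.scores.iloc[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            pca(pd.DataFrame({"x": [1.0, np.nan]}))


class TestAnovaOnComponents:
    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        scores = pd.DataFrame({"PC1": np.concatenate([a, b])})
        pools = ["A"] * 30 + ["B"] * 30
        (res,), excluded = anova_on_components(scores, pools, min_pool=7)
        all_vals = scores["PC1"].to_numpy()
        grand = all_vals.mean()
        ss_between = 30 * (a.mean() - grand) ** 2 + 30 * (b.mean() - grand) ** 2
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_expect = (ss_between / 1) / (ss_within / 58)
        assert res.statistic == pytest.approx(f_expect, rel=1e-10)
        assert excluded == []

    def test_small_pool_is_excluded(self):
        rng = np.random.default_rng(8)
        sizes = {"novus": 2, "SAO": 29, "SIO": 38, "NZ": 121}
        pools, vals = [], []
        for pool, n in sizes.items():
            pools += [pool] * n
            vals += list(rng.normal(0, 1, n))
        results, excluded = anova_on_components(pd.DataFrame({"PC1": vals}), pools)
        assert excluded == ["novus"]
        assert results[0].df[0] == 2  # three groups retained

    def test_fewer_than_two_eligible_pools_errors(self):
        scores = pd.DataFrame({"PC1": np.arange(10.0)})
        with pytest.raises(ValueError):
            anova_on_components(scores, ["A"] * 8 + ["B"] * 2, min_pool=7)

    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, 60)
        (res,), _ = anova_on_components(
            pd.DataFrame({"PC1": vals}), ["A"] * 30 + ["B"] * 30, min_pool=7
        )
        assert res.p > 0.05


def test_separated_pools_give_significant_pc1(biometric_fixture):
    """On the moment-matched fixture the NZ pool separates on PC1."""
    res = pca_by_pool(biometric_fixture, "biometric")
    assert res.excluded_pools == ["novus"]
    assert res.anova[0].p < 0.001
    assert "tail_fork_depth" not in res.loadings.index
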