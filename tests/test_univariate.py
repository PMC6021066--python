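"""Per-character pool comparisons: ANOVA + Tukey, Kruskal–Wallis + Welch."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from phenodelim import (
    TestResult,
    anova_tukey,
    kruskal_pairwise,
    reference,
    significance_matrix,
)
from phenodelim.synthetic import PoolSpec, SyntheticSpec, fit_ordinal_probs, generate
from phenodelim.univariate import CharacterTestReport


def _kruskal_oracle(groups):
    """Tie-corrected rank H computed from the textbook formula."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = sps.rankdata(all_vals)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    h = 0.0
    for r in np.split(ranks, splits):
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestAnovaTukey:
    def test_outlying_group_detected(self):
        rep = anova_tukey(
            {"A": [1, 2, 3], "B": [1, 2, 3], "C": [11, 12, 13]}, min_pool=2
        )
        assert rep.omnibus.p < 0.001
        assert rep.pairwise[("A", "B")].p > 0.05
        assert rep.pairwise[("A", "C")].p < 0.05
        assert rep.pairwise[("B", "C")].p < 0.05

    def test_pairwise_p_matches_studentized_range(self):
        rng = np.random.default_rng(0)
        groups = {p: rng.normal(0, 1, n) for p, n in [("A", 9), ("B", 12), ("C", 10)]}
        rep = anova_tukey(groups, min_pool=2)
        # Tukey-Kramer by hand: q = |diff| / sqrt(MSE/2 (1/ni + 1/nj))
        k = len(groups)
        n_tot = sum(len(g) for g in groups.values())
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / (n_tot - k)
        for (a, b), res in rep.pairwise.items():
            ga, gb = groups[a], groups[b]
            q = abs(ga.mean() - gb.mean()) / math.sqrt(
                mse / 2 * (1 / ga.size + 1 / gb.size)
            )
            p = sps.studentized_range.sf(q, k, n_tot - k)
            assert res.p == pytest.approx(p, abs=1e-8)

    def test_pairwise_p_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(m, 1, 10) for m in (0.0, 0.6, 1.2)])
        labels = np.repeat(["A", "B", "C"], 10)
        rep = anova_tukey({p: vals[labels == p] for p in "ABC"}, min_pool=2)
        sm = pairwise_tukeyhsd(vals, labels)
        for (a, b), p_sm in zip(itertools.combinations("ABC", 2), sm.pvalues):
            assert rep.pairwise[(a, b)].p == pytest.approx(p_sm, abs=2e-3)

    def test_adjustment_never_anti_conservative(self):
        # compared with the unadjusted p of the same pooled-variance
        # contrast (pooled MSE, N-k df), which Tukey can only inflate
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = {p: rng.normal(rng.normal(0, 0.5), 1, 12) for p in "ABCD"}
            rep = anova_tukey(groups, min_pool=2)
            k = len(groups)
            n_tot = sum(g.size for g in groups.values())
            mse = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / (n_tot - k)
            for (a, b), res in rep.pairwise.items():
                ga, gb = groups[a], groups[b]
                t = abs(ga.mean() - gb.mean()) / math.sqrt(mse * (1 / ga.size + 1 / gb.size))
                plain = 2 * sps.t.sf(t, n_tot - k)
                assert res.p >= plain - 1e-12

    def test_single_eligible_pool_errors(self):
        with pytest.raises(ValueError):
            anova_tukey({"A": list(range(10)), "B": [1, 2]}, min_pool=7)

    def test_constant_data_errors(self):
        with pytest.raises(ValueError, match="identical"):
            anova_tukey({"A": [2.0] * 8, "B": [2.0] * 8}, min_pool=7)


class TestKruskalPairwise:
    def test_constant_scores_degenerate_to_null(self):
        rep = kruskal_pairwise({"A": [2] * 8, "B": [2] * 8}, min_pool=7)
        assert rep.omnibus.statistic == 0.0
        assert rep.omnibus.p == 1.0
        assert all(t.p == 1.0 for t in rep.pairwise.values())

    def test_matches_tie_corrected_rank_formula(self):
        groups = {"A": [1, 1, 2], "B": [1, 2, 2], "C": [4, 4, 4]}
        rep = kruskal_pairwise(groups, min_pool=2)
        h = _kruskal_oracle([np.asarray(groups[p], float) for p in "ABC"])
        assert rep.omnibus.statistic == pytest.approx(h, abs=1e-10)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        groups = {p: rng.integers(1, 5, 15).astype(float) for p in "ABC"}
        h0 = kruskal_pairwise(groups, min_pool=2).omnibus.statistic
        squared = {p: g**2 for p, g in groups.items()}
        assert kruskal_pairwise(squared, min_pool=2).omnibus.statistic == pytest.approx(h0)

    def test_relabeling_permutes_pairwise_results(self):
        rng = np.random.default_rng(4)
        groups = {p: rng.integers(1, 5, 12).astype(float) for p in ("X", "Y", "Z")}
        rep = kruskal_pairwise(groups, min_pool=2)
        swapped = kruskal_pairwise(
            {"Z": groups["Z"], "Y": groups["Y"], "X": groups["X"]}, min_pool=2
        )
        for (a, b), t in rep.pairwise.items():
            t2 = swapped.pairwise.get((a, b)) or swapped.pairwise[(b, a)]
            assert t2.p == pytest.approx(t.p, abs=1e-12)
            assert abs(t2.statistic) == pytest.approx(abs(t.statistic), abs=1e-12)

    def test_collar_extent_structure_is_detected(self):
        """Ordinal pools shaped like the published collar-extent summaries
        separate decisively in nearly every replicate."""
        summaries = reference.summary_stats("plumage")["collar_extent"]
        probs = {
            pool: fit_ordinal_probs(s.mean, s.sd, 4)
            for pool, s in summaries.items()
            if pool != "novus"
        }
        hits = 0
        seeds = range(20)
        for seed in seeds:
            rng = np.random.default_rng(1000 + seed)
            groups = {
                pool: rng.choice(np.arange(1, 5), size=summaries[pool].n, p=p).astype(float)
                for pool, p in probs.items()
            }
            rep = kruskal_pairwise(groups, min_pool=7)
            hits += rep.omnibus.p < 0.001
        assert hits >= 19


class TestSignificanceMatrix:
    def _report(self, p):
        t = TestResult(2.0, 10.0, p, "tukey_hsd")
        return CharacterTestReport("wing_length", t, {("SAO", "NZ"): t})

    def test_strictly_below_alpha(self):
        gate = significance_matrix({"wing_length": self._report(0.049)})
        assert gate[("wing_length", "SAO", "NZ")] is True
        assert gate[("wing_length", "NZ", "SAO")] is True

    def test_boundary_p_equal_alpha_is_not_significant(self):
        gate = significance_matrix({"wing_length": self._report(0.05)})
        assert gate[("wing_length", "SAO", "NZ")] is False

    def test_fixture_reproduces_published_separations(self, biometric_fixture):
        """SAO vs NZ separates on wing, T6, bill depth, head and tarsus."""
        from phenodelim import compare_characters

        chars = ["wing_length", "t6_length", "bill_depth", "head_length", "tarsus_length"]
        reports = compare_characters(biometric_fixture, chars)
        gate = significance_matrix(reports)
        for c in chars:
            assert gate[(c, "SAO", "NZ")], c
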