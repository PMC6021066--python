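"""Per-character differentiation tests between population pools.

Continuous (biometric) characters: one-factor ANOVA across pools followed
by Tukey HSD for all retained pool pairs. Ordinal (plumage) characters:
Kruskal–Wallis rank-sum omnibus (with the standard tie correction, which
matters for heavily tied ordinal scores) followed by pairwise two-sided
Welch t-tests on the raw scores, uncorrected by default. Pools below the
minimum sample size are excluded per character, since per-character n
varies after specimen-type exclusions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset import SpecimenRecord, TestResult, stars
from .multivariate import MIN_POOL
from .specimen_bias import welch_t


@dataclass
class CharacterTestReport:
    """Omnibus and pairwise test results for one character."""

    character: str
    omnibus: TestResult
    pairwise: dict[tuple[str, str], TestResult] = field(default_factory=dict)
    excluded_pools: list[str] = field(default_factory=list)


def _eligible(
    values_by_pool: Mapping[str, Sequence[float]], min_pool: int
) -> tuple[dict[str, np.ndarray], list[str]]:
    eligible: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for pool, vals in values_by_pool.items():
        arr = np.asarray([v for v in vals if v is not None and np.isfinite(v)], float)
        if arr.size >= max(min_pool, 2):
            eligible[pool] = arr
        else:
            excluded.append(pool)
    return eligible, excluded


def anova_tukey(
    values_by_pool: Mapping[str, Sequence[float]],
    min_pool: int = MIN_POOL,
    character: str = "",
) -> CharacterTestReport:
    """One-factor ANOVA omnibus plus Tukey HSD pairwise comparisons.

    Tukey p-values are family-wise adjusted over the retained pools. Raises
    if fewer than two pools are eligible or all retained values coincide.
    """
    eligible, excluded = _eligible(values_by_pool, min_pool)
    if len(eligible) < 2:
        raise ValueError(
            f"{character or 'character'}: fewer than 2 pools with n >= {min_pool}"
        )
    pools = list(eligible)
    groups = [eligible[p] for p in pools]
    if np.ptp(np.concatenate(groups)) == 0:
        raise ValueError(f"{character or 'character'}: all retained values identical")
    f, p = stats.f_oneway(*groups)
    n_tot = sum(g.size for g in groups)
    omnibus = TestResult(
        statistic=float(f),
        df=(float(len(groups) - 1), float(n_tot - len(groups))),
        p=float(p),
        test_name="anova",
    )
    hsd = stats.tukey_hsd(*groups)
    pairwise = {}
    for i, j in itertools.combinations(range(len(pools)), 2):
        pairwise[(pools[i], pools[j])] = TestResult(
            statistic=float(hsd.statistic[i, j]),
            df=float(n_tot - len(groups)),
            p=float(min(1.0, hsd.pvalue[i, j])),
            test_name="tukey_hsd",
        )
    return CharacterTestReport(
        character=character, omnibus=omnibus, pairwise=pairwise, excluded_pools=excluded
    )


def kruskal_pairwise(
    scores_by_pool: Mapping[str, Sequence[float]],
    min_pool: int = MIN_POOL,
    character: str = "",
    correction: Literal["none", "holm"] = "none",
) -> CharacterTestReport:
    """Kruskal–Wallis omnibus plus pairwise Welch t-tests on raw scores.

    The omnibus H uses the standard tie-correction; an all-constant input
    degenerates to H = 0, p = 1 by convention. Pairwise Welch p-values are
    uncorrected by default ("holm" applies a Holm adjustment across pairs).
    """
    eligible, excluded = _eligible(scores_by_pool, min_pool)
    if len(eligible) < 2:
        raise ValueError(
            f"{character or 'character'}: fewer than 2 pools with n >= {min_pool}"
        )
    pools = list(eligible)
    groups = [eligible[p] for p in pools]
    if np.ptp(np.concatenate(groups)) == 0:
        omnibus = TestResult(
            statistic=0.0, df=float(len(groups) - 1), p=1.0, test_name="kruskal"
        )
        pairwise = {
            (pools[i], pools[j]): TestResult(0.0, float(len(groups[i]) + len(groups[j]) - 2), 1.0, "welch_t")
            for i, j in itertools.combinations(range(len(pools)), 2)
        }
        return CharacterTestReport(character, omnibus, pairwise, excluded)
    h, p = stats.kruskal(*groups)
    omnibus = TestResult(
        statistic=float(h), df=float(len(groups) - 1), p=float(p), test_name="kruskal"
    )
    pairs = list(itertools.combinations(range(len(pools)), 2))
    results = [welch_t(groups[i], groups[j]) for i, j in pairs]
    if correction == "holm":
        padj = _holm_adjust(np.array([r.p for r in results]))
        results = [
            TestResult(r.statistic, r.df, float(q), r.test_name)
            for r, q in zip(results, padj)
        ]
    pairwise = {(pools[i], pools[j]): r for (i, j), r in zip(pairs, results)}
    return CharacterTestReport(character, omnibus, pairwise, excluded)


def _holm_adjust(pvals: np.ndarray) -> np.ndarray:
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_characters(
    records: Sequence[SpecimenRecord],
    characters: Sequence[str],
    ordinal: Mapping[str, bool] | None = None,
    min_pool: int = MIN_POOL,
) -> dict[str, CharacterTestReport]:
    """Run the appropriate per-character test for each listed character.

    ``ordinal[c]`` selects Kruskal–Wallis + Welch for ordinal characters,
    ANOVA + Tukey otherwise. Characters whose data cannot support a test
    (e.g. fewer than two eligible pools) are skipped with a warning.
    """
    reports: dict[str, CharacterTestReport] = {}
    for c in characters:
        by_pool: dict[str, list[float]] = {}
        for r in records:
            if r.pool is not None and c in r.values:
                by_pool.setdefault(r.pool, []).append(r.values[c])
        is_ord = bool(ordinal.get(c)) if ordinal else False
        try:
            if is_ord:
                reports[c] = kruskal_pairwise(by_pool, min_pool=min_pool, character=c)
            else:
                reports[c] = anova_tukey(by_pool, min_pool=min_pool, character=c)
        except ValueError as exc:
            warnings.warn(str(exc))
    return reports


def significance_matrix(
    reports: Mapping[str, CharacterTestReport], alpha: float = 0.05
) -> dict[tuple[str, str, str], bool]:
    """(character, poolA, poolB) → pairwise adjusted p strictly below alpha.

    This gate feeds delimitation scoring: characters whose pools do not
    differ significantly carry no effect-size score.
    """
    gate: dict[tuple[str, str, str], bool] = {}
    for c, rep in reports.items():
        for (a, b), t in rep.pairwise.items():
            decision = t.p < alpha
            gate[(c, a, b)] = decision
            gate[(c, b, a)] = decision
    return gate


def report_stars(report: CharacterTestReport) -> dict[tuple[str, str], str]:
    """Pairwise significance stars for table output."""
    return {pair: stars(t.p) for pair, t in report.pairwise.items()}
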