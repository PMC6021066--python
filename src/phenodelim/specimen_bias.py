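"""Live-bird vs study-skin measurement bias screening.

Museum study skins shrink as they dry (biometrics measure short) and their
plumage fades (colour scores drift), so characters measured on a mixture of
live birds and skins can carry a systematic specimen-type bias. Each
character is screened with a two-sided Welch two-sample t-test between live
and skin values inside a single reference pool — the pool with both
specimen types and the largest sample, so that population differences
cannot masquerade as specimen-type effects. Characters that test biased
have one specimen class excluded outright (masked to missing) rather than
corrected: the class retained is the one with records from every pool, so
that between-pool comparisons stay possible for the character.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset import SpecimenRecord, TestResult


@dataclass(frozen=True)
class BiasFlag:
    """Screening outcome for one character."""

    character: str
    test: TestResult
    biased: bool
    excluded_class: Literal["live", "skin", "none"]

    def __post_init__(self) -> None:
        if self.excluded_class != "none" and not self.biased:
            raise ValueError("excluded_class set on an unbiased character")


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Welch two-sample t-test with Welch–Satterthwaite df.

    Requires at least two observations per sample. If both samples have
    zero variance and equal means the test is degenerate and p = 1 by
    convention (t = 0); zero variance with unequal means gives p = 0.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        equal = a.mean() == b.mean()
        return TestResult(
            statistic=0.0 if equal else math.inf,
            df=float(a.size + b.size - 2),
            p=1.0 if equal else 0.0,
            test_name="welch_t",
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        test_name="welch_t",
    )


def _classes_missing_from_some_pool(
    records: Sequence[SpecimenRecord], character: str
) -> set[str]:
    """Specimen classes with no value for `character` in at least one pool."""
    pools = sorted({r.pool for r in records if r.pool is not None})
    present: dict[str, set[str]] = {p: set() for p in pools}
    for r in records:
        if r.pool is not None and character in r.values:
            present[r.pool].add(r.specimen_type)
    missing: set[str] = set()
    for p in pools:
        for cls in ("live", "skin"):
            if cls not in present[p]:
                missing.add(cls)
    return missing


def screen_specimen_type_bias(
    records: Sequence[SpecimenRecord],
    characters: Iterable[str] | None = None,
    reference_pool: str = "NZ",
    alpha: float = 0.05,
    correction: Literal["none", "holm"] = "none",
) -> list[BiasFlag]:
    """Screen characters for live-vs-skin bias within a reference pool.

    One flag per testable character (>= 2 live and >= 2 skin values in the
    reference pool; others are skipped with a warning). With
    ``correction="holm"`` the p-values are Holm-adjusted across the screened
    characters before the alpha decision; the default is per-character
    decisions with no correction. For each biased character the excluded
    class is the one absent from at least one pool (defaulting to "live"
    when both classes occur everywhere, since skin series typically have
    the wider site coverage).
    """
    if characters is None:
        chars: list[str] = sorted({c for r in records for c in r.values})
    else:
        chars = list(characters)
    ref = [r for r in records if r.pool == reference_pool]
    if not ref:
        raise ValueError(f"reference pool {reference_pool!r} has no records")

    tested: list[tuple[str, TestResult]] = []
    for c in chars:
        live = [r.values[c] for r in ref if r.specimen_type == "live" and c in r.values]
        skin = [r.values[c] for r in ref if r.specimen_type == "skin" and c in r.values]
        if len(live) < 2 or len(skin) < 2:
            warnings.warn(
                f"{c}: fewer than 2 live or skin observations in pool "
                f"{reference_pool}; skipped"
            )
            continue
        tested.append((c, welch_t(live, skin)))

    pvals = np.array([t.p for _, t in tested])
    if correction == "holm" and pvals.size:
        decide = _holm_reject(pvals, alpha)
    else:
        decide = pvals < alpha

    flags: list[BiasFlag] = []
    for (c, test), biased in zip(tested, decide):
        if biased:
            missing = _classes_missing_from_some_pool(records, c)
            excluded = "live" if ("live" in missing or not missing) else "skin"
        else:
            excluded = "none"
        flags.append(BiasFlag(character=c, test=test, biased=bool(biased), excluded_class=excluded))
    return flags


def _holm_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down rejection decisions for a vector of p-values."""
    m = pvals.size
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] < alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def apply_exclusions(
    records: Iterable[SpecimenRecord],
    flags: Iterable[BiasFlag],
    verbose: bool = False,
) -> list[SpecimenRecord]:
    """Mask values of biased characters for their excluded specimen class.

    Values are never altered, only removed; everything else is untouched.
    Returns new records. Flags naming characters absent from the dataset
    are no-ops with a warning.
    """
    records = list(records)
    excl: Mapping[str, str] = {
        f.character: f.excluded_class for f in flags if f.biased and f.excluded_class != "none"
    }
    present = {c for r in records for c in r.values}
    for c in excl:
        if c not in present:
            warnings.warn(f"exclusion flag for {c!r}, which is absent from the dataset")
    removed: dict[str, int] = {c: 0 for c in excl}
    out: list[SpecimenRecord] = []
    for r in records:
        values = dict(r.values)
        for c, cls in excl.items():
            if r.specimen_type == cls and c in values:
                del values[c]
                removed[c] += 1
        out.append(replace(r, values=values))
    if verbose:
        for c, k in removed.items():
            warnings.warn(f"excluded {k} {excl[c]} value(s) of {c}")
    return out
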