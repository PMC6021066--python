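"""Quantitative species-delimitation scoring (Tobias criteria).

Each character contrast between two population pools earns an integer
score. Continuous characters are scored by binning the absolute pooled-SD
Cohen's d effect size:

    |d| < 0.2        → 0 (no score)
    0.2 ≤ |d| < 2.0  → 1 (weak)
    2.0 ≤ |d| < 5.0  → 2 (medium)
    5.0 ≤ |d| < 10.0 → 3 (strong)
    |d| ≥ 10.0       → 4 (exceptional)

and only characters passing the pairwise significance gate score at all.
Plumage characters are expert-scored on the same 1–4 magnitude scale;
behavioural/ecological contrasts can score at most 1. The decision sums
the two largest biometric scores, the three largest plumage scores and
the behavioural score; species rank is supported when the total reaches
the threshold (7 by default).

Cohen's d here uses the pooled sample SD with no small-sample (Hedges)
correction, the convention of the R ``effsize`` package. When only
published summary statistics are available, per-pool SDs are reconstructed
as SE·√n and pooled the same way, which reproduces the raw-data d exactly
for complete samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .characters import CharClass
from .dataset import SummaryStat

TOBIAS_BIN_EDGES = (0.2, 2.0, 5.0, 10.0)
DEFAULT_THRESHOLD = 7


@dataclass(frozen=True)
class EffectSize:
    """Signed pooled-SD Cohen's d for one character between two pools."""

    character: str
    pool_a: str
    pool_b: str
    d: float
    source: Literal["raw", "summary"]

    @property
    def abs_d(self) -> float:
        return abs(self.d)

    def swapped(self) -> "EffectSize":
        return EffectSize(self.character, self.pool_b, self.pool_a, -self.d, self.source)


@dataclass(frozen=True)
class CharacterScore:
    """One character's delimitation score for a pool contrast."""

    character: str
    char_class: CharClass
    score: int
    gated: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.score <= 4):
            raise ValueError("score must be in 0..4")
        if self.char_class is CharClass.BEHAVIORAL and self.score > 1:
            raise ValueError("behavioral characters can score at most 1")


@dataclass(frozen=True)
class DelimitationResult:
    """Class-wise top-k sums, total and the species decision."""

    pool_a: str
    pool_b: str
    biometric_sum: int
    plumage_sum: int
    behavioral: int
    total: int
    threshold: int
    is_species: bool


def _pooled_sd(n_a: int, sd_a: float, n_b: int, sd_b: float) -> float:
    num = (n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2
    return math.sqrt(num / (n_a + n_b - 2))


def cohens_d_raw(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    character: str = "",
    pool_a: str = "a",
    pool_b: str = "b",
) -> EffectSize:
    """Pooled-SD Cohen's d from raw samples (n ≥ 2 each, no correction)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d_raw needs >= 2 observations per sample")
    sp = _pooled_sd(a.size, a.std(ddof=1), b.size, b.std(ddof=1))
    if sp == 0.0:
        raise ValueError("zero pooled variance; d undefined")
    return EffectSize(character, pool_a, pool_b, float((a.mean() - b.mean()) / sp), "raw")


def cohens_d_from_summary(stat_a: SummaryStat, stat_b: SummaryStat) -> EffectSize:
    """Cohen's d reconstructed from (mean, SE, n) summaries.

    Per-pool SD = SE·√n, then pooled exactly as for raw samples.
    """
    for s in (stat_a, stat_b):
        if s.n < 2:
            raise ValueError(f"{s.character}/{s.pool}: n >= 2 required")
        if s.se is None:
            raise ValueError(f"{s.character}/{s.pool}: SE missing")
    sp = _pooled_sd(stat_a.n, stat_a.sd, stat_b.n, stat_b.sd)
    if sp == 0.0:
        raise ValueError("zero pooled variance; d undefined")
    return EffectSize(
        stat_a.character,
        stat_a.pool,
        stat_b.pool,
        float((stat_a.mean - stat_b.mean) / sp),
        "summary",
    )


def tobias_bin(effect: EffectSize | float) -> int:
    """Map |d| to its 0–4 effect-size score.

    The published ranges share endpoints, so a half-open convention is
    required; bins are [lo, hi), keeping "d > 10 → 4" exact and the step
    function monotone (d = 2.0 scores 2).
    """
    abs_d = effect.abs_d if isinstance(effect, EffectSize) else abs(float(effect))
    if not math.isfinite(abs_d):
        raise ValueError("effect size must be finite")
    score = 0
    for edge in TOBIAS_BIN_EDGES:
        if abs_d >= edge:
            score += 1
    return score


def score_biometrics(
    effects: Iterable[EffectSize],
    significance_gate: Mapping[str, bool],
) -> list[CharacterScore]:
    """Score biometric effect sizes subject to the significance gate.

    ``significance_gate[character]`` must cover every effect's character;
    non-significant characters score 0 (gated = False).
    """
    scores = []
    for e in effects:
        if e.character not in significance_gate:
            raise ValueError(f"significance gate missing character {e.character!r}")
        ok = bool(significance_gate[e.character])
        scores.append(
            CharacterScore(
                character=e.character,
                char_class=CharClass.BIOMETRIC,
                score=tobias_bin(e) if ok else 0,
                gated=ok,
            )
        )
    return scores


def max_cumulative(scores: Iterable[int | CharacterScore], k: int) -> int:
    """Sum of the k largest scores (all of them if fewer than k)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    vals = sorted(
        (s.score if isinstance(s, CharacterScore) else int(s) for s in scores),
        reverse=True,
    )
    if any(v < 0 for v in vals):
        raise ValueError("scores must be non-negative")
    return sum(vals[:k])


def delimit(
    biometric_scores: Iterable[int | CharacterScore],
    plumage_scores: Iterable[int | CharacterScore],
    behavioral_score: int,
    threshold: int = DEFAULT_THRESHOLD,
    pool_a: str = "a",
    pool_b: str = "b",
    strict: bool = False,
) -> DelimitationResult:
    """Combine class-wise scores into the species decision.

    total = top-2 biometric + top-3 plumage + behavioral; species status is
    supported when total ≥ threshold (or > threshold with ``strict=True``).
    """
    if behavioral_score not in (0, 1):
        raise ValueError("behavioral score must be 0 or 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    bio = max_cumulative(biometric_scores, 2)
    plu = max_cumulative(plumage_scores, 3)
    total = bio + plu + behavioral_score
    decided = total > threshold if strict else total >= threshold
    return DelimitationResult(
        pool_a=pool_a,
        pool_b=pool_b,
        biometric_sum=bio,
        plumage_sum=plu,
        behavioral=behavioral_score,
        total=total,
        threshold=threshold,
        is_species=decided,
    )
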