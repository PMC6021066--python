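"""Synthetic specimen datasets with the structure the pipeline assumes.

Two generators are provided. ``generate`` draws fresh datasets from a
parametric description of the study conditions: allopatric population
pools of fixed sizes with a live/skin mixture, truncated-normal biometric
characters, categorical ordinal plumage scores, additive shrinkage/fading
offsets applied to study skins on a subset of characters, and
missing-at-random values. ``fixture_from_summary`` reconstructs a dataset
from published per-pool summary statistics by drawing values and affinely
rescaling them so the sample mean and sample SD match the printed mean and
SE·√n exactly — a moment-matched stand-in for raw data that were never
deposited.

Randomness is reproducible from a single root seed; each (pool, character)
pair gets its own derived stream (stable string hashing), so adding a
character to a spec never perturbs the draws of the others.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .characters import CharacterDefinition, DEFAULT_CHARACTER_MAP, Scale
from .dataset import SpecimenRecord, SummaryStat


def _rng(seed: int, *keys: str) -> np.random.Generator:
    """Independent, stable stream for (seed, keys)."""
    spawn = tuple(zlib.crc32(k.encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


@dataclass(frozen=True)
class PoolSpec:
    label: str
    n: int
    live_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"pool {self.label}: n must be >= 1")
        if not (0.0 <= self.live_fraction <= 1.0):
            raise ValueError(f"pool {self.label}: live_fraction outside [0, 1]")


@dataclass
class SyntheticSpec:
    """Parametric description of a synthetic specimen dataset.

    ``continuous_params[(pool, char)]`` is (mean, sd) of a normal truncated
    to the character's valid range; ``ordinal_params[(pool, char)]`` are
    category probabilities over scores 1..K. ``shrinkage``/``fading`` map
    characters to additive offsets applied to study skins only (ordinal
    results are rounded and clipped back into 1..K).
    """

    pools: list[PoolSpec]
    continuous_params: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    ordinal_params: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)
    shrinkage: dict[str, float] = field(default_factory=dict)
    fading: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for (pool, char), (_, sd) in self.continuous_params.items():
            if sd <= 0:
                raise ValueError(f"{pool}/{char}: sd must be > 0")
        for (pool, char), probs in self.ordinal_params.items():
            p = np.asarray(probs, float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"{pool}/{char}: probabilities must be a distribution")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        pools = [PoolSpec(p["label"], int(p["n"]), float(p.get("live_fraction", 0.0)))
                 for p in d["pools"]]
        cont = {
            (pool, char): (float(v["mean"]), float(v["sd"]))
            for pool, chars in d.get("continuous", {}).items()
            for char, v in chars.items()
        }
        ordi = {
            (pool, char): tuple(float(x) for x in probs)
            for pool, chars in d.get("ordinal", {}).items()
            for char, probs in chars.items()
        }
        return cls(
            pools=pools,
            continuous_params=cont,
            ordinal_params=ordi,
            shrinkage={k: float(v) for k, v in d.get("shrinkage", {}).items()},
            fading={k: float(v) for k, v in d.get("fading", {}).items()},
            missing_rate=float(d.get("missing_rate", 0.0)),
            seed=int(d.get("seed", 0)),
        )


def generate(
    spec: SyntheticSpec,
    definitions: Mapping[str, CharacterDefinition] | None = None,
) -> list[SpecimenRecord]:
    """Draw a specimen dataset from a spec; fully reproducible from seed."""
    defs = definitions if definitions is not None else DEFAULT_CHARACTER_MAP
    records: list[SpecimenRecord] = []
    for pool in spec.pools:
        n = pool.n
        n_live = int(round(n * pool.live_fraction))
        types = np.array(["live"] * n_live + ["skin"] * (n - n_live))
        types = types[_rng(spec.seed, pool.label, "types").permutation(n)]
        values_by_char: dict[str, np.ndarray] = {}
        missing_by_char: dict[str, np.ndarray] = {}

        for (p, char), (mean, sd) in spec.continuous_params.items():
            if p != pool.label:
                continue
            d = defs.get(char)
            lo, hi = d.valid_range if d else (-math.inf, math.inf)
            rng = _rng(spec.seed, pool.label, char, "draw")
            a, b = (lo - mean) / sd, (hi - mean) / sd
            vals = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
            if char in spec.shrinkage:
                skins = types == "skin"
                shifted = vals[skins] + spec.shrinkage[char]
                out_of_range = (shifted < lo) | (shifted > hi)
                if skins.sum() and out_of_range.mean() > 0.5:
                    raise ValueError(
                        f"{pool.label}/{char}: shrinkage offset pushes "
                        ">50% of skin draws outside the valid range"
                    )
                vals[skins] = np.clip(shifted, lo, hi)
            values_by_char[char] = vals

        for (p, char), probs in spec.ordinal_params.items():
            if p != pool.label:
                continue
            k = len(probs)
            rng = _rng(spec.seed, pool.label, char, "draw")
            vals = rng.choice(np.arange(1, k + 1), size=n, p=np.asarray(probs, float))
            vals = vals.astype(float)
            if char in spec.fading:
                skins = types == "skin"
                vals[skins] = np.clip(np.rint(vals[skins] + spec.fading[char]), 1, k)
            values_by_char[char] = vals

        for char in values_by_char:
            rng = _rng(spec.seed, pool.label, char, "missing")
            missing_by_char[char] = rng.random(n) < spec.missing_rate

        for i in range(n):
            vals = {
                char: float(arr[i])
                for char, arr in values_by_char.items()
                if not missing_by_char[char][i]
            }
            records.append(
                SpecimenRecord(
                    specimen_id=f"{pool.label}-{i:03d}",
                    origin=pool.label,
                    specimen_type=str(types[i]),
                    pool=pool.label,
                    values=vals,
                )
            )
    return records


def fixture_from_summary(
    summary: Mapping[str, Mapping[str, SummaryStat]],
    seed: int = 0,
    specimen_type: str = "skin",
) -> list[SpecimenRecord]:
    """Moment-matched specimen records from per-(character, pool) summaries.

    For each (pool, character) with n ≥ 2, draws n values and affinely
    rescales them so the sample mean and sample SD (n−1) equal the printed
    mean and SE·√n exactly; rows with n = 1 get the mean as a single value
    (flagged with a warning). When a character's n is below the pool size,
    the values land on a seed-determined random subset of the pool's
    records, emulating missing-at-random coverage. Printed min/max are not
    enforced.
    """
    pool_sizes: dict[str, int] = {}
    for char, by_pool in summary.items():
        for pool, s in by_pool.items():
            pool_sizes[pool] = max(pool_sizes.get(pool, 0), s.n)

    values: dict[str, dict[str, dict[int, float]]] = {p: {} for p in pool_sizes}
    for char, by_pool in summary.items():
        for pool, s in by_pool.items():
            if s.n == 1:
                warnings.warn(f"{char}/{pool}: n = 1, fixture value set to the mean")
                vals = np.array([s.mean])
            else:
                if s.se is None:
                    raise ValueError(f"{char}/{pool}: SE required for n >= 2")
                rng = _rng(seed, pool, char, "fixture")
                z = rng.standard_normal(s.n)
                sz = z.std(ddof=1)
                while sz == 0.0:  # vanishingly unlikely; redraw for safety
                    z = rng.standard_normal(s.n)
                    sz = z.std(ddof=1)
                target_sd = s.se * math.sqrt(s.n)
                vals = s.mean + (z - z.mean()) * (target_sd / sz)
            rows = _rng(seed, pool, char, "rows").permutation(pool_sizes[pool])[: s.n]
            values[pool][char] = {int(r): float(v) for r, v in zip(sorted(rows), vals)}

    records: list[SpecimenRecord] = []
    for pool in sorted(pool_sizes):
        for i in range(pool_sizes[pool]):
            vals = {
                char: rowmap[i]
                for char, rowmap in values[pool].items()
                if i in rowmap
            }
            records.append(
                SpecimenRecord(
                    specimen_id=f"{pool}-{i:03d}",
                    origin=pool,
                    specimen_type=specimen_type,
                    pool=pool,
                    values=vals,
                )
            )
    return records


def inject_bias(
    records: Iterable[SpecimenRecord],
    character: str,
    offset: float,
    target_class: str,
    definitions: Mapping[str, CharacterDefinition] | None = None,
) -> list[SpecimenRecord]:
    """Add an offset to one character for one specimen class.

    Ordinal characters are rounded and clipped back into 1..K. Used to
    create known shrinkage/fading signals for parameter-recovery tests.
    """
    if target_class not in ("live", "skin"):
        raise ValueError("target_class must be 'live' or 'skin'")
    defs = definitions if definitions is not None else DEFAULT_CHARACTER_MAP
    d = defs.get(character)
    out = []
    for r in records:
        if r.specimen_type == target_class and character in r.values:
            v = r.values[character] + offset
            if d is not None and d.scale is Scale.ORDINAL:
                v = float(np.clip(np.rint(v), 1, d.ordinal_levels))
            vals = dict(r.values)
            vals[character] = v
            out.append(replace(r, values=vals))
        else:
            out.append(r)
    return out


def fit_ordinal_probs(mean: float, sd: float, k: int) -> tuple[float, ...]:
    """Category probabilities over 1..K matching a target mean and SD.

    Uses a discretised-normal family (normal density integrated over
    half-integer cells, tails absorbed into the end categories) and tunes
    its location and scale by least squares on (mean, SD). Exact ordinal
    moment-matching is impossible in general; the fit is typically within
    a few hundredths on both moments for the scales used here.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    levels = np.arange(1, k + 1)
    if sd < 1e-6:
        probs = np.zeros(k)
        probs[int(np.clip(round(mean), 1, k)) - 1] = 1.0
        return tuple(probs)

    def probs_of(mu: float, sigma: float) -> np.ndarray:
        edges = np.concatenate(([-np.inf], levels[:-1] + 0.5, [np.inf]))
        cdf = stats.norm.cdf(edges, loc=mu, scale=sigma)
        p = np.diff(cdf)
        return p / p.sum()

    def loss(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        p = probs_of(mu, math.exp(log_sigma))
        m = float(p @ levels)
        v = float(p @ (levels - m) ** 2)
        return (m - mean) ** 2 + (math.sqrt(v) - sd) ** 2

    res = optimize.minimize(
        loss, x0=np.array([mean, math.log(max(sd, 0.2))]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    return tuple(probs_of(res.x[0], math.exp(res.x[1])))
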