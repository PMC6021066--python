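"""Specimen records, delimited-text IO, pooling and summary statistics.

The on-disk format is a plain comma-delimited table with a header row, one
row per specimen: the metadata columns ``specimen_id``, ``origin``,
``pool`` (optional), ``specimen_type`` (live/skin), ``sex`` (optional),
followed by one column per character. Empty cells are missing values.
Values are validated against the character definitions on read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .characters import (
    CharacterDefinition,
    DEFAULT_CHARACTER_MAP,
    DEFAULT_POOL_MAP,
    normalize_origin,
)

META_COLUMNS = ("specimen_id", "origin", "pool", "specimen_type", "sex")

SPECIMEN_TYPES = ("live", "skin")


@dataclass
class SpecimenRecord:
    """One measured individual with a partial character → value map."""

    specimen_id: str
    origin: str
    specimen_type: str
    pool: str | None = None
    sex: str | None = None
    values: dict[str, float] = field(default_factory=dict)

    def get(self, character: str) -> float | None:
        return self.values.get(character)


@dataclass(frozen=True)
class SummaryStat:
    """Per-pool summary of one character: mean ± SE (min–max; n).

    ``se`` is the standard error of the mean, sample SD (n−1 denominator)
    over √n; it is ``None`` when n = 1 (undefined, stored as missing).
    """

    character: str
    pool: str
    mean: float
    se: float | None
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"{self.character}/{self.pool}: mean outside [min, max]")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be >= 0")
        if self.n == 1 and self.se is not None:
            raise ValueError("se is undefined for n = 1; store as None")

    @property
    def sd(self) -> float | None:
        """Sample SD reconstructed as se·√n."""
        return None if self.se is None else self.se * math.sqrt(self.n)

    def format(self) -> str:
        se = "NA" if self.se is None else f"{self.se:.2f}"
        return f"{self.mean:.2f} ± {se} ({self.min:g}–{self.max:g}; {self.n})"


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def stars(p: float) -> str:
    """Conventional significance stars: * < 0.05, ** < 0.01, *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# IO

def read_dataset(
    source,
    definitions: Mapping[str, CharacterDefinition] | None = None,
) -> list[SpecimenRecord]:
    """Read a CSV measurement table into validated specimen records.

    Unknown character columns raise; out-of-range values raise with the
    specimen id and character named. Empty cells become missing values.
    """
    defs = definitions if definitions is not None else DEFAULT_CHARACTER_MAP
    df = pd.read_csv(source, dtype=str)
    unknown = [c for c in df.columns if c not in META_COLUMNS and c not in defs]
    if unknown:
        raise ValueError(f"unknown character column(s): {', '.join(unknown)}")
    if "specimen_id" not in df.columns:
        raise ValueError("missing required column: specimen_id")

    char_cols = [c for c in df.columns if c in defs]
    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"])
        values: dict[str, float] = {}
        for c in char_cols:
            raw = row[c]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                continue
            try:
                values[c] = defs[c].validate_value(float(raw))
            except ValueError as exc:
                raise ValueError(f"specimen {sid}: {exc}") from exc
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                origin=_opt(row.get("origin")) or "",
                specimen_type=_opt(row.get("specimen_type")) or "",
                pool=_opt(row.get("pool")),
                sex=_opt(row.get("sex")),
                values=values,
            )
        )
    return records


def _opt(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def to_frame(
    records: Sequence[SpecimenRecord],
    definitions: Mapping[str, CharacterDefinition] | None = None,
) -> pd.DataFrame:
    """Specimens as a DataFrame: metadata columns then character columns."""
    defs = definitions if definitions is not None else DEFAULT_CHARACTER_MAP
    present = [c for c in defs if any(c in r.values for r in records)]
    rows = []
    for r in records:
        row: dict[str, object] = {
            "specimen_id": r.specimen_id,
            "origin": r.origin,
            "pool": r.pool,
            "specimen_type": r.specimen_type,
            "sex": r.sex,
        }
        for c in present:
            row[c] = r.values.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + present)


def write_dataset(
    records: Sequence[SpecimenRecord],
    path,
    definitions: Mapping[str, CharacterDefinition] | None = None,
) -> None:
    """Write records to CSV; missing values become empty cells."""
    to_frame(records, definitions).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pooling and derived characters

def assign_pools(
    records: Iterable[SpecimenRecord],
    origin_to_pool: Mapping[str, str] | None = None,
) -> list[SpecimenRecord]:
    """Assign each record to a population pool from its origin.

    The default map pools South Georgia and the Southern Atlantic Ocean as
    SAO; Crozet, Kerguelen and Heard as SIO; Codfish, Dundas and Enderby as
    NZ; and Macquarie as novus. Origins are matched case-insensitively with
    any "Island(s)" suffix stripped. Unmapped origins raise.
    """
    records = list(records)
    raw_map = origin_to_pool if origin_to_pool is not None else DEFAULT_POOL_MAP
    if not raw_map:
        raise ValueError("origin → pool map is empty")
    norm_map = {normalize_origin(k): v for k, v in raw_map.items()}
    unmapped = sorted(
        {r.origin for r in records if normalize_origin(r.origin) not in norm_map}
    )
    if unmapped:
        raise ValueError(f"origin(s) not covered by pool map: {', '.join(unmapped)}")
    return [replace(r, pool=norm_map[normalize_origin(r.origin)]) for r in records]


def pool_counts(records: Iterable[SpecimenRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.pool or "<unassigned>"] = counts.get(r.pool or "<unassigned>", 0) + 1
    return counts


def derive_tail_fork(
    records: Iterable[SpecimenRecord],
    t6: str = "t6_length",
    t1: str = "t1_length",
    out: str = "tail_fork_depth",
) -> list[SpecimenRecord]:
    """Add the derived tail fork depth, T6 − T1; negative values are valid.

    If either rectrix length is missing the derived value stays missing.
    """
    result = []
    for r in records:
        values = dict(r.values)
        if t6 in values and t1 in values:
            values[out] = values[t6] - values[t1]
        else:
            values.pop(out, None)
        result.append(replace(r, values=values))
    return result


# ---------------------------------------------------------------------------
# Summaries

def summarize(
    records: Iterable[SpecimenRecord],
    character: str,
    pools: Sequence[str] | None = None,
) -> dict[str, SummaryStat]:
    """Per-pool mean, SE, min, max and n of one character.

    Pools with zero observations are omitted with a warning.
    """
    by_pool: dict[str, list[float]] = {}
    for r in records:
        v = r.values.get(character)
        if v is not None and r.pool is not None:
            by_pool.setdefault(r.pool, []).append(v)
    order = pools if pools is not None else sorted(by_pool)
    out: dict[str, SummaryStat] = {}
    for pool in order:
        vals = by_pool.get(pool, [])
        if not vals:
            warnings.warn(f"{character}: no observations in pool {pool}; omitted")
            continue
        arr = np.asarray(vals, float)
        n = arr.size
        se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        out[pool] = SummaryStat(
            character=character,
            pool=pool,
            mean=float(arr.mean()),
            se=se,
            min=float(arr.min()),
            max=float(arr.max()),
            n=n,
        )
    return out


def summary_table(
    records: Sequence[SpecimenRecord],
    characters: Sequence[str],
    pools: Sequence[str],
) -> pd.DataFrame:
    """Formatted "mean ± SE (min–max; n)" table, characters × pools."""
    rows = {}
    for c in characters:
        stats = summarize(records, c, pools)
        rows[c] = {p: (stats[p].format() if p in stats else "") for p in pools}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(pools))
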