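"""Character definitions for diving-petrel phenotypic analyses.

A *character* is one measured or scored trait of a specimen. Biometric
characters are continuous measurements in millimetres (or, for the position
of the paraseptal process inside the nasal tube, a percentage of skull
length); plumage characters are ordinal expert scores on small scales
(1–4 or 1–5, e.g. 1 = white, 5 = black for the colour characters);
behavioural/ecological characters are binary contrasts assessed from the
literature. The default registry below covers the full character set used
to compare *Pelecanoides georgicus* populations: nine measured biometric
variables, the derived tail fork depth (T6 − T1, which may be negative),
the paraseptal-process position, and eight ordinal plumage scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class CharClass(str, Enum):
    """Broad class of a character, driving which statistics apply."""

    BIOMETRIC = "biometric"
    PLUMAGE = "plumage"
    BEHAVIORAL = "behavioral"


class Scale(str, Enum):
    CONTINUOUS_MM = "continuous_mm"
    PERCENTAGE = "percentage"
    ORDINAL = "ordinal"


@dataclass(frozen=True)
class CharacterDefinition:
    """Definition and validity envelope of one character.

    Parameters
    ----------
    name:
        Identifier used as the column name in measurement tables.
    char_class:
        Biometric, plumage or behavioral.
    scale:
        Measurement scale. Ordinal characters additionally carry the number
        of levels ``ordinal_levels`` (K); valid scores are integers 1..K.
    valid_range:
        Inclusive ``(lo, hi)`` bounds for plausible values; reading a value
        outside this range is treated as a data error, not a statistical
        outlier.
    derived:
        True for characters computed from others (tail fork depth); derived
        continuous characters may be negative.
    """

    name: str
    char_class: CharClass
    scale: Scale
    valid_range: tuple[float, float]
    ordinal_levels: int | None = None
    derived: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if lo > hi:
            raise ValueError(f"{self.name}: valid_range lo > hi")
        if self.scale is Scale.ORDINAL:
            if self.ordinal_levels is None or self.ordinal_levels < 2:
                raise ValueError(f"{self.name}: ordinal character needs ordinal_levels >= 2")
        elif self.ordinal_levels is not None:
            raise ValueError(f"{self.name}: ordinal_levels only valid for ordinal scale")
        if self.scale is Scale.PERCENTAGE and (lo < 0 or hi > 100):
            raise ValueError(f"{self.name}: percentage range must lie in [0, 100]")
        if self.scale is Scale.CONTINUOUS_MM and not self.derived and lo < 0:
            raise ValueError(f"{self.name}: non-derived continuous character cannot be negative")

    def validate_value(self, value: float) -> float:
        """Return ``value`` as float, raising ``ValueError`` if invalid."""
        v = float(value)
        lo, hi = self.valid_range
        if self.scale is Scale.ORDINAL:
            if v != int(v):
                raise ValueError(f"{self.name}: ordinal score {value!r} is not an integer")
            if not (1 <= v <= self.ordinal_levels):
                raise ValueError(
                    f"{self.name}: score {value!r} outside 1..{self.ordinal_levels}"
                )
        if not (lo <= v <= hi):
            raise ValueError(f"{self.name}: value {value!r} outside [{lo}, {hi}]")
        return v


_B, _P = CharClass.BIOMETRIC, CharClass.PLUMAGE
_MM, _PCT, _ORD = Scale.CONTINUOUS_MM, Scale.PERCENTAGE, Scale.ORDINAL

#: Characters used in the P. georgicus species-delimitation analysis.
DEFAULT_CHARACTERS: tuple[CharacterDefinition, ...] = (
    CharacterDefinition("wing_length", _B, _MM, (0.0, 200.0)),
    CharacterDefinition("t6_length", _B, _MM, (0.0, 100.0)),
    CharacterDefinition("t1_length", _B, _MM, (0.0, 100.0)),
    CharacterDefinition("tail_fork_depth", _B, _MM, (-50.0, 50.0), derived=True),
    CharacterDefinition("bill_length", _B, _MM, (0.0, 30.0)),
    CharacterDefinition("bill_width", _B, _MM, (0.0, 20.0)),
    CharacterDefinition("bill_depth", _B, _MM, (0.0, 20.0)),
    CharacterDefinition("arch_length", _B, _MM, (0.0, 20.0)),
    CharacterDefinition("head_length", _B, _MM, (0.0, 80.0)),
    CharacterDefinition("tarsus_length", _B, _MM, (0.0, 50.0)),
    CharacterDefinition("paraseptal_position", _B, _PCT, (0.0, 100.0)),
    CharacterDefinition("ear_covert_extent", _P, _ORD, (1, 4), ordinal_levels=4),
    CharacterDefinition("collar_extent", _P, _ORD, (1, 4), ordinal_levels=4),
    CharacterDefinition("scapular_extent", _P, _ORD, (1, 4), ordinal_levels=4),
    CharacterDefinition("secondary_extent", _P, _ORD, (1, 5), ordinal_levels=5),
    CharacterDefinition("secondary_shape", _P, _ORD, (1, 4), ordinal_levels=4),
    CharacterDefinition("ear_covert_colour", _P, _ORD, (1, 5), ordinal_levels=5),
    CharacterDefinition("collar_colour", _P, _ORD, (1, 5), ordinal_levels=5),
    CharacterDefinition("flank_colour", _P, _ORD, (1, 5), ordinal_levels=5),
)

DEFAULT_CHARACTER_MAP: dict[str, CharacterDefinition] = {
    c.name: c for c in DEFAULT_CHARACTERS
}

#: Default origin → pool assignment. Keys are matched after normalisation
#: (lowercase, "island(s)" suffix stripped), so "Heard Island" maps via
#: "heard". SAO = South Atlantic Ocean, SIO = South Indian Ocean,
#: NZ = New Zealand, novus = the Macquarie Island population.
DEFAULT_POOL_MAP: dict[str, str] = {
    "south georgia": "SAO",
    "southern atlantic ocean": "SAO",
    "south atlantic ocean": "SAO",
    "crozet": "SIO",
    "kerguelen": "SIO",
    "heard": "SIO",
    "codfish": "NZ",
    "dundas": "NZ",
    "enderby": "NZ",
    "macquarie": "novus",
}


def normalize_origin(origin: str) -> str:
    """Normalise a locality label for pool-map lookup."""
    s = origin.strip().lower()
    for suffix in (" islands", " island"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    return s


def characters_of_class(
    char_class: CharClass | str,
    definitions: dict[str, CharacterDefinition] | None = None,
    include_derived: bool = True,
) -> list[CharacterDefinition]:
    defs = definitions if definitions is not None else DEFAULT_CHARACTER_MAP
    cc = CharClass(char_class)
    return [
        d for d in defs.values()
        if d.char_class is cc and (include_derived or not d.derived)
    ]
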