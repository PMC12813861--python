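"""Age bands, band schemes and age-sex strata.

A *band scheme* is an ordered, disjoint, gap-free list of :class:`AgeBand`
objects covering ages 0 upward, ending in an open-ended band.  Demand
projection uses the four-band scheme ``0-64 / 65-74 / 75-84 / 85+``;
the descriptive profile uses ``<15 / 15-34 / 35-64 / 65+``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

MALE = "M"
FEMALE = "F"
BOTH = "BOTH"
SEXES = (MALE, FEMALE)

_BAND_RE = re.compile(r"^\s*(?:<\s*(\d+)|(\d+)\s*(?:-\s*(\d+)|(\+))?)\s*$")


@dataclass(frozen=True, order=True)
class AgeBand:
    """A contiguous range of integer ages, inclusive on both ends.

    ``upper is None`` marks an open-ended band such as ``85+``.
    """

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"band lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"band upper {self.upper} below lower {self.lower}")

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    @property
    def label(self) -> str:
        if self.open_ended:
            return f"{self.lower}+"
        if self.upper == self.lower:
            return str(self.lower)
        return f"{self.lower}-{self.upper}"

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)

    def within(self, other: "AgeBand") -> bool:
        """True if every age of this band lies inside *other*."""
        if not other.contains(self.lower):
            return False
        if self.open_ended:
            return other.open_ended
        return other.contains(self.upper)

    @classmethod
    def parse(cls, text: str | int) -> "AgeBand":
        """Parse ``"7"``, ``"0-64"``, ``"85+"`` or ``"<15"`` (= 0-14)."""
        if isinstance(text, int):
            return cls(text, text)
        m = _BAND_RE.match(str(text))
        if m is None:
            raise ValueError(f"cannot parse age or age band {text!r}")
        below, lo, hi, plus = m.groups()
        if below is not None:
            if int(below) < 1:
                raise ValueError(f"cannot parse age band {text!r}")
            return cls(0, int(below) - 1)
        if plus is not None:
            return cls(int(lo), None)
        if hi is not None:
            return cls(int(lo), int(hi))
        return cls(int(lo), int(lo))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def validate_scheme(scheme: Iterable[AgeBand]) -> tuple[AgeBand, ...]:
    """Check a band scheme is disjoint and covers 0..open-end without gaps.

    Returns the bands sorted by lower bound.  Raises :class:`ValueError`
    naming the first offending age on a gap or overlap.
    """
    bands = tuple(sorted(scheme))
    if not bands:
        raise ValueError("empty band scheme")
    if bands[0].lower != 0:
        raise ValueError(f"scheme does not cover age 0 (starts at {bands[0].lower})")
    for prev, nxt in zip(bands, bands[1:]):
        if prev.open_ended:
            raise ValueError(f"open-ended band {prev.label} is not last in scheme")
        if nxt.lower <= prev.upper:
            raise ValueError(f"bands {prev.label} and {nxt.label} overlap")
        if nxt.lower != prev.upper + 1:
            raise ValueError(f"gap at {prev.upper + 1} between {prev.label} and {nxt.label}")
    if not bands[-1].open_ended:
        raise ValueError(f"scheme is not open-ended (stops at {bands[-1].upper})")
    return bands


def band_for_age(age: int, scheme: Sequence[AgeBand]) -> AgeBand:
    for band in scheme:
        if band.contains(age):
            return band
    raise ValueError(f"age {age} not covered by scheme")


#: Four-band scheme used for the demographic weighting and projection.
PROJECTION_BANDS: tuple[AgeBand, ...] = validate_scheme(
    [AgeBand(0, 64), AgeBand(65, 74), AgeBand(75, 84), AgeBand(85, None)]
)

#: Scheme used by the descriptive demand profile.
PROFILE_BANDS: tuple[AgeBand, ...] = validate_scheme(
    [AgeBand(0, 14), AgeBand(15, 34), AgeBand(35, 64), AgeBand(65, None)]
)


def parse_scheme(text: str) -> tuple[AgeBand, ...]:
    """Parse a comma-separated scheme such as ``"0-64,65-74,75-84,85+"``."""
    return validate_scheme(AgeBand.parse(part) for part in text.split(","))
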