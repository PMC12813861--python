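"""Population pyramids and age-gender population-change weights.

The demographic driver of the projection is the *weighting factor*
``W(band, sex) = population(target year) / population(base year)`` per
age-sex stratum, together with the overall (both-sex, all-age) ratio
used by the structure-blind projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bands import BOTH, FEMALE, MALE, SEXES, AgeBand, validate_scheme

__all__ = [
    "PopulationPyramid",
    "WeightTable",
    "read_pyramid",
    "bin_pyramid",
    "compute_weights",
]


@dataclass
class PopulationPyramid:
    """Counts of people by age (single year or band) and sex for one year."""

    year: int
    counts: dict[tuple[AgeBand, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (band, sex), n in self.counts.items():
            if sex not in SEXES:
                raise ValueError(f"unknown sex code {sex!r} in pyramid")
            if n < 0:
                raise ValueError(f"negative count {n} for {band.label}/{sex}")

    def count(self, band: AgeBand, sex: str = BOTH) -> float:
        if sex == BOTH:
            return self.count(band, MALE) + self.count(band, FEMALE)
        return self.counts.get((band, sex), 0.0)

    def total(self, sex: str = BOTH) -> float:
        if sex == BOTH:
            return sum(self.counts.values())
        return sum(n for (_, s), n in self.counts.items() if s == sex)

    @property
    def bands(self) -> tuple[AgeBand, ...]:
        return tuple(sorted({band for band, _ in self.counts}))

    def scaled(self, k: float) -> "PopulationPyramid":
        return PopulationPyramid(self.year, {key: n * k for key, n in self.counts.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": self.year, "sex": sex, "age": band.label, "count": n}
            for (band, sex), n in sorted(self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1]))
        ]
        return pd.DataFrame(rows, columns=["year", "sex", "age", "count"])


def read_pyramid(path: str | Path, year: int) -> PopulationPyramid:
    """Read one year's pyramid from a ``year,sex,age,count`` delimited file.

    ``age`` may be a single year ("90") or a band label ("0-64", "85+"),
    so official projections supplied either way are accepted.  Lines
    starting with ``#`` are ignored.
    """
    df = pd.read_csv(path, comment="#")
    required = {"year", "sex", "age", "count"}
    if missing := required - set(df.columns):
        raise ValueError(f"pyramid file {path} lacks columns: {sorted(missing)}")
    df = df[df["year"].astype(int) == year]
    if df.empty:
        raise ValueError(f"no rows for requested year {year} in {path}")
    counts: dict[tuple[AgeBand, str], float] = {}
    for idx, row in df.iterrows():
        sex = str(row["sex"]).strip().upper()
        if sex not in SEXES:
            raise ValueError(f"unknown sex code {row['sex']!r} at row {idx + 2} of {path}")
        n = float(row["count"])
        if n < 0:
            raise ValueError(f"negative count {row['count']} at row {idx + 2} of {path}")
        band = AgeBand.parse(row["age"])
        key = (band, sex)
        counts[key] = counts.get(key, 0.0) + n
    return PopulationPyramid(year, counts)


def bin_pyramid(p: PopulationPyramid, scheme: Iterable[AgeBand]) -> PopulationPyramid:
    """Re-bin a pyramid onto *scheme*, conserving the grand total.

    Every source band must nest entirely inside one scheme band; a
    pre-binned pyramid that straddles scheme boundaries is rejected.
    """
    bands = validate_scheme(scheme)
    out: dict[tuple[AgeBand, str], float] = {(b, s): 0.0 for b in bands for s in SEXES}
    for (band, sex), n in p.counts.items():
        target = next((b for b in bands if band.within(b)), None)
        if target is None:
            raise ValueError(
                f"source band {band.label} straddles the target scheme "
                f"{[b.label for b in bands]}"
            )
        out[(target, sex)] += n
    return PopulationPyramid(p.year, out)


@dataclass
class WeightTable:
    """Age-gender population-change indices between two years.

    ``weights`` maps ``(band label, sex)`` — sex in ``{M, F, BOTH}`` — to
    the target/base population ratio; ``overall_ratio`` is the both-sex
    all-age ratio driving the structure-blind projection.
    """

    base_year: int
    target_year: int
    band_labels: tuple[str, ...]
    weights: dict[tuple[str, str], float]
    overall_ratio: float

    def weight(self, band: str | AgeBand, sex: str) -> float:
        label = band.label if isinstance(band, AgeBand) else band
        try:
            return self.weights[(label, sex)]
        except KeyError:
            raise KeyError(f"no weight for stratum {label}/{sex}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "base_year": self.base_year,
                "target_year": self.target_year,
                "age_band": label,
                "sex": sex,
                "weight": self.weights[(label, sex)],
            }
            for label in self.band_labels
            for sex in (MALE, FEMALE, BOTH)
            if (label, sex) in self.weights
        ]
        rows.append(
            {
                "base_year": self.base_year,
                "target_year": self.target_year,
                "age_band": "ALL",
                "sex": BOTH,
                "weight": self.overall_ratio,
            }
        )
        return pd.DataFrame(rows)

    @classmethod
    def from_mapping(
        cls,
        base_year: int,
        target_year: int,
        weights: Mapping[tuple[str, str], float],
        overall_ratio: float,
    ) -> "WeightTable":
        labels = tuple(dict.fromkeys(label for label, _ in weights))
        return cls(base_year, target_year, labels, dict(weights), overall_ratio)


def compute_weights(
    base: PopulationPyramid,
    target: PopulationPyramid,
    scheme: Sequence[AgeBand],
) -> WeightTable:
    """Elementwise target/base population ratios per stratum.

    Computed per sex and for both sexes combined; the both-sex weight is
    therefore the base-population-weighted mean of the sex-specific ones.
    """
    bands = validate_scheme(scheme)
    b = bin_pyramid(base, bands)
    t = bin_pyramid(target, bands)
    weights: dict[tuple[str, str], float] = {}
    for band in bands:
        for sex in (MALE, FEMALE, BOTH):
            denom = b.count(band, sex)
            numer = t.count(band, sex)
            if denom <= 0:
                if numer > 0:
                    raise ValueError(
                        f"zero base population in stratum {band.label}/{sex} "
                        f"({base.year}); weight undefined"
                    )
                continue  # stratum empty in both years: no weight needed
            weights[(band.label, sex)] = numer / denom
    base_total = b.total()
    if base_total <= 0:
        raise ValueError("base pyramid is empty")
    return WeightTable(
        base_year=base.year,
        target_year=target.year,
        band_labels=tuple(band.label for band in bands),
        weights=weights,
        overall_ratio=t.total() / base_total,
    )
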