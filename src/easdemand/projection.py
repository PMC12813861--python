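"""Yearly demand projection with and without age-gender adjustment.

The adjusted projection is a weighted linear combination of base-year
stratum demands, the weights being the stratum population ratios
between target and base year:

    Y(target) = sum_band sum_sex W(band, sex) * Y(band, sex, base)

The unadjusted (structure-blind) projection scales every stratum by the
single overall both-sex all-age population ratio.  The misestimation
incurred by ignoring demographic structure is the relative difference
between the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BOTH, FEMALE, MALE, AgeBand, validate_scheme
from .demand import DemandTable
from .pyramids import PopulationPyramid, WeightTable, compute_weights

__all__ = [
    "project_adjusted",
    "project_unadjusted",
    "misestimation",
    "trajectory",
    "DemandProjectionModel",
    "ProjectionResults",
]

ALL_BANDS = "All"
SUM_OF_SEX = "sum_of_sex"
AGGREGATE_WEIGHT = "aggregate_weight"
_MODES = (SUM_OF_SEX, AGGREGATE_WEIGHT)


def _base_cells(
    base: DemandTable,
    base_year: int,
    both_base: Mapping[str, int] | None = None,
) -> dict[tuple[str, str], int]:
    """Stratum base counts; ``both_base`` optionally overrides the
    derived both-sex cells with independently recorded totals (e.g.
    counts that include records of known age but missing sex)."""
    cells = {}
    for label in base.band_labels:
        for sex in (MALE, FEMALE, BOTH):
            cells[(label, sex)] = base.yearly_value(base_year, label, sex)
        if both_base is not None and label in both_base:
            cells[(label, BOTH)] = both_base[label]
    return cells


def project_adjusted(
    base: DemandTable,
    w: WeightTable,
    both_mode: str = SUM_OF_SEX,
    both_base: Mapping[str, int] | None = None,
) -> dict[tuple[str, str], float]:
    """Age-gender-adjusted projection per stratum.

    Sex-specific cells are always W(band, sex) * base count.  The
    both-sex cell is the sum of the two sex projections under
    ``sum_of_sex`` (the literal double sum), or the both-sex weight
    times the both-sex base count under ``aggregate_weight``.  The two
    modes disagree exactly when male and female weights differ within a
    band.  ``All`` rows are sums of the mode's stratum cells.
    ``both_base`` supplies independently recorded both-sex base counts
    (which may exceed male + female when some records lack sex).
    """
    if both_mode not in _MODES:
        raise ValueError(f"both_mode must be one of {_MODES}, got {both_mode!r}")
    if set(base.band_labels) != set(w.band_labels):
        raise ValueError(
            f"demand table bands {base.band_labels} do not match weight bands {w.band_labels}"
        )
    cells = _base_cells(base, w.base_year, both_base)
    out: dict[tuple[str, str], float] = {}
    for label in w.band_labels:
        for sex in (MALE, FEMALE):
            if cells[(label, sex)] and (label, sex) not in w.weights:
                raise KeyError(f"no weight for populated stratum {label}/{sex}")
            out[(label, sex)] = w.weight(label, sex) * cells[(label, sex)]
        if both_mode == SUM_OF_SEX:
            out[(label, BOTH)] = out[(label, MALE)] + out[(label, FEMALE)]
        else:
            out[(label, BOTH)] = w.weight(label, BOTH) * cells[(label, BOTH)]
    for sex in (MALE, FEMALE, BOTH):
        out[(ALL_BANDS, sex)] = sum(out[(label, sex)] for label in w.band_labels)
    return out


def project_unadjusted(
    base: DemandTable,
    w: WeightTable,
    both_base: Mapping[str, int] | None = None,
) -> dict[tuple[str, str], float]:
    """Structure-blind projection: every cell scaled by the overall ratio."""
    cells = _base_cells(base, w.base_year, both_base)
    out = {key: w.overall_ratio * n for key, n in cells.items()}
    for sex in (MALE, FEMALE, BOTH):
        out[(ALL_BANDS, sex)] = sum(out[(label, sex)] for label in base.band_labels)
    return out


def misestimation(adjusted: float, unadjusted: float) -> float:
    """Percent misestimation of the structure-blind projection.

    100 * (unadjusted - adjusted) / adjusted; negative values mean the
    structure-blind projection underestimates demand.
    """
    if adjusted <= 0:
        raise ValueError(f"adjusted projection must be positive, got {adjusted}")
    return 100.0 * (unadjusted - adjusted) / adjusted


def trajectory(
    base: DemandTable,
    pyramids: Mapping[int, PopulationPyramid],
    scheme: Sequence[AgeBand],
    both_mode: str = SUM_OF_SEX,
    base_year: int | None = None,
) -> pd.DataFrame:
    """Adjusted and unadjusted total demand for every year covered.

    Requires a pyramid for every year from the base year to the horizon;
    year-specific overall ratios drive the unadjusted series.
    """
    bands = validate_scheme(scheme)
    years = sorted(pyramids)
    if base_year is None:
        base_year = years[0]
    gaps = [y for y in range(base_year, years[-1] + 1) if y not in pyramids]
    if gaps:
        raise ValueError(f"missing pyramids for years: {gaps}")
    rows = []
    for year in range(base_year, years[-1] + 1):
        w = compute_weights(pyramids[base_year], pyramids[year], bands)
        adj = project_adjusted(base, w, both_mode)
        unadj = project_unadjusted(base, w)
        rows.append(
            {
                "year": year,
                "adjusted_total": adj[(ALL_BANDS, BOTH)],
                "unadjusted_total": unadj[(ALL_BANDS, BOTH)],
            }
        )
    return pd.DataFrame(rows)


class DemandProjectionModel:
    """Projects base-year yearly demand to target years.

    Parameters
    ----------
    base_demand : yearly :class:`~easdemand.demand.DemandTable` for the
        base year.
    weight_tables : one :class:`~easdemand.pyramids.WeightTable` per
        target year, sharing the demand table's band scheme and base year.
    both_mode : how both-sex cells are formed — ``"sum_of_sex"`` (male +
        female projections) or ``"aggregate_weight"`` (both-sex weight
        times both-sex base demand).
    """

    def __init__(
        self,
        base_demand: DemandTable,
        weight_tables: Sequence[WeightTable],
        both_mode: str = SUM_OF_SEX,
        both_base: Mapping[str, int] | None = None,
    ):
        if not weight_tables:
            raise ValueError("need at least one weight table")
        base_years = {w.base_year for w in weight_tables}
        if len(base_years) > 1:
            raise ValueError(f"weight tables disagree on base year: {sorted(base_years)}")
        self.base_demand = base_demand.to_yearly()
        self.base_year = base_years.pop()
        self.weight_tables = list(weight_tables)
        self.both_mode = both_mode
        self.both_base = dict(both_base) if both_base else None

    @classmethod
    def from_pyramids(
        cls,
        base_demand: DemandTable,
        pyramids: Mapping[int, PopulationPyramid],
        base_year: int,
        target_years: Sequence[int],
        scheme: Sequence[AgeBand],
        both_mode: str = SUM_OF_SEX,
    ) -> "DemandProjectionModel":
        tables = [
            compute_weights(pyramids[base_year], pyramids[y], scheme) for y in target_years
        ]
        return cls(base_demand, tables, both_mode)

    def fit(self) -> "ProjectionResults":
        rows = []
        for w in self.weight_tables:
            adj = project_adjusted(self.base_demand, w, self.both_mode, self.both_base)
            unadj = project_unadjusted(self.base_demand, w, self.both_base)
            cells = _base_cells(self.base_demand, self.base_year, self.both_base)
            for label in (*w.band_labels, ALL_BANDS):
                for sex in (MALE, FEMALE, BOTH):
                    actual = (
                        cells[(label, sex)]
                        if label != ALL_BANDS
                        else sum(cells[(b, sex)] for b in w.band_labels)
                    )
                    rows.append(
                        {
                            "target_year": w.target_year,
                            "age_band": label,
                            "sex": sex,
                            "actual_base": actual,
                            "unadjusted": unadj[(label, sex)],
                            "adjusted": adj[(label, sex)],
                            "difference_pct": misestimation(
                                adj[(label, sex)], unadj[(label, sex)]
                            )
                            if adj[(label, sex)] > 0
                            else np.nan,
                        }
                    )
        return ProjectionResults(self, pd.DataFrame(rows))


@dataclass
class ProjectionResults:
    """Projected demand per target year and stratum, with misestimation."""

    model: DemandProjectionModel
    projections: pd.DataFrame

    def lookup(self, target_year: int, band: str, sex: str, column: str = "adjusted") -> float:
        df = self.projections
        row = df[
            (df["target_year"] == target_year) & (df["age_band"] == band) & (df["sex"] == sex)
        ]
        if row.empty:
            raise KeyError(f"no projection for {target_year}/{band}/{sex}")
        return float(row.iloc[0][column])

    def summary(self) -> pd.DataFrame:
        """Report-ready table: demand rounded to integers, differences to
        integer percent."""
        df = self.projections.copy()
        for col in ("unadjusted", "adjusted"):
            df[col] = np.rint(df[col]).astype(int)
        df["difference_pct"] = pd.Series(
            np.rint(df["difference_pct"]), index=df.index
        ).convert_dtypes()
        return df

    def __repr__(self) -> str:  # pragma: no cover
        years = sorted(self.projections["target_year"].unique())
        return f"<ProjectionResults base={self.model.base_year} targets={years}>"
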