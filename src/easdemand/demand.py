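"""Patient-level ambulance records, demand tables and the descriptive profile.

One record is one ambulance transport event.  Records carry date, age and
sex (the projection inputs) plus optional triage level (1 = most urgent,
5 = least) and a trauma flag, which feed only the descriptive profile.
Records missing age or sex cannot be assigned to a stratum; they are
excluded from demand tables and the exclusion is counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .bands import BOTH, FEMALE, MALE, PROFILE_BANDS, SEXES, AgeBand, validate_scheme

__all__ = ["EASRecord", "DemandTable", "read_records", "aggregate", "profile"]

logger = logging.getLogger("easdemand")

MAX_AGE = 130

RECORD_COLUMNS = ["date", "age", "sex", "triage", "trauma"]


class EASRecord(NamedTuple):
    """One ambulance transport event."""

    date: object  # datetime.date
    age: int | None
    sex: str | None
    triage: int | None = None
    trauma: bool | None = None


def records_frame(records: Sequence[EASRecord]) -> pd.DataFrame:
    """Pack records into the canonical DataFrame layout."""
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    return _coerce(df)


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["date"] = pd.to_datetime(df["date"], errors="coerce")
    out["age"] = pd.to_numeric(df["age"], errors="coerce").astype("Int64")
    sex = df["sex"].astype("string").str.strip().str.upper()
    out["sex"] = sex.where(sex.isin(SEXES))
    if "triage" in df:
        triage = pd.to_numeric(df["triage"], errors="coerce").astype("Int64")
        out["triage"] = triage.where((triage >= 1) & (triage <= 5))
    else:
        out["triage"] = pd.array([pd.NA] * len(df), dtype="Int64")
    if "trauma" in df:
        trauma = pd.to_numeric(df["trauma"], errors="coerce")
        out["trauma"] = pd.array(
            [bool(v) if v in (0, 1) else pd.NA for v in trauma], dtype="boolean"
        )
    else:
        out["trauma"] = pd.array([pd.NA] * len(df), dtype="boolean")
    bad_age = out["age"].notna() & ((out["age"] < 0) | (out["age"] > MAX_AGE))
    if bad_age.any():
        logger.warning("%d records with implausible age set to missing", int(bad_age.sum()))
        out.loc[bad_age, "age"] = pd.NA
    return out


def read_records(path: str | Path) -> pd.DataFrame:
    """Read patient records from a ``date,age,sex[,triage,trauma]`` file.

    Malformed optional fields become missing (logged); rows whose date
    cannot be parsed are dropped (logged).  Returns a DataFrame with
    columns date, age, sex, triage, trauma.
    """
    raw = pd.read_csv(path, comment="#", dtype=str)
    if missing := {"date", "age", "sex"} - set(raw.columns):
        raise ValueError(f"records file {path} lacks columns: {sorted(missing)}")
    df = _coerce(raw)
    n_bad_triage = int((raw.get("triage", pd.Series(dtype=str)).notna() & df["triage"].isna()).sum()) if "triage" in raw else 0
    if n_bad_triage:
        logger.warning("%d records with invalid triage set to missing", n_bad_triage)
    bad_date = df["date"].isna()
    if bad_date.any():
        logger.warning("%d records with unparseable date dropped", int(bad_date.sum()))
        df = df[~bad_date]
    return df.reset_index(drop=True)


@dataclass
class DemandTable:
    """Event counts per period key and age-sex stratum.

    ``cells`` is indexed by ``(key, band label, sex)`` with sex in
    ``{M, F}``; both-sex and all-age values are derived sums, never
    stored.  ``key`` is a calendar date for daily tables, a year for
    yearly ones.  ``n_dropped`` counts records excluded for missing
    age or sex.
    """

    period: str  # "daily" | "yearly"
    cells: pd.Series
    scheme: tuple[AgeBand, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.period not in ("daily", "yearly"):
            raise ValueError(f"period must be 'daily' or 'yearly', got {self.period!r}")

    @property
    def band_labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.scheme)

    def keys(self) -> list:
        return list(self.cells.index.get_level_values(0).unique())

    def value(self, key, band: str | AgeBand, sex: str = BOTH) -> int:
        label = band.label if isinstance(band, AgeBand) else band
        if sex == BOTH:
            return self.value(key, label, MALE) + self.value(key, label, FEMALE)
        try:
            return int(self.cells.loc[(key, label, sex)])
        except KeyError:
            return 0

    def yearly_value(self, year: int, band: str | AgeBand, sex: str = BOTH) -> int:
        if self.period == "yearly":
            return self.value(year, band, sex)
        label = band.label if isinstance(band, AgeBand) else band
        if sex == BOTH:
            return self.yearly_value(year, label, MALE) + self.yearly_value(year, label, FEMALE)
        mask = self.cells.index.get_level_values(0).year == year
        sub = self.cells[mask]
        try:
            return int(sub.xs(label, level=1).xs(sex, level=1).sum())
        except KeyError:
            return 0

    def total(self, key=None) -> int:
        if key is None:
            return int(self.cells.sum())
        return int(self.cells.xs(key, level=0).sum())

    def stratum_series(self, band: str | AgeBand, sex: str) -> pd.Series:
        """Counts over period keys for one stratum (zeros kept)."""
        label = band.label if isinstance(band, AgeBand) else band
        if sex == BOTH:
            return self.stratum_series(label, MALE) + self.stratum_series(label, FEMALE)
        keys = self.cells.index.get_level_values(0).unique()
        try:
            s = self.cells.xs(label, level=1).xs(sex, level=1)
        except KeyError:
            s = pd.Series(dtype=int)
        return s.reindex(keys, fill_value=0).sort_index()

    def to_yearly(self) -> "DemandTable":
        if self.period == "yearly":
            return self
        df = self.cells.reset_index()
        df.columns = ["key", "age_band", "sex", "count"]
        df["key"] = pd.DatetimeIndex(df["key"]).year
        cells = df.groupby(["key", "age_band", "sex"], sort=True)["count"].sum()
        return DemandTable("yearly", cells, self.scheme, self.n_dropped)

    def to_frame(self) -> pd.DataFrame:
        df = self.cells.reset_index()
        df.columns = ["period_key", "age_band", "sex", "count"]
        return df


def aggregate(
    records: pd.DataFrame | Sequence[EASRecord],
    scheme: Sequence[AgeBand],
    period: str = "daily",
) -> DemandTable:
    """Count records per (period key, band, sex) cell.

    Records missing age or sex are excluded and tallied in ``n_dropped``.
    Daily tables span the full calendar from the first to the last record
    date, with zero cells kept, so regression on daily counts sees every
    day.  Conservation: sum of all cells + n_dropped = number of records.
    """
    bands = validate_scheme(scheme)
    if not isinstance(records, pd.DataFrame):
        records = records_frame(list(records))
    usable = records.dropna(subset=["age", "sex"])
    n_dropped = len(records) - len(usable)
    labels = [b.label for b in bands]
    if len(usable):
        edges = [b.lower for b in bands] + [np.inf]
        band_of = pd.cut(
            usable["age"].astype(int), bins=edges, labels=labels, right=False
        ).astype(str)
        key = (
            usable["date"].dt.normalize()
            if period == "daily"
            else usable["date"].dt.year
        )
        grouped = (
            pd.DataFrame({"key": key, "age_band": band_of, "sex": usable["sex"]})
            .groupby(["key", "age_band", "sex"], sort=True, observed=True)
            .size()
        )
        if period == "daily":
            all_keys = pd.date_range(key.min(), key.max(), freq="D")
        else:
            all_keys = range(int(key.min()), int(key.max()) + 1)
        full = pd.MultiIndex.from_product(
            [all_keys, labels, list(SEXES)], names=["key", "age_band", "sex"]
        )
        cells = grouped.reindex(full, fill_value=0).astype(int)
    else:
        full = pd.MultiIndex.from_arrays([[], [], []], names=["key", "age_band", "sex"])
        cells = pd.Series([], index=full, dtype=int)
    table = DemandTable(period, cells, bands, n_dropped)
    return table


def table_from_counts(
    year: int,
    counts: Mapping[tuple[str, str], int],
    scheme: Sequence[AgeBand],
    n_dropped: int = 0,
) -> DemandTable:
    """Build a yearly demand table directly from stratum counts.

    Useful when the age-gender breakdown is already published as a
    table rather than derivable from record-level data.
    """
    bands = validate_scheme(scheme)
    labels = [b.label for b in bands]
    idx = pd.MultiIndex.from_product(
        [[year], labels, list(SEXES)], names=["key", "age_band", "sex"]
    )
    cells = pd.Series(
        [int(counts.get((label, sex), 0)) for label in labels for sex in SEXES],
        index=idx,
        dtype=int,
    )
    return DemandTable("yearly", cells, bands, n_dropped)


_PROFILE_AGE_LABELS = {"0-14": "<15", "15-34": "15-34", "35-64": "35-64", "65+": "65+"}


def profile(records: pd.DataFrame, year: int | None = None) -> pd.DataFrame:
    """Descriptive profile: counts and percentages by age category,
    triage level, sex and trauma status.

    Each block's percentage denominator is the number of records with
    that field present, so blocks may have different denominators when
    data are missing.  Returns columns block, category, count, percent.
    """
    if year is not None:
        records = records[records["date"].dt.year == year]
    rows: list[dict] = []

    def block(name: str, series: pd.Series, order: list) -> None:
        counts = series.dropna().value_counts()
        denom = int(counts.sum())
        for cat in order:
            n = int(counts.get(cat, 0))
            pct = 100.0 * n / denom if denom else float("nan")
            rows.append({"block": name, "category": str(cat), "count": n, "percent": pct})

    age = records["age"].dropna().astype(int)
    edges = [b.lower for b in PROFILE_BANDS] + [np.inf]
    age_cat = pd.cut(age, bins=edges, labels=[b.label for b in PROFILE_BANDS], right=False)
    age_cat = age_cat.map(_PROFILE_AGE_LABELS)
    block("age", age_cat, list(_PROFILE_AGE_LABELS.values()))
    block("triage", records["triage"], [1, 2, 3, 4, 5])
    block("sex", records["sex"].map({FEMALE: "Female", MALE: "Male"}), ["Female", "Male"])
    block(
        "trauma",
        records["trauma"].map({True: "Trauma", False: "Nontrauma"}),
        ["Trauma", "Nontrauma"],
    )
    return pd.DataFrame(rows, columns=["block", "category", "count", "percent"])
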