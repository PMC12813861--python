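"""Synthetic scenario generator.

Emulates the three restricted data sources the analysis consumes:

* an official multi-decade population projection — per-stratum
  exponential growth from a base-year pyramid;
* a daily mean temperature series — a sinusoidal seasonal cycle with
  Gaussian day-to-day noise;
* patient-level ambulance records — per stratum-day Poisson counts
  whose rate is a quadratic in that day's temperature, scaled by the
  stratum's population relative to the base year so demographic drift
  propagates into record volume.

Default parameters reproduce a Taipei-like scenario: the base-year
stratum rate curves have the shapes of the published 2015 regressions,
calibrated so the deterministic-climate yearly expectation matches the
published 2015 stratum totals, and 36-year growth factors match the
published 2051 weighting factors.  Everything is overridable and fully
deterministic given (config, seed).
"""

from __future__ import annotations

import calendar
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .bands import BOTH, FEMALE, MALE, PROJECTION_BANDS, AgeBand, band_for_age, validate_scheme
from .demand import RECORD_COLUMNS, _coerce
from .pyramids import PopulationPyramid, WeightTable, compute_weights

__all__ = [
    "ScenarioConfig",
    "default_scenario",
    "simulate_pyramids",
    "simulate_temperature",
    "simulate_records",
    "ground_truth",
    "GroundTruth",
    "write_scenario",
]

Stratum = tuple[str, str]  # (band label, sex)

#: Taipei-like 2015 base populations per projection stratum.
DEFAULT_BASE_POPULATION: dict[Stratum, int] = {
    ("0-64", MALE): 1_180_000,
    ("0-64", FEMALE): 1_210_000,
    ("65-74", MALE): 93_000,
    ("65-74", FEMALE): 108_000,
    ("75-84", MALE): 62_000,
    ("75-84", FEMALE): 76_000,
    ("85+", MALE): 21_000,
    ("85+", FEMALE): 32_000,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one synthetic scenario."""

    base_year: int = 2015
    horizon_year: int = 2051
    scheme: tuple[AgeBand, ...] = PROJECTION_BANDS
    base_population: Mapping[Stratum, int] = field(
        default_factory=lambda: dict(DEFAULT_BASE_POPULATION)
    )
    growth_rate: Mapping[Stratum, float] = field(default_factory=dict)
    rates: Mapping[Stratum, tuple[float, float, float]] = field(default_factory=dict)
    temp_mean: float = 23.0  # annual mean, °C
    temp_amplitude: float = 6.0  # seasonal half-range, °C
    temp_phase_day: int = 197  # day of year of the seasonal peak
    temp_sd: float = 2.0  # day-to-day Gaussian noise, °C
    triage_probs: Mapping[int, float] | None = None
    trauma_prob: float | None = None
    p_missing_triage: float = 0.02
    age_cap: int = 100  # sampling cap for the open-ended band
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                k: (sorted((str(a), b) for a, b in v.items()) if isinstance(v, Mapping) else str(v))
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @property
    def strata(self) -> list[Stratum]:
        return [(b.label, s) for b in self.scheme for s in (MALE, FEMALE)]


def _deterministic_temperature(year: int, cfg: ScenarioConfig) -> pd.Series:
    n = 366 if calendar.isleap(year) else 365
    idx = pd.date_range(f"{year}-01-01", periods=n, freq="D")
    doy = np.arange(1, n + 1)
    t = cfg.temp_mean + cfg.temp_amplitude * np.cos(
        2 * np.pi * (doy - cfg.temp_phase_day) / 365.25
    )
    return pd.Series(t, index=idx, name="temperature")


def _calibrated_rates(cfg: ScenarioConfig) -> dict[Stratum, tuple[float, float, float]]:
    """Base-year stratum rate curves.

    Shapes come from the published 2015 regressions; each curve is
    scaled so its deterministic-climate yearly sum equals the published
    2015 stratum total.
    """
    temps = _deterministic_temperature(cfg.base_year, cfg).to_numpy()
    out = {}
    for stratum, target in datasets.BASE_DEMAND_2015.items():
        eq = datasets.BASE_EQUATIONS[stratum]
        expected = np.maximum(0.0, eq.predict(temps)).sum()
        k = target / expected
        out[stratum] = (eq.constant * k, eq.b1 * k, eq.b2 * k)
    return out


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The Taipei-like default scenario.

    Growth rates solve ``(1+r)^36 = W_2051`` per stratum, so the
    36-year population factors match the published 2051 weights.
    """
    cfg = ScenarioConfig(seed=seed, **{k: v for k, v in overrides.items() if k != "rates"})
    span = cfg.horizon_year - cfg.base_year
    growth = dict(cfg.growth_rate) or {
        (label, sex): datasets.WEIGHTS_2051.weight(label, sex) ** (1.0 / span) - 1.0
        for (label, sex) in cfg.strata
    }
    rates = overrides.get("rates") or _calibrated_rates(cfg)
    triage_total = sum(datasets.TRIAGE_COUNTS_2015.values())
    return replace(
        cfg,
        growth_rate=growth,
        rates=dict(rates),
        triage_probs=cfg.triage_probs
        or {k: v / triage_total for k, v in datasets.TRIAGE_COUNTS_2015.items()},
        trauma_prob=cfg.trauma_prob if cfg.trauma_prob is not None else datasets.TRAUMA_SHARE_2015,
    )


def _rng(cfg_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed % 2**31, *keys])


def simulate_pyramids(cfg: ScenarioConfig) -> dict[int, PopulationPyramid]:
    """One pyramid per year, base to horizon: exponential stratum growth.

    count(year) = round(base_count * (1+rate)^(year-base)); deterministic.
    """
    band_by_label = {b.label: b for b in cfg.scheme}
    out: dict[int, PopulationPyramid] = {}
    for year in range(cfg.base_year, cfg.horizon_year + 1):
        counts = {}
        for (label, sex), base_n in cfg.base_population.items():
            r = cfg.growth_rate.get((label, sex), 0.0)
            counts[(band_by_label[label], sex)] = float(
                round(base_n * (1.0 + r) ** (year - cfg.base_year))
            )
        out[year] = PopulationPyramid(year, counts)
    return out


def simulate_temperature(year: int, cfg: ScenarioConfig, seed: int | None = None) -> pd.Series:
    """Sinusoidal seasonal cycle plus Gaussian daily noise.

    T(d) = mean + amplitude * cos(2π (doy - phase)/365.25) + N(0, sd).
    """
    if cfg.temp_sd < 0:
        raise ValueError("temperature noise sd must be >= 0")
    base = _deterministic_temperature(year, cfg)
    if cfg.temp_sd == 0:
        return base
    rng = _rng(cfg.seed if seed is None else seed, year, 1)
    return base + rng.normal(0.0, cfg.temp_sd, size=len(base))


def simulate_records(
    year: int,
    pyramid: PopulationPyramid,
    temps: pd.Series,
    cfg: ScenarioConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Patient-level records for one year.

    Per stratum-day the count is Poisson with rate
    ``max(0, c0 + c1 T + c2 T^2) * population scaling``, the scaling
    being the stratum's population in *year* relative to the base year.
    Counts are expanded to records with age uniform within the band
    (open band capped at ``cfg.age_cap``), plus optional triage and
    trauma fields drawn from the configured frequencies.
    """
    rng = _rng(cfg.seed if seed is None else seed, year, 2)
    band_by_label = {b.label: b for b in cfg.scheme}
    t = temps.to_numpy(dtype=float)
    dates = temps.index
    frames = []
    for (label, sex) in cfg.strata:
        c0, c1, c2 = cfg.rates[(label, sex)]
        band = band_by_label[label]
        base_n = cfg.base_population[(label, sex)]
        scaling = pyramid.count(band, sex) / base_n if base_n else 0.0
        lam = np.maximum(0.0, c0 + c1 * t + c2 * t**2) * scaling
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        hi = min(band.upper if band.upper is not None else cfg.age_cap, cfg.age_cap)
        ages = rng.integers(band.lower, hi + 1, size=total)
        frames.append(
            pd.DataFrame(
                {
                    "date": np.repeat(dates, counts),
                    "age": ages,
                    "sex": sex,
                    "triage": _draw_triage(rng, total, cfg),
                    "trauma": rng.random(total) < (cfg.trauma_prob or 0.0),
                }
            )
        )
    if not frames:
        return _coerce(pd.DataFrame(columns=RECORD_COLUMNS))
    df = pd.concat(frames, ignore_index=True).sort_values(["date", "sex", "age"], kind="stable")
    return _coerce(df.reset_index(drop=True))


def _draw_triage(rng: np.random.Generator, n: int, cfg: ScenarioConfig):
    if not cfg.triage_probs:
        return np.full(n, np.nan)
    levels = np.array(sorted(cfg.triage_probs))
    p = np.array([cfg.triage_probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    triage = rng.choice(levels, size=n, p=p).astype(float)
    if cfg.p_missing_triage > 0:
        triage[rng.random(n) < cfg.p_missing_triage] = np.nan
    return triage


@dataclass
class GroundTruth:
    """Closed-form truths implied by a scenario config (no sampling)."""

    weights: dict[int, WeightTable]  # per target year, from rounded pyramids
    rates: dict[Stratum, tuple[float, float, float]]
    expected_yearly: dict[tuple[int, Stratum], float]

    def expected_total(self, year: int) -> float:
        return sum(v for (y, _), v in self.expected_yearly.items() if y == year)


def ground_truth(cfg: ScenarioConfig, years: Sequence[int] | None = None) -> GroundTruth:
    """True weights, rate coefficients and yearly demand expectations.

    Weights are ratios of the generated (integer-rounded) pyramids, so a
    pipeline run on simulated files recovers them exactly.  The yearly
    expectation per stratum sums the rate curve along the deterministic
    seasonal path, adding the Jensen term ``b2 * sd^2`` per day for
    temperature noise (exact while the rate stays positive).
    """
    pyramids = simulate_pyramids(cfg)
    if years is None:
        years = [cfg.base_year, cfg.horizon_year]
    weights = {
        y: compute_weights(pyramids[cfg.base_year], pyramids[y], cfg.scheme) for y in years
    }
    expected: dict[tuple[int, Stratum], float] = {}
    band_by_label = {b.label: b for b in cfg.scheme}
    for year in years:
        t = _deterministic_temperature(year, cfg).to_numpy()
        for (label, sex) in cfg.strata:
            c0, c1, c2 = cfg.rates[(label, sex)]
            base_n = cfg.base_population[(label, sex)]
            scaling = (
                pyramids[year].count(band_by_label[label], sex) / base_n if base_n else 0.0
            )
            daily = np.maximum(0.0, c0 + c1 * t + c2 * t**2) + c2 * cfg.temp_sd**2
            expected[(year, (label, sex))] = float(daily.sum() * scaling)
    return GroundTruth(weights=weights, rates=dict(cfg.rates), expected_yearly=expected)


def write_scenario(
    cfg: ScenarioConfig,
    out_dir: str | Path,
    years: Sequence[int] | None = None,
) -> dict[str, Path]:
    """Emit the file dialects the readers consume, plus a manifest.

    Writes ``records_<year>.csv`` and ``temperature_<year>.csv`` for each
    requested record year (default: base year only), a single
    ``pyramids.csv`` covering base..horizon, and ``manifest.txt`` with
    the seed and config hash.  Byte-identical for identical (cfg, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    years = list(years) if years is not None else [cfg.base_year]
    header = f"# easdemand synthetic scenario seed={cfg.seed} config={cfg.config_hash()}\n"
    paths: dict[str, Path] = {}

    pyramids = simulate_pyramids(cfg)
    pyr_path = out_dir / "pyramids.csv"
    with open(pyr_path, "w") as fh:
        fh.write(header)
        pd.concat([p.to_frame() for _, p in sorted(pyramids.items())]).to_csv(fh, index=False)
    paths["pyramids"] = pyr_path

    for year in years:
        temps = simulate_temperature(year, cfg)
        tpath = out_dir / f"temperature_{year}.csv"
        with open(tpath, "w") as fh:
            fh.write(header)
            temps.round(3).rename_axis("date").to_frame().to_csv(fh, date_format="%Y-%m-%d")
        paths[f"temperature_{year}"] = tpath

        records = simulate_records(year, pyramids[year], temps, cfg)
        rpath = out_dir / f"records_{year}.csv"
        out = records.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out["trauma"] = out["trauma"].map({True: 1, False: 0})
        with open(rpath, "w") as fh:
            fh.write(header)
            out.to_csv(fh, index=False)
        paths[f"records_{year}"] = rpath

    man_path = out_dir / "manifest.txt"
    truth = ground_truth(cfg)
    with open(man_path, "w") as fh:
        fh.write(f"seed = {cfg.seed}\n")
        fh.write(f"config_hash = {cfg.config_hash()}\n")
        fh.write(f"base_year = {cfg.base_year}\n")
        fh.write(f"horizon_year = {cfg.horizon_year}\n")
        for (label, sex), (c0, c1, c2) in sorted(cfg.rates.items()):
            fh.write(f"rate[{label},{sex}] = {c0:.6f},{c1:.6f},{c2:.6f}\n")
        for y, w in sorted(truth.weights.items()):
            for key in sorted(w.weights):
                fh.write(f"weight[{y},{key[0]},{key[1]}] = {w.weights[key]:.6f}\n")
    paths["manifest"] = man_path
    return paths
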