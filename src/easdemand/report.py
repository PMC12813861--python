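"""End-to-end pipeline and report generation.

Runs the full analysis — aggregate records, compute weights, project
yearly demand, fit and project temperature equations — and writes the
report tables: weights, projections, base and projected equations, the
year-by-year trajectory, and temperature-demand curve tables.  All
numeric report rounding (weights 2 dp, coefficients 2 dp, demand to
integers, percentages to integers) lives here; upstream modules keep
full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .bands import BOTH, FEMALE, MALE, PROJECTION_BANDS, AgeBand, parse_scheme
from .demand import aggregate, read_records
from .outliers import grubbs_test
from .projection import ALL_BANDS, SUM_OF_SEX, DemandProjectionModel, trajectory
from .pyramids import compute_weights, read_pyramid
from .temperature import (
    QuadraticEquation,
    TemperatureDemandModel,
    combine,
    curve_table,
    project_equation,
    read_temperature,
)

logger = logging.getLogger("easdemand")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """File paths and analysis settings for one pipeline run."""

    records: str
    pyramids: str
    temperature: str
    out_dir: str
    base_year: int = 2015
    target_years: tuple[int, ...] = (2036, 2051)
    scheme: tuple[AgeBand, ...] = PROJECTION_BANDS
    both_mode: str = SUM_OF_SEX
    alpha: float = 0.05
    grid: tuple[float, float, float] = (0.0, 50.0, 1.0)  # t_min, t_max, step
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(y < self.base_year for y in self.target_years):
            raise ValueError("target years must not precede the base year")
        if isinstance(self.scheme, str):
            self.scheme = parse_scheme(self.scheme)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "target_years" in raw:
            raw["target_years"] = tuple(raw["target_years"])
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        return cls(**raw)

    def config_hash(self) -> str:
        # identifies the analysis settings; where outputs land is excluded
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, float_format: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# easdemand {__version__} config={cfg.config_hash()} seed={cfg.seed}\n"
        )
        df.to_csv(fh, index=False, float_format=float_format)


def _equation_rows(equations: dict[tuple[str, str], QuadraticEquation]) -> pd.DataFrame:
    rows = []
    for (label, sex), eq in equations.items():
        rows.append(
            {
                "sex": sex,
                "age_band": label,
                "constant": round(eq.constant, 2),
                "b1": round(eq.b1, 2),
                "b2": round(eq.b2, 2),
                "ci_b1_low": round(eq.ci_b1[0], 2) if eq.ci_b1 else None,
                "ci_b1_high": round(eq.ci_b1[1], 2) if eq.ci_b1 else None,
                "ci_b2_low": round(eq.ci_b2[0], 2) if eq.ci_b2 else None,
                "ci_b2_high": round(eq.ci_b2[1], 2) if eq.ci_b2 else None,
                "adj_r2": round(eq.adj_r2, 2) if eq.adj_r2 is not None else None,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full projection pipeline; returns written artifacts.

    Stages: read inputs -> aggregate demand -> screen yearly totals
    (when several years are present) -> compute weights -> project
    yearly demand -> fit temperature equations -> project and combine
    equations -> tabulate curves.  Any stage failure aborts with the
    stage named.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"easdemand {__version__}",
        f"config_hash = {cfg.config_hash()}",
        f"seed = {cfg.seed}",
    ]
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        log_lines.append(f"stage: {name}")

    try:
        stage("read_inputs")
        records = read_records(cfg.records)
        temps = read_temperature(cfg.temperature)
        pyramids = {
            year: read_pyramid(cfg.pyramids, year)
            for year in range(cfg.base_year, max(cfg.target_years) + 1)
        }
        log_lines.append(f"records_in = {len(records)}")

        stage("aggregate")
        daily = aggregate(records, cfg.scheme, period="daily")
        yearly = daily.to_yearly()
        log_lines.append(f"records_dropped_missing_age_or_sex = {daily.n_dropped}")

        stage("screen_yearly_totals")
        years = yearly.keys()
        if len(years) >= 3:
            totals = {y: yearly.total(y) for y in years}
            g = grubbs_test(totals, alpha=cfg.alpha)
            log_lines.append(
                f"grubbs: farthest={g.max_item} max_z={g.max_z:.3f} "
                f"critical={g.critical_value:.3f} significant={g.significant}"
            )
        else:
            log_lines.append("grubbs: skipped (fewer than 3 yearly totals)")

        stage("weights")
        weight_tables = [
            compute_weights(pyramids[cfg.base_year], pyramids[y], cfg.scheme)
            for y in cfg.target_years
        ]
        wdf = pd.concat([w.to_frame() for w in weight_tables], ignore_index=True)
        wdf["weight"] = wdf["weight"].round(2)
        artifacts["weights"] = out_dir / "weights.csv"
        _write_csv(wdf, artifacts["weights"], cfg, float_format="%.2f")

        stage("project_demand")
        model = DemandProjectionModel(yearly, weight_tables, cfg.both_mode)
        results = model.fit()
        artifacts["projection"] = out_dir / "projection.csv"
        _write_csv(results.summary(), artifacts["projection"], cfg)

        stage("trajectory")
        traj = trajectory(
            yearly, pyramids, cfg.scheme, cfg.both_mode, base_year=cfg.base_year
        )
        artifacts["trajectory"] = out_dir / "trajectory.csv"
        _write_csv(traj.round(1), artifacts["trajectory"], cfg, float_format="%.1f")

        stage("fit_equations")
        base_eqs: dict[tuple[str, str], QuadraticEquation] = {}
        for band in cfg.scheme:
            for sex in (MALE, FEMALE):
                fit = TemperatureDemandModel.from_demand_table(
                    daily, band, sex, temps
                ).fit()
                base_eqs[(band.label, sex)] = fit.equation
        artifacts["base_equations"] = out_dir / "base_equations.csv"
        _write_csv(_equation_rows(base_eqs), artifacts["base_equations"], cfg)

        stage("project_equations")
        rows = []
        curves = []
        combined_base = combine(base_eqs.values(), label="all/base")
        curves.append(("base", cfg.base_year, combined_base))
        for w in weight_tables:
            projected = {
                key: project_equation(eq, w.weight(*key)) for key, eq in base_eqs.items()
            }
            unadj = {
                key: project_equation(eq, w.overall_ratio) for key, eq in base_eqs.items()
            }
            for adjustment, eqs in (("adjusted", projected), ("unadjusted", unadj)):
                df = _equation_rows(eqs)
                df.insert(0, "target_year", w.target_year)
                df.insert(1, "adjustment", adjustment)
                rows.append(df)
                combined = combine(eqs.values())
                rows.append(
                    pd.DataFrame(
                        [
                            {
                                "target_year": w.target_year,
                                "adjustment": adjustment,
                                "sex": BOTH,
                                "age_band": ALL_BANDS,
                                "constant": round(combined.constant, 2),
                                "b1": round(combined.b1, 2),
                                "b2": round(combined.b2, 2),
                            }
                        ]
                    )
                )
                curves.append((adjustment, w.target_year, combined))
        artifacts["projected_equations"] = out_dir / "projected_equations.csv"
        _write_csv(pd.concat(rows, ignore_index=True), artifacts["projected_equations"], cfg)

        stage("curve_tables")
        t_min, t_max, step = cfg.grid
        curve_frames = []
        for scenario, year, eq in curves:
            df = curve_table(eq, t_min, t_max, step)
            df.insert(0, "scenario", scenario)
            df.insert(1, "year", year)
            curve_frames.append(df)
        artifacts["curves"] = out_dir / "curves.csv"
        _write_csv(
            pd.concat(curve_frames, ignore_index=True).round(3),
            artifacts["curves"],
            cfg,
            float_format="%.3f",
        )
    except Exception as err:
        current = next(
            (ln.split(": ", 1)[1] for ln in reversed(log_lines) if ln.startswith("stage:")),
            "unknown",
        )
        raise RuntimeError(f"pipeline failed at stage {current!r}: {err}") from err

    artifacts["log"] = out_dir / "run.log"
    with open(artifacts["log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return artifacts
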