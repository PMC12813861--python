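import filecmp

import numpy as np
import pandas as pd
import pytest

import easdemand as e
from easdemand import datasets
from easdemand.bands import FEMALE, MALE, AgeBand, validate_scheme
from easdemand.demand import aggregate
from easdemand.simulate import (
    ScenarioConfig,
    default_scenario,
    ground_truth,
    simulate_pyramids,
    simulate_records,
    simulate_temperature,
    write_scenario,
)

TWO_BAND = validate_scheme([AgeBand(0, 84), AgeBand(85, None)])


def tiny_config(**kw):
    defaults = dict(
        base_year=2015,
        horizon_year=2017,
        scheme=TWO_BAND,
        base_population={("0-84", MALE): 1000, ("0-84", FEMALE): 1000,
                         ("85+", MALE): 100, ("85+", FEMALE): 100},
        growth_rate={("0-84", MALE): 0.0, ("0-84", FEMALE): 0.0,
                     ("85+", MALE): 0.0, ("85+", FEMALE): 0.0},
        rates={("0-84", MALE): (0.0, 0.0, 0.0), ("0-84", FEMALE): (0.0, 0.0, 0.0),
               ("85+", MALE): (0.0, 0.0, 0.0), ("85+", FEMALE): (0.0, 0.0, 0.0)},
        temp_sd=0.0,
        p_missing_triage=0.0,
        seed=3,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestPyramids:
    def test_zero_growth_identical_every_year(self):
        pyramids = simulate_pyramids(tiny_config())
        for y, p in pyramids.items():
            assert p.counts == pyramids[2015].counts

    def test_36_year_factor_matches_target(self, scenario):
        pyramids = simulate_pyramids(scenario)
        w = e.compute_weights(pyramids[2015], pyramids[2051], scenario.scheme)
        assert w.weight("85+", FEMALE) == pytest.approx(10.13, abs=0.01)
        assert w.weight("0-64", MALE) == pytest.approx(0.76, abs=0.01)

    def test_rate_one_quadruples_in_two_years(self):
        cfg = tiny_config(growth_rate={k: 1.0 for k in tiny_config().growth_rate})
        pyramids = simulate_pyramids(cfg)
        assert pyramids[2017].count(AgeBand(85, None), MALE) == 400


class TestTemperature:
    def test_constant_when_no_amplitude_or_noise(self):
        cfg = tiny_config(temp_amplitude=0.0, temp_sd=0.0, temp_mean=23.0)
        t = simulate_temperature(2015, cfg)
        assert (t == 23.0).all()
        assert len(t) == 365

    def test_deterministic_extremes_at_phase(self):
        cfg = tiny_config(temp_sd=0.0, temp_phase_day=197)
        t = simulate_temperature(2015, cfg)
        assert t.idxmax().dayofyear == 197
        # coldest about half a year away from the peak
        assert abs(t.idxmin().dayofyear - (197 + 183) % 365) <= 2

    def test_annual_mean_across_seeds(self):
        cfg = tiny_config(temp_mean=23.0, temp_amplitude=6.0, temp_sd=2.0)
        means = [simulate_temperature(2015, cfg, seed=s).mean() for s in range(20)]
        assert np.mean(means) == pytest.approx(23.0, abs=0.5)

    def test_leap_year_has_366_days(self):
        assert len(simulate_temperature(2016, tiny_config())) == 366


class TestRecords:
    def test_zero_rates_no_records(self):
        cfg = tiny_config()
        pyramids = simulate_pyramids(cfg)
        temps = simulate_temperature(2015, cfg)
        records = simulate_records(2015, pyramids[2015], temps, cfg)
        assert len(records) == 0

    def test_constant_rate_poisson_total(self):
        cfg = tiny_config(rates={**tiny_config().rates, ("85+", MALE): (10.0, 0.0, 0.0)})
        pyramids = simulate_pyramids(cfg)
        temps = simulate_temperature(2015, cfg)
        records = simulate_records(2015, pyramids[2015], temps, cfg)
        # Poisson(3650): within 4 standard deviations
        assert abs(len(records) - 3650) < 4 * np.sqrt(3650)
        assert (records["sex"] == MALE).all()
        assert records["age"].between(85, 100).all()

    def test_default_scenario_matches_2015_margins(self):
        """Regenerated stratum totals sit within 5% of the published
        2015 breakdown for each of three seeds."""
        for seed in (0, 1, 2):
            cfg = default_scenario(seed=seed)
            pyramids = simulate_pyramids(cfg)
            temps = simulate_temperature(2015, cfg)
            records = simulate_records(2015, pyramids[2015], temps, cfg)
            yearly = aggregate(records, cfg.scheme, "yearly")
            for (label, sex), target in datasets.BASE_DEMAND_2015.items():
                got = yearly.value(2015, label, sex)
                assert got == pytest.approx(target, rel=0.05), (seed, label, sex)

    def test_poisson_dispersion_of_daily_cells(self, scenario, base_sim):
        _, temps, records = base_sim
        daily = aggregate(records, scenario.scheme, "daily")
        s = daily.stratum_series("85+", MALE).to_numpy(dtype=float)
        # residual dispersion about the generating curve is Poisson-like
        c0, c1, c2 = scenario.rates[("85+", MALE)]
        mu = np.maximum(0.0, c0 + c1 * temps.to_numpy() + c2 * temps.to_numpy() ** 2)
        index_of_dispersion = np.mean((s - mu) ** 2) / np.mean(mu)
        assert 0.8 < index_of_dispersion < 1.25


class TestSignalToNoise:
    def test_adj_r2_maximum_tracks_theoretical_signal_to_noise(self, scenario, base_sim):
        """The stratum with the largest fitted adjusted R² is the one
        whose rate curve has the largest variance relative to its
        Poisson noise (Var(mu) / (Var(mu) + mean(mu)))."""
        _, temps, records = base_sim
        daily = aggregate(records, scenario.scheme, "daily")
        t = temps.to_numpy()
        theoretical, fitted = {}, {}
        for (label, sex) in scenario.strata:
            c0, c1, c2 = scenario.rates[(label, sex)]
            mu = np.maximum(0.0, c0 + c1 * t + c2 * t**2)
            theoretical[(label, sex)] = mu.var() / (mu.var() + mu.mean())
            fit = e.TemperatureDemandModel.from_demand_table(
                daily, label, sex, temps
            ).fit()
            fitted[(label, sex)] = fit.adj_r2
        assert max(fitted, key=fitted.get) == max(theoretical, key=theoretical.get)


class TestGroundTruth:
    def test_identity_config_unit_weights(self):
        truth = ground_truth(tiny_config())
        for w in truth.weights.values():
            assert all(v == pytest.approx(1.0) for v in w.weights.values())

    def test_rates_passed_through(self):
        cfg = tiny_config(rates={**tiny_config().rates, ("85+", MALE): (5.0, -0.1, 0.01)})
        assert ground_truth(cfg).rates[("85+", MALE)] == (5.0, -0.1, 0.01)

    def test_expected_total_matches_direct_summation(self):
        cfg = tiny_config(rates={**tiny_config().rates, ("85+", FEMALE): (30.0, -1.0, 0.02)})
        truth = ground_truth(cfg)
        temps = simulate_temperature(2015, cfg)  # sd = 0: deterministic
        expected = sum(max(0.0, 30.0 - 1.0 * t + 0.02 * t * t) for t in temps)
        assert truth.expected_yearly[(2015, ("85+", FEMALE))] == pytest.approx(expected)


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path, small_scenario):
        a = write_scenario(small_scenario, tmp_path / "a")
        b = write_scenario(small_scenario, tmp_path / "b")
        for name in a:
            assert filecmp.cmp(a[name], b[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        cfg1 = tiny_config(rates={k: (5.0, 0, 0) for k in tiny_config().rates}, seed=1)
        cfg2 = tiny_config(rates={k: (5.0, 0, 0) for k in tiny_config().rates}, seed=2)
        r1 = simulate_records(2015, simulate_pyramids(cfg1)[2015],
                              simulate_temperature(2015, cfg1), cfg1)
        r2 = simulate_records(2015, simulate_pyramids(cfg2)[2015],
                              simulate_temperature(2015, cfg2), cfg2)
        assert len(r1) != len(r2) or not r1.equals(r2)

    def test_emitted_files_roundtrip_through_readers(self, tmp_path, small_scenario):
        paths = write_scenario(small_scenario, tmp_path, years=[2015])
        records = e.read_records(paths["records_2015"])
        temps = e.read_temperature(paths["temperature_2015"])
        pyramid = e.read_pyramid(paths["pyramids"], 2015)
        assert len(records) > 0
        assert len(temps) == 365
        assert pyramid.total() == pytest.approx(
            sum(small_scenario.base_population.values())
        )
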