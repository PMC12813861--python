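import pandas as pd
import pytest

import easdemand as e


@pytest.fixture(scope="session")
def scenario():
    """Default Taipei-like synthetic scenario."""
    return e.default_scenario(seed=11)


@pytest.fixture(scope="session")
def base_sim(scenario):
    """One simulated base year: pyramids, temperature, records."""
    pyramids = e.simulate_pyramids(scenario)
    temps = e.simulate_temperature(scenario.base_year, scenario)
    records = e.simulate_records(
        scenario.base_year, pyramids[scenario.base_year], temps, scenario
    )
    return pyramids, temps, records


@pytest.fixture(scope="session")
def small_scenario():
    """A down-scaled scenario (~10% of full volume) for pipeline tests."""
    full = e.default_scenario(seed=5)
    rates = {k: (c0 * 0.1, c1 * 0.1, c2 * 0.1) for k, (c0, c1, c2) in full.rates.items()}
    return e.default_scenario(seed=5, rates=rates)


def write_pyramid_csv(path, rows):
    """rows: iterable of (year, sex, age, count)."""
    df = pd.DataFrame(rows, columns=["year", "sex", "age", "count"])
    df.to_csv(path, index=False)
    return path
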