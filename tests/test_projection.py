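import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import easdemand as e
from easdemand import datasets
from easdemand.bands import BOTH, FEMALE, MALE, PROJECTION_BANDS
from easdemand.projection import (
    AGGREGATE_WEIGHT,
    ALL_BANDS,
    SUM_OF_SEX,
    DemandProjectionModel,
    misestimation,
    project_adjusted,
    project_unadjusted,
    trajectory,
)
from easdemand.pyramids import WeightTable
from easdemand.demand import table_from_counts


@pytest.fixture(scope="module")
def base_table():
    return table_from_counts(2015, datasets.BASE_DEMAND_2015, PROJECTION_BANDS)


def uniform_weights(k=1.0, base_year=2015, target_year=2036):
    w = {
        (b.label, s): k for b in PROJECTION_BANDS for s in (MALE, FEMALE, BOTH)
    }
    return WeightTable.from_mapping(base_year, target_year, w, overall_ratio=k)


class TestProjectAdjusted:
    def test_published_male_65_74(self, base_table):
        adj = project_adjusted(base_table, datasets.WEIGHTS_2036)
        assert adj[("65-74", MALE)] == pytest.approx(12_227.6, abs=0.1)
        assert adj[("65-74", MALE)] == pytest.approx(12_225, rel=5e-4)

    def test_published_both_85plus_aggregate_mode(self, base_table):
        adj = project_adjusted(
            base_table,
            datasets.WEIGHTS_2036,
            AGGREGATE_WEIGHT,
            both_base=datasets.BASE_DEMAND_2015_BOTH,
        )
        assert adj[("85+", BOTH)] == pytest.approx(17_218 * 3.43)
        assert adj[("85+", BOTH)] == pytest.approx(59_100, rel=1e-3)

    def test_identity_weights(self, base_table):
        adj = project_adjusted(base_table, uniform_weights(1.0))
        for key, n in datasets.BASE_DEMAND_2015.items():
            assert adj[key] == pytest.approx(n)

    def test_sum_of_sex_both_equals_male_plus_female(self, base_table):
        adj = project_adjusted(base_table, datasets.WEIGHTS_2051, SUM_OF_SEX)
        for label in ("0-64", "65-74", "75-84", "85+", ALL_BANDS):
            assert adj[(label, BOTH)] == pytest.approx(
                adj[(label, MALE)] + adj[(label, FEMALE)]
            )

    def test_modes_disagree_iff_sex_weights_differ(self, base_table):
        sum_mode = project_adjusted(base_table, datasets.WEIGHTS_2036, SUM_OF_SEX)
        agg_mode = project_adjusted(base_table, datasets.WEIGHTS_2036, AGGREGATE_WEIGHT)
        for label in ("0-64", "65-74", "75-84", "85+"):
            w = datasets.WEIGHTS_2036
            if w.weight(label, MALE) == w.weight(label, FEMALE):
                assert sum_mode[(label, BOTH)] == pytest.approx(agg_mode[(label, BOTH)])
        # documented inconsistency: 85+ male/female weights differ widely
        assert sum_mode[("85+", BOTH)] != pytest.approx(agg_mode[("85+", BOTH)], rel=1e-3)

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.integers(1, 10_000), b=st.integers(1, 10_000),
        wm=st.floats(0.1, 10), wf=st.floats(0.1, 10),
    )
    def test_linearity(self, a, b, wm, wf):
        w = WeightTable.from_mapping(
            2015, 2036,
            {(band.label, s): {MALE: wm, FEMALE: wf, BOTH: (wm + wf) / 2}[s]
             for band in PROJECTION_BANDS for s in (MALE, FEMALE, BOTH)},
            overall_ratio=1.0,
        )
        t1 = table_from_counts(2015, {("85+", MALE): a}, PROJECTION_BANDS)
        t2 = table_from_counts(2015, {("85+", MALE): b}, PROJECTION_BANDS)
        t12 = table_from_counts(2015, {("85+", MALE): a + b}, PROJECTION_BANDS)
        p1 = project_adjusted(t1, w)
        p2 = project_adjusted(t2, w)
        p12 = project_adjusted(t12, w)
        for key in p12:
            assert p12[key] == pytest.approx(p1[key] + p2[key], rel=1e-12)

    def test_constant_weights_equal_unadjusted(self, base_table):
        for mode in (SUM_OF_SEX, AGGREGATE_WEIGHT):
            adj = project_adjusted(base_table, uniform_weights(1.7), mode)
            unadj = project_unadjusted(base_table, uniform_weights(1.7))
            for key in adj:
                assert adj[key] == pytest.approx(unadj[key])


class TestProjectUnadjusted:
    def test_published_cells(self, base_table):
        w = uniform_weights(1.0405)
        unadj = project_unadjusted(base_table, w)
        assert unadj[("0-64", MALE)] == pytest.approx(51_560, abs=2)
        assert unadj[(ALL_BANDS, FEMALE)] == pytest.approx(55_502, abs=2)

    def test_ratio_one_is_identity(self, base_table):
        unadj = project_unadjusted(base_table, uniform_weights(1.0))
        for key, n in datasets.BASE_DEMAND_2015.items():
            assert unadj[key] == pytest.approx(n)


class TestMisestimation:
    @pytest.mark.parametrize(
        "adjusted, unadjusted, expected",
        [
            (190_599, 132_977, -30),
            (79_269, 7_992, -90),
            (123.0, 123.0, 0),
        ],
    )
    def test_published_percentages(self, adjusted, unadjusted, expected):
        assert round(misestimation(adjusted, unadjusted)) == expected

    def test_nonpositive_adjusted_rejected(self):
        with pytest.raises(ValueError):
            misestimation(0, 10)


class TestTrajectory:
    def test_constant_pyramids_flat_series(self, base_table):
        p = {
            y: e.PopulationPyramid(
                y, {(b, s): 100.0 for b in PROJECTION_BANDS for s in (MALE, FEMALE)}
            )
            for y in range(2015, 2020)
        }
        df = trajectory(base_table, p, PROJECTION_BANDS)
        total = base_table.total()
        assert np.allclose(df["adjusted_total"], total)
        assert np.allclose(df["unadjusted_total"], total)

    def test_only_oldest_growing_adjusted_above_unadjusted(self, base_table):
        def pyr(y):
            # oldest band: small population share but a large demand share,
            # so growth there lifts the adjusted series faster than the
            # overall population ratio lifts the unadjusted one
            counts = {(b, s): 10_000.0 for b in PROJECTION_BANDS for s in (MALE, FEMALE)}
            grow = 1.05 ** (y - 2015)
            counts[(PROJECTION_BANDS[-1], MALE)] = 100.0 * grow
            counts[(PROJECTION_BANDS[-1], FEMALE)] = 100.0 * grow
            return e.PopulationPyramid(y, counts)

        p = {y: pyr(y) for y in range(2015, 2025)}
        df = trajectory(base_table, p, PROJECTION_BANDS)
        after = df[df["year"] > 2015]
        assert (after["adjusted_total"] > after["unadjusted_total"]).all()

    def test_default_scenario_gap_nondecreasing(self, base_table, scenario):
        pyramids = e.simulate_pyramids(scenario)
        df = trajectory(base_table, pyramids, scenario.scheme)
        gap = df["adjusted_total"] - df["unadjusted_total"]
        assert (np.diff(gap) >= -1e-9).all()

    def test_missing_year_listed(self, base_table):
        p = {
            y: e.PopulationPyramid(
                y, {(b, s): 10.0 for b in PROJECTION_BANDS for s in (MALE, FEMALE)}
            )
            for y in (2015, 2017)
        }
        with pytest.raises(ValueError, match="2016"):
            trajectory(base_table, p, PROJECTION_BANDS)


class TestModelInterface:
    def test_results_summary_layout(self, base_table):
        model = DemandProjectionModel(
            base_table, [datasets.WEIGHTS_2036, datasets.WEIGHTS_2051]
        )
        res = model.fit()
        df = res.summary()
        assert set(df.columns) == {
            "target_year", "age_band", "sex", "actual_base",
            "unadjusted", "adjusted", "difference_pct",
        }
        assert res.lookup(2036, "65-74", MALE) == pytest.approx(12_227.6, abs=0.1)
        # integer-rounded report values
        row = df[(df.target_year == 2036) & (df.age_band == "65-74") & (df.sex == MALE)]
        assert int(row["adjusted"].iloc[0]) == 12_228

    def test_base_year_mismatch_rejected(self, base_table):
        w1 = uniform_weights(1.0)
        w2 = uniform_weights(1.0, base_year=2014, target_year=2036)
        with pytest.raises(ValueError, match="base year"):
            DemandProjectionModel(base_table, [w1, w2])
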