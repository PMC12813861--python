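"""Published Taipei reference values (base year 2015).

These are the printed inputs of the original Taipei study: yearly
demand totals 2011-2015, the 2015 age-gender demand breakdown, the
official population-change weighting factors for 2036 and 2051, and
the base-year temperature-demand regression equations.  They serve as
desk-scale inputs for reproducing the study's projections and as
calibration margins for the synthetic scenario.
"""

from __future__ import annotations

from .bands import BOTH, FEMALE, MALE
from .pyramids import WeightTable
from .temperature import QuadraticEquation

BASE_YEAR = 2015
TARGET_YEARS = (2036, 2051)
BAND_LABELS = ("0-64", "65-74", "75-84", "85+")

#: Total emergency ambulance calls per year, 2011-2015 (all records,
#: including those missing age or sex).
YEARLY_TOTALS = {
    2011: 141_250,
    2012: 140_153,
    2013: 136_988,
    2014: 143_243,
    2015: 144_539,
}

#: 2015 yearly demand by age band and sex (records with known age and
#: sex only; the gap to YEARLY_TOTALS[2015] is missing-field records).
BASE_DEMAND_2015 = {
    ("0-64", MALE): 49_554,
    ("0-64", FEMALE): 32_703,
    ("65-74", MALE): 7_366,
    ("65-74", FEMALE): 5_441,
    ("75-84", MALE): 8_029,
    ("75-84", FEMALE): 7_373,
    ("85+", MALE): 9_387,
    ("85+", FEMALE): 7_826,
}

#: Published 2015 both-sex demand per band.  These exceed male + female
#: because records with known age but missing sex are counted here;
#: the original aggregate-weight both-sex projections use these cells.
BASE_DEMAND_2015_BOTH = {
    "0-64": 82_361,
    "65-74": 12_815,
    "75-84": 15_409,
    "85+": 17_218,
}

_W2036 = {
    ("0-64", MALE): 0.86, ("0-64", FEMALE): 0.81, ("0-64", BOTH): 0.84,
    ("65-74", MALE): 1.66, ("65-74", FEMALE): 1.72, ("65-74", BOTH): 1.69,
    ("75-84", MALE): 2.61, ("75-84", FEMALE): 2.69, ("75-84", BOTH): 2.66,
    ("85+", MALE): 2.22, ("85+", FEMALE): 4.63, ("85+", BOTH): 3.43,
}
_W2051 = {
    ("0-64", MALE): 0.76, ("0-64", FEMALE): 0.66, ("0-64", BOTH): 0.71,
    ("65-74", MALE): 1.77, ("65-74", FEMALE): 1.78, ("65-74", BOTH): 1.78,
    ("75-84", MALE): 2.77, ("75-84", FEMALE): 2.91, ("75-84", BOTH): 2.85,
    ("85+", MALE): 4.20, ("85+", FEMALE): 10.13, ("85+", BOTH): 7.18,
}

#: Published age-gender weighting factors (two-decimal precision) with
#: the overall both-sex population ratios.
WEIGHTS_2036 = WeightTable.from_mapping(BASE_YEAR, 2036, _W2036, overall_ratio=1.04)
WEIGHTS_2051 = WeightTable.from_mapping(BASE_YEAR, 2051, _W2051, overall_ratio=1.02)
WEIGHT_TABLES = {2036: WEIGHTS_2036, 2051: WEIGHTS_2051}

#: Base-year quadratic temperature-demand equations per stratum
#: (counts/day as a function of daily mean temperature in °C).
BASE_EQUATIONS = {
    ("0-64", MALE): QuadraticEquation(
        153.31, -1.88, 0.05, ci_b1=(-3.82, 0.05), ci_b2=(0.00, 0.09),
        adj_r2=0.02, label="0-64/M"),
    ("65-74", MALE): QuadraticEquation(
        25.69, -0.37, 0.01, ci_b1=(-0.94, 0.20), ci_b2=(-0.01, 0.02),
        adj_r2=0.04, label="65-74/M"),
    ("75-84", MALE): QuadraticEquation(
        30.24, -0.55, 0.01, ci_b1=(-1.18, 0.07), ci_b2=(-0.01, 0.02),
        adj_r2=0.07, label="75-84/M"),
    ("85+", MALE): QuadraticEquation(
        45.12, -1.48, 0.03, ci_b1=(-2.26, -0.71), ci_b2=(0.01, 0.04),
        adj_r2=0.12, label="85+/M"),
    ("0-64", FEMALE): QuadraticEquation(
        91.67, -0.10, 0.00, ci_b1=(-1.41, 1.21), ci_b2=(-0.03, 0.03),
        adj_r2=0.00, label="0-64/F"),
    ("65-74", FEMALE): QuadraticEquation(
        18.72, -0.26, 0.00, ci_b1=(-0.67, 0.16), ci_b2=(-0.01, 0.01),
        adj_r2=0.03, label="65-74/F"),
    ("75-84", FEMALE): QuadraticEquation(
        29.87, -0.65, 0.01, ci_b1=(-1.20, -0.10), ci_b2=(-0.00, 0.02),
        adj_r2=0.12, label="75-84/F"),
    ("85+", FEMALE): QuadraticEquation(
        44.25, -1.69, 0.03, ci_b1=(-2.34, -1.04), ci_b2=(0.02, 0.04),
        adj_r2=0.24, label="85+/F"),
}

#: 2015 triage-level shares (levels 1-5) and trauma share, used as
#: categorical frequencies by the synthetic record generator.
TRIAGE_COUNTS_2015 = {1: 8_786, 2: 20_914, 3: 59_600, 4: 9_317, 5: 609}
TRAUMA_SHARE_2015 = 64_892 / (64_892 + 79_647)
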