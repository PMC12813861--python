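"""Grubbs' test (extreme studentized deviate) for a single outlier.

Used to screen yearly demand totals before adopting a base year: the
candidate year should not be a significant outlier among its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GrubbsResult", "grubbs_test", "grubbs_critical_value"]


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical value for the maximum studentized deviation.

    G = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError(f"Grubbs' test requires n >= 3, got {n}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


@dataclass
class GrubbsResult:
    z: pd.Series  # |x - mean| / s per item
    max_item: object  # label of the item farthest from the mean
    critical_value: float
    alpha: float
    significant: bool

    @property
    def max_z(self) -> float:
        return float(self.z.max())

    def summary(self) -> pd.DataFrame:
        df = self.z.rename("z").to_frame()
        df["farthest"] = df.index == self.max_item
        df["significant"] = df["farthest"] & self.significant
        return df


def grubbs_test(
    values: Mapping[object, float] | Sequence[float] | pd.Series,
    alpha: float = 0.05,
) -> GrubbsResult:
    """Two-sided Grubbs' test on a small sample of totals.

    Z_i = |x_i - mean| / s with s the sample (n-1 denominator) standard
    deviation.  ``significant`` is true when max Z exceeds the two-sided
    critical value at level *alpha*.  A zero-variance sample yields all
    Z = 0 and is never significant.
    """
    s = pd.Series(dict(values)) if isinstance(values, Mapping) else pd.Series(values)
    s = s.astype(float)
    n = len(s)
    crit = grubbs_critical_value(n, alpha)
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        z = pd.Series(0.0, index=s.index)
    else:
        z = (s - s.mean()).abs() / sd
    max_item = z.idxmax()
    return GrubbsResult(
        z=z,
        max_item=max_item,
        critical_value=float(crit),
        alpha=alpha,
        significant=bool(z.max() > crit),
    )
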