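"""Fire-regime trend analysis on annual event statistics.

Annual series of mean fire size, extreme (95th-percentile) fire size and
burnt area are tested for monotonic trend with the Mann-Kendall test and
summarised with the Theil-Sen slope; long-term change is reported as the
relative difference of the fitted endpoints. Small fires below a size
threshold (default 2 km2, strict) are excluded first for cross-registry
consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "annual_fire_stats",
    "mann_kendall",
    "theil_sen",
    "relative_change",
    "trend_summary",
]


@dataclass
class TrendResult:
    sen_slope: float          # units per year
    intercept: float
    mk_s: int
    mk_p: float               # two-tailed
    relative_change_pct: float


def annual_fire_stats(events: pd.DataFrame, min_size_km2: float = 2.0,
                      ) -> pd.DataFrame:
    """Per-year fire statistics over events strictly larger than the
    size threshold.

    ``events`` needs columns ``year`` and ``size_km2``. Returns a
    DataFrame indexed by year with mean_size, p95_size (linear-
    interpolation percentile), burnt_area and n_fires; years without any
    qualifying event are simply absent (missing, not zero).
    """
    sub = events.loc[events["size_km2"] > min_size_km2]
    if sub.empty:
        return pd.DataFrame(columns=["mean_size", "p95_size", "burnt_area",
                                     "n_fires"]).rename_axis("year")
    g = sub.groupby("year")["size_km2"]
    out = pd.DataFrame({
        "mean_size": g.mean(),
        "p95_size": g.quantile(0.95, interpolation="linear"),
        "burnt_area": g.sum(),
        "n_fires": g.size(),
    }).rename_axis("year")
    return out


def mann_kendall(series: Sequence[float]) -> tuple[int, float]:
    """Mann-Kendall trend test: (S, two-tailed p).

    S sums the signs of all pairwise later-minus-earlier differences.
    The p-value uses the normal approximation with the tie-corrected
    variance and a continuity correction.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 values")
    sgn = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(sgn, 1).sum())
    # tie-corrected variance
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return s, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(p)


def theil_sen(years: Sequence[float], values: Sequence[float],
              ) -> tuple[float, float]:
    """Theil-Sen fit: (slope, intercept).

    The slope is the median of all pairwise slopes (pairs sharing a year
    are skipped); the intercept is median(value - slope * year), so the
    fitted line is value = slope * year + intercept.
    """
    t = np.asarray(years, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2 or np.unique(t).size < 2:
        raise ValueError("Theil-Sen needs >= 2 points with distinct years")
    slope = float(stats.theilslopes(v, t).slope)
    intercept = float(np.median(v - slope * t))
    return slope, intercept


def relative_change(years: Sequence[float], values: Sequence[float]) -> float:
    """Relative change (%) between the Theil-Sen fitted end and start
    values, as a fraction of the fitted start value."""
    t = np.asarray(years, dtype=float)
    slope, intercept = theil_sen(t, values)
    start, end = t.min(), t.max()
    fit_start = slope * start + intercept
    fit_end = slope * end + intercept
    if fit_start == 0:
        raise ValueError("fitted start value is zero; relative change undefined")
    return 100.0 * (fit_end - fit_start) / fit_start


def trend_summary(years: Sequence[float], values: Sequence[float]) -> TrendResult:
    """Full trend report (Sen slope, Mann-Kendall S and p, % change)."""
    slope, intercept = theil_sen(years, values)
    s, p = mann_kendall(values)
    return TrendResult(sen_slope=slope, intercept=intercept, mk_s=s, mk_p=p,
                       relative_change_pct=relative_change(years, values))
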