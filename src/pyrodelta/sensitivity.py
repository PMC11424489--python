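"""Amplification of postfire responses with fire size.

The central statistic is the slope beta of y = a + beta * log10(fire
size), fitted per grid cell (with a minimum number of fires) and
domain-wide. Local slope significance uses the two-tailed t-test at
0.05; field significance across cells controls the false-discovery rate
with the Benjamini-Hochberg step-up at alpha_FDR = 0.10. A categorical
interaction model yields per-forest-type slopes and pairwise slope
contrasts; fire vulnerability is summarised per type with one-tailed
t-tests and Tukey HSD multiple comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CellRegressionResult",
    "InteractionModelResult",
    "cell_regression",
    "field_significance",
    "apply_field_significance",
    "domain_regression",
    "warming_per_doubling",
    "fraction_of_mean_warming",
    "interaction_model",
    "vulnerability_summary",
]

LOG10_2 = math.log10(2.0)


@dataclass
class CellRegressionResult:
    """OLS of a postfire change on log10(fire size) within one cell."""

    cell_id: object
    n_fires: int
    beta: float
    intercept: float
    p_value: float
    r_squared: float
    locally_significant: bool
    field_significant: bool | None = None  # filled by apply_field_significance


@dataclass
class InteractionModelResult:
    """Per-forest-type size slopes from a categorical interaction model."""

    slopes: dict[str, float]
    slope_se: dict[str, float]
    slope_p: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    r_squared: float


def _prepare(sizes, y, min_size_km2: float):
    sizes = np.asarray(sizes, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (sizes >= min_size_km2) & np.isfinite(y) & np.isfinite(sizes)
    return np.log10(sizes[keep]), y[keep]


def cell_regression(sizes: Sequence[float], y: Sequence[float],
                    cell_id: object = None, min_fires: int = 10,
                    min_size_km2: float = 1.0, alpha_local: float = 0.05,
                    ) -> CellRegressionResult | None:
    """Per-cell OLS of y on log10(size km2).

    Events below ``min_size_km2`` are excluded before fitting; cells with
    fewer than ``min_fires`` qualifying events, or without size spread,
    return None (no hypothesis tested).
    """
    logs, yv = _prepare(sizes, y, min_size_km2)
    if len(logs) < min_fires:
        return None
    if np.ptp(logs) == 0:
        return None  # undefined slope: all fires the same size
    if np.ptp(yv) == 0:
        # flat response: zero slope, no explained variance, nothing to reject
        return CellRegressionResult(cell_id=cell_id, n_fires=len(logs),
                                    beta=0.0, intercept=float(yv[0]),
                                    p_value=1.0, r_squared=0.0,
                                    locally_significant=False)
    res = stats.linregress(logs, yv)
    p = float(res.pvalue)
    return CellRegressionResult(
        cell_id=cell_id, n_fires=len(logs), beta=float(res.slope),
        intercept=float(res.intercept), p_value=p,
        r_squared=float(res.rvalue) ** 2,
        locally_significant=bool(p < alpha_local))


def field_significance(p_values: Sequence[float], alpha_fdr: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up field-significance mask.

    Sorts the p-values ascending, finds the largest k with
    p_(k) <= k * alpha / m and flags every test with p <= p_(k).
    Applied only across the hypotheses actually tested.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha_fdr, method="fdr_bh")
    return reject


def apply_field_significance(results: Sequence[CellRegressionResult],
                             alpha_fdr: float = 0.10) -> None:
    """Fill ``field_significant`` in place across a family of cell fits."""
    if not results:
        return
    mask = field_significance([r.p_value for r in results], alpha_fdr)
    for r, m in zip(results, mask):
        r.field_significant = bool(m) and r.locally_significant


def domain_regression(sizes: Sequence[float], y: Sequence[float],
                      min_size_km2: float = 1.0) -> tuple[float, float, float]:
    """Single OLS over the whole domain: returns (beta, se, p)."""
    logs, yv = _prepare(sizes, y, min_size_km2)
    if len(logs) < 3:
        raise ValueError("domain regression needs at least 3 events")
    if np.unique(logs).size < 2:
        raise ValueError("domain regression needs at least 2 distinct sizes")
    res = stats.linregress(logs, yv)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def warming_per_doubling(beta: float) -> float:
    """Convert a slope per log10(km2) into the change per size doubling."""
    return beta * LOG10_2


def fraction_of_mean_warming(per_doubling: float, regional_mean: float) -> float:
    """Per-doubling change as a percentage of the regional mean change."""
    if regional_mean == 0:
        raise ValueError("regional mean change is zero")
    return 100.0 * per_doubling / regional_mean


def interaction_model(sizes: Sequence[float], y: Sequence[float],
                      forest_types: Sequence[str],
                      min_size_km2: float = 1.0) -> InteractionModelResult:
    """Per-type size sensitivity via a categorical interaction OLS.

    Fits y ~ C(type) + log10(size) + C(type):log10(size); the per-type
    slope is the reference slope plus that type's interaction contrast,
    and pairwise slope differences are tested with two-tailed t-tests on
    the corresponding coefficient contrasts.
    """
    sizes = np.asarray(sizes, dtype=float)
    y = np.asarray(y, dtype=float)
    ftype = np.asarray(forest_types, dtype=object)
    keep = (sizes >= min_size_km2) & np.isfinite(y)
    sizes, y, ftype = sizes[keep], y[keep], ftype[keep]

    types = sorted(set(ftype))
    if len(types) < 2:
        raise ValueError("interaction model needs at least 2 forest types")
    for t in types:
        logs_t = np.log10(sizes[ftype == t])
        if len(logs_t) < 3 or np.unique(logs_t).size < 2:
            raise ValueError(f"forest type {t!r} lacks events or size spread "
                             "(need >= 3 events with >= 2 distinct sizes)")

    df = pd.DataFrame({"y": y, "logs": np.log10(sizes), "ftype": ftype})
    model = sm.OLS.from_formula("y ~ C(ftype) * logs", data=df).fit()

    ref = types[0]
    names = list(model.params.index)

    def slope_vector(t: str) -> np.ndarray:
        v = np.zeros(len(names))
        v[names.index("logs")] = 1.0
        if t != ref:
            v[names.index(f"C(ftype)[T.{t}]:logs")] = 1.0
        return v

    slopes, ses, ps = {}, {}, {}
    for t in types:
        tt = model.t_test(slope_vector(t))
        slopes[t] = float(np.ravel(tt.effect)[0])
        ses[t] = float(np.ravel(tt.sd)[0])
        ps[t] = float(np.ravel(tt.pvalue)[0])
    pairwise = {}
    for a, b in itertools.combinations(types, 2):
        tt = model.t_test(slope_vector(a) - slope_vector(b))
        pairwise[(a, b)] = float(np.ravel(tt.pvalue)[0])
    return InteractionModelResult(slopes=slopes, slope_se=ses, slope_p=ps,
                                  pairwise_p=pairwise,
                                  r_squared=float(model.rsquared))


def vulnerability_summary(values_by_type: Mapping[str, Sequence[float]],
                          direction: str = "greater",
                          alpha: float = 0.05) -> pd.DataFrame:
    """Fire vulnerability per forest type, with Tukey HSD comparisons.

    ``values_by_type`` maps forest type -> event-level changes (e.g.
    delta T or delta LAI). Each type's mean is tested against zero with
    a one-tailed t-test (``direction`` = "greater" for warming-type
    variables, "less" for LAI-type losses). Returns a DataFrame with
    per-type mean, n, one-tailed p, and, for every other type, the Tukey
    HSD rejection flag at ``alpha`` in columns ``tukey_vs_<type>``.
    Types with fewer than 2 events are excluded.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    groups = {t: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
              for t, v in values_by_type.items()}
    groups = {t: v for t, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 forest types with >= 2 events")

    rows = {}
    for t, v in groups.items():
        tt = stats.ttest_1samp(v, 0.0, alternative=direction)
        rows[t] = {"mean": float(v.mean()), "n": len(v),
                   "p_one_tailed": float(tt.pvalue)}

    data = np.concatenate(list(groups.values()))
    labels = np.concatenate([[t] * len(v) for t, v in groups.items()])
    tuk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    out = pd.DataFrame(rows).T
    for t in groups:
        out[f"tukey_vs_{t}"] = False
    for _, r in res.iterrows():
        a, b, rej = str(r["group1"]), str(r["group2"]), bool(r["reject"])
        out.loc[a, f"tukey_vs_{b}"] = rej
        out.loc[b, f"tukey_vs_{a}"] = rej
    return out
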