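"""Space-and-time counterfactual isolation of fire-induced changes.

For a burnt pixel the gross change of a variable between the year after
fire (lag L) and the year before fire mixes the fire effect with the
interannual background signal. Subtracting the mean gross change of
matched unburnt control pixels — nearby, same forest type, undisturbed —
removes the background term:

    delta = [v(pixel, y_fire + L) - v(pixel, y_fire - 1)]
          - mean_c [v(c, y_fire + L) - v(c, y_fire - 1)]

Event-level deltas are unweighted means over the event's burnt pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import FireEvent, GriddedScene

__all__ = [
    "ControlCriteria",
    "DeltaRecord",
    "select_controls",
    "pixel_delta",
    "event_delta",
    "compute_deltas",
    "daily_lst",
    "seasonal_mean",
]


@dataclass(frozen=True)
class ControlCriteria:
    """Rules for admitting unburnt control pixels.

    The search window is ``window_x_km`` x ``window_y_km`` centred on the
    target pixel (default 50 x 25 km, about 100 x 50 pixels at 500 m).
    A candidate is admitted if it is unburnt in every year from the fire
    year through the analysis year, carries the same (prefire) forest
    type, and its cumulative tree-cover loss over that period stays below
    ``max_cum_loss``.
    """

    window_x_km: float = 50.0
    window_y_km: float = 25.0
    max_cum_loss: float = 0.20
    require_same_forest_type: bool = True
    min_controls: int = 1

    def __post_init__(self) -> None:
        if self.window_x_km <= 0 or self.window_y_km <= 0:
            raise ValueError("window dimensions must be > 0")
        if not 0.0 <= self.max_cum_loss <= 1.0:
            raise ValueError("max_cum_loss must lie in [0, 1]")

    def half_extent_px(self, pixel_size_m: float) -> tuple[int, int]:
        """(half-rows, half-cols) of the window on a given grid."""
        wx = math.floor(self.window_x_km * 1000.0 / pixel_size_m)
        wy = math.floor(self.window_y_km * 1000.0 / pixel_size_m)
        return wy // 2, wx // 2


@dataclass
class DeltaRecord:
    """Event-level fire-induced change in one variable at one season/lag."""

    event_id: int
    variable: str
    season: str
    lag_years: int
    delta: float  # NaN when every pixel was dropped
    n_pixels_used: int
    n_pixels_dropped: int
    n_controls_mean: float = float("nan")


def select_controls(pixel: tuple[int, int], scene: GriddedScene, fire_year: int,
                    lag: int = 1, criteria: ControlCriteria = ControlCriteria(),
                    ) -> set[tuple[int, int]]:
    """All admissible control pixels for a burnt target pixel.

    Returns the (row, col) set inside the search window that (i) lies on
    the grid, (ii) is unburnt in every year from ``fire_year`` through
    ``fire_year + lag``, (iii) shares the target's prefire forest type,
    and (iv) accumulated less than ``max_cum_loss`` tree-cover loss over
    ``fire_year .. fire_year + lag``. The target itself is excluded; an
    empty set is a legal result.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    r0, c0 = pixel
    hr, hc = criteria.half_extent_px(scene.pixel_size_m)
    ny, nx = scene.shape
    r_lo, r_hi = max(0, r0 - hr), min(ny, r0 + hr + 1)
    c_lo, c_hi = max(0, c0 - hc), min(nx, c0 + hc + 1)

    by = scene.burn_year[r_lo:r_hi, c_lo:c_hi]
    ok = (by < fire_year) | (by > fire_year + lag)  # includes by == -1

    if criteria.require_same_forest_type:
        ok &= scene.forest_type[r_lo:r_hi, c_lo:c_hi] == scene.forest_type[r0, c0]

    yi0 = scene.year_index(fire_year)
    yi1 = scene.year_index(min(fire_year + lag, int(scene.years[-1])))
    cum_loss = scene.loss_fraction[yi0:yi1 + 1, r_lo:r_hi, c_lo:c_hi].sum(axis=0)
    ok &= cum_loss < criteria.max_cum_loss

    rows, cols = np.nonzero(ok)
    out = {(int(r + r_lo), int(c + c_lo)) for r, c in zip(rows, cols)}
    out.discard((r0, c0))
    return out


def _gross_change(scene: GriddedScene, variable: str, season: str,
                  fire_year: int, lag: int) -> np.ndarray:
    """Per-pixel v(fire_year + lag) - v(fire_year - 1) raster."""
    arr = scene.field(variable)
    si = scene.season_index(season)
    pre = arr[scene.year_index(fire_year - 1), si]
    post = arr[scene.year_index(fire_year + lag), si]
    return post - pre


def pixel_delta(pixel: tuple[int, int], variable: str, season: str,
                fire_year: int, lag: int, controls: Iterable[tuple[int, int]],
                scene: GriddedScene, min_controls: int = 1) -> float:
    """Counterfactual change for one burnt pixel; NaN if it must be dropped
    (too few controls, or missing pre/postfire values)."""
    controls = list(controls)
    gross = _gross_change(scene, variable, season, fire_year, lag)
    target = gross[pixel]
    if not np.isfinite(target):
        return float("nan")
    ctrl = np.array([gross[c] for c in controls], dtype=float)
    ctrl = ctrl[np.isfinite(ctrl)]
    if ctrl.size < min_controls:
        return float("nan")
    return float(target - ctrl.mean())


def event_delta(event: FireEvent, variable: str, season: str, lag: int,
                scene: GriddedScene,
                criteria: ControlCriteria = ControlCriteria()) -> DeltaRecord:
    """Event-level delta: unweighted mean of the per-pixel counterfactual
    changes over the event's burnt pixels.

    Pixels without enough admissible controls (or with missing values)
    are dropped and counted; if every pixel drops, ``delta`` is NaN and
    ``n_pixels_used`` is 0.
    """
    gross = _gross_change(scene, variable, season, event.fire_year, lag)
    values: list[float] = []
    n_controls: list[int] = []
    for r, c in map(tuple, event.pixels):
        ctrl = select_controls((r, c), scene, event.fire_year, lag, criteria)
        target = gross[r, c]
        ctrl_vals = np.array([gross[p] for p in ctrl], dtype=float)
        ctrl_vals = ctrl_vals[np.isfinite(ctrl_vals)]
        if not np.isfinite(target) or ctrl_vals.size < criteria.min_controls:
            continue
        values.append(float(target - ctrl_vals.mean()))
        n_controls.append(ctrl_vals.size)
    n_used = len(values)
    return DeltaRecord(
        event_id=event.event_id, variable=variable, season=season,
        lag_years=lag,
        delta=float(np.mean(values)) if n_used else float("nan"),
        n_pixels_used=n_used, n_pixels_dropped=event.n_pixels - n_used,
        n_controls_mean=float(np.mean(n_controls)) if n_controls else float("nan"))


def compute_deltas(scene: GriddedScene, events: Sequence[FireEvent],
                   variables: Sequence[str] = ("T", "albedo", "ET", "LAI"),
                   seasons: Sequence[str] = ("JJA", "DJF", "annual"),
                   lags: Sequence[int] = (1,),
                   criteria: ControlCriteria = ControlCriteria()) -> pd.DataFrame:
    """Delta table over events x variables x seasons x lags.

    Lags whose analysis year (or the prefire year) falls outside the
    scene's record are skipped for that event. Returns a DataFrame with
    one row per DeltaRecord.
    """
    rows = []
    y_min, y_max = int(scene.years[0]), int(scene.years[-1])
    for ev in events:
        if ev.fire_year - 1 < y_min:
            continue
        for lag in lags:
            if ev.fire_year + lag > y_max:
                continue
            # controls depend only on (pixel, fire year, lag): select once,
            # reuse across every variable and season
            controls = []
            for r, c in ev.pixels:
                ctrl = select_controls((int(r), int(c)), scene, ev.fire_year,
                                       lag, criteria)
                idx = np.array(sorted(ctrl), dtype=np.int64).reshape(-1, 2)
                controls.append((idx[:, 0], idx[:, 1]))
            for var in variables:
                for season in seasons:
                    gross = _gross_change(scene, var, season, ev.fire_year, lag)
                    values, n_ctrl = [], []
                    for (r, c), (cr, cc) in zip(ev.pixels, controls):
                        target = gross[r, c]
                        cv = gross[cr, cc]
                        cv = cv[np.isfinite(cv)]
                        if not np.isfinite(target) or cv.size < criteria.min_controls:
                            continue
                        values.append(float(target - cv.mean()))
                        n_ctrl.append(cv.size)
                    n_used = len(values)
                    rows.append(vars(DeltaRecord(
                        event_id=ev.event_id, variable=var, season=season,
                        lag_years=lag,
                        delta=float(np.mean(values)) if n_used else float("nan"),
                        n_pixels_used=n_used,
                        n_pixels_dropped=ev.n_pixels - n_used,
                        n_controls_mean=float(np.mean(n_ctrl)) if n_ctrl
                        else float("nan"))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temporal aggregation helpers (real-data mode)
# ---------------------------------------------------------------------------

def daily_lst(t_day, t_night):
    """Daily surface temperature: mean of the 10:30 day and 22:30 night
    overpasses. Missing inputs propagate (None -> None, NaN -> NaN)."""
    if t_day is None or t_night is None:
        return None
    return 0.5 * (np.asarray(t_day, dtype=float) + np.asarray(t_night, dtype=float)) \
        if np.ndim(t_day) or np.ndim(t_night) else 0.5 * (t_day + t_night)


def seasonal_mean(values: pd.Series, season: str) -> pd.Series:
    """Collapse a monthly series to per-year seasonal means.

    ``values`` must have a DatetimeIndex (or PeriodIndex) at monthly or
    finer resolution. Seasons: "JJA" (Jun-Aug), "DJF" (Dec of the prior
    year + Jan-Feb, labelled by the January-February year) and "annual"
    (calendar year). Years where every contributing value is missing are
    returned as NaN-free gaps (omitted).
    """
    if season not in ("JJA", "DJF", "annual"):
        raise ValueError(f"unknown season {season!r}")
    s = values.copy()
    idx = pd.DatetimeIndex(s.index.to_timestamp() if isinstance(s.index, pd.PeriodIndex)
                           else s.index)
    month, year = idx.month, idx.year.to_numpy()
    if season == "JJA":
        mask = (month >= 6) & (month <= 8)
        label = year
    elif season == "DJF":
        mask = (month == 12) | (month <= 2)
        label = np.where(month == 12, year + 1, year)
    else:
        mask = np.ones(len(s), dtype=bool)
        label = year
    sub = pd.Series(s.to_numpy(dtype=float)[mask], index=label[mask])
    out = sub.groupby(level=0).mean()  # skips NaN; all-NaN season -> NaN
    return out.dropna()
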