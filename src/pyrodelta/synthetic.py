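"""Synthetic boreal/temperate fire landscapes.

Generates multi-year gridded scenes (surface temperature, albedo,
evapotranspiration, leaf area index, emissivity bands, incoming shortwave)
together with a fire-event table, with the statistical structure the
downstream attribution analysis assumes:

* fire sizes follow a base-10 log-normal distribution truncated below,
* fire effects on each biogeophysical variable are linear in
  log10(fire size), differ by forest type, and decay over postfire years,
* interannual background anomalies are shared by every pixel of a year
  (so the space-and-time counterfactual recovers injected effects exactly
  in the zero-noise limit),
* independent per-pixel observation noise,
* 30-m forest-loss subpixel counts inside each 500-m pixel,
* active-fire detections with scan angles.

All randomness flows through a single integer seed; identical
configuration + seed gives bit-identical output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FOREST_TYPES",
    "TYPE_CODES",
    "NONFOREST",
    "SyntheticConfig",
    "GriddedScene",
    "FireEvent",
    "ActiveFireDetection",
    "PlacementError",
    "generate_fire_sizes",
    "generate_scene",
    "generate_active_fires",
    "injected_effect",
]

#: Forest classes distinguished by the analysis. Codes index baseline tables.
FOREST_TYPES = ("ENF", "DNF", "DBF", "MF")
NONFOREST = 0
TYPE_CODES = {"none": 0, "ENF": 1, "DNF": 2, "DBF": 3, "MF": 4}
CODE_NAMES = {v: k for k, v in TYPE_CODES.items()}

SEASONS = ("JJA", "DJF", "annual")

#: Scene raster fields, one array of shape (year, season, y, x) each.
FIELDS = ("T_day", "T_night", "albedo", "ET", "LAI", "e29", "e31", "e32", "SW_in")

#: Weights of the empirical broadband-emissivity combination of MODIS
#: bands 29/31/32 (sum = 1.0010).
EMIS_WEIGHTS = (0.2122, 0.3859, 0.4029)
_EMIS_WSUM = sum(EMIS_WEIGHTS)

# Seasonal baselines per class (rows: none, ENF, DNF, DBF, MF; cols: JJA, DJF, annual)
_BASE = {
    "T_day": [[302.0, 262.0, 282.0], [299.0, 263.0, 281.0], [300.0, 262.0, 281.0],
              [301.0, 264.0, 283.0], [300.0, 263.0, 282.0]],
    "T_night": [[284.0, 252.0, 268.0], [283.0, 254.0, 269.0], [283.0, 253.0, 268.0],
                [284.0, 255.0, 270.0], [283.0, 254.0, 269.0]],
    "albedo": [[0.17, 0.55, 0.30], [0.10, 0.25, 0.16], [0.11, 0.28, 0.18],
               [0.16, 0.45, 0.26], [0.13, 0.35, 0.21]],
    "ET": [[1.8, 0.15, 1.0], [2.6, 0.20, 1.4], [2.4, 0.18, 1.3],
           [3.2, 0.22, 1.7], [2.9, 0.20, 1.5]],
    "LAI": [[1.0, 0.3, 0.6], [3.5, 2.5, 3.0], [3.0, 0.6, 1.8],
            [4.5, 0.5, 2.4], [4.0, 1.2, 2.6]],
    "e29": [[0.968, 0.968, 0.968]] + [[0.975, 0.975, 0.975]] * 4,
    "e31": [[0.982, 0.982, 0.982]] + [[0.986, 0.986, 0.986]] * 4,
    "e32": [[0.978, 0.978, 0.978]] + [[0.983, 0.983, 0.983]] * 4,
    "SW_in": [[250.0, 60.0, 155.0]] * 5,
}

#: Default fire-effect slope (per log10 km2 of fire size) by variable and
#: forest type; ordering ENF > DNF > MF > DBF in magnitude throughout,
#: with near-zero effects in DBF.
DEFAULT_EFFECT_SLOPES: dict[str, dict[str, float]] = {
    "T": {"ENF": 0.55, "DNF": 0.48, "DBF": 0.06, "MF": 0.30},
    "albedo": {"ENF": -0.008, "DNF": -0.007, "DBF": -0.001, "MF": -0.004},
    "ET": {"ENF": -0.22, "DNF": -0.18, "DBF": -0.02, "MF": -0.10},
    "LAI": {"ENF": -0.55, "DNF": -0.45, "DBF": -0.05, "MF": -0.25},
    "emissivity": {"ENF": -0.001, "DNF": -0.0008, "DBF": -0.0001, "MF": -0.0005},
    "mortality": {"ENF": 0.12, "DNF": 0.10, "DBF": 0.02, "MF": 0.06},
}

#: Default lag-1 effect at 1 km2 (the regression intercept) by variable/type.
DEFAULT_EFFECT_INTERCEPTS: dict[str, dict[str, float]] = {
    "T": {"ENF": 0.20, "DNF": 0.15, "DBF": 0.02, "MF": 0.08},
    "albedo": {"ENF": -0.002, "DNF": -0.0015, "DBF": 0.0, "MF": -0.001},
    "ET": {"ENF": -0.10, "DNF": -0.08, "DBF": -0.01, "MF": -0.05},
    "LAI": {"ENF": -0.30, "DNF": -0.25, "DBF": -0.03, "MF": -0.12},
    "emissivity": {"ENF": -0.0005, "DNF": -0.0004, "DBF": 0.0, "MF": -0.0002},
    "mortality": {"ENF": 0.10, "DNF": 0.08, "DBF": 0.02, "MF": 0.05},
}

DEFAULT_BACKGROUND_SD: dict[str, float] = {
    "T_day": 0.6, "T_night": 0.5, "albedo": 0.004, "ET": 0.10, "LAI": 0.10,
    "e29": 0.001, "e31": 0.001, "e32": 0.001, "SW_in": 5.0,
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "T_day": 0.5, "T_night": 0.5, "albedo": 0.008, "ET": 0.12, "LAI": 0.20,
    "e29": 0.0015, "e31": 0.0015, "e32": 0.0015, "SW_in": 0.0,
}

DEFAULT_FOREST_FRACTIONS = {"ENF": 0.35, "DNF": 0.20, "DBF": 0.15, "MF": 0.20, "none": 0.10}

#: Seasonal modulation of the injected fire effect. Postfire signals are
#: summer-dominated; winter responses are much weaker (and winter ET
#: baselines are small enough that a full-strength effect would violate
#: physical bounds), so the injected effect is scaled per season.
DEFAULT_SEASON_EFFECT_SCALE = {"JJA": 1.0, "DJF": 0.1, "annual": 0.6}


class PlacementError(RuntimeError):
    """Raised when fires cannot be placed disjointly on the grid."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterisation of a synthetic scene.

    ``effect_slopes`` / ``effect_intercepts`` define, per variable and
    forest type, the injected lag-1 fire effect
    ``intercept + slope * log10(size_km2)``; the effect decays by a factor
    ``2**(-(lag-1)/decay_halflife_yr)`` in later postfire years (lag 1 is
    the reference year and carries the undecayed effect).
    """

    grid_nx: int = 120
    grid_ny: int = 120
    pixel_size_m: float = 500.0
    years: tuple[int, ...] = tuple(range(2002, 2012))
    fire_years: tuple[int, ...] | None = None  # None: any year with a prefire and postfire neighbour
    n_fires: int = 40
    lognormal_mu: float = 0.8
    lognormal_sigma: float = 0.6
    min_size_km2: float = 1.0
    effect_slopes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_EFFECT_SLOPES)
    effect_intercepts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_EFFECT_INTERCEPTS)
    season_effect_scale: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_SEASON_EFFECT_SCALE)
    decay_halflife_yr: float = 7.0
    background_sd: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_BACKGROUND_SD)
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_NOISE_SD)
    forest_fractions: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_FOREST_FRACTIONS)
    n_type_patches: int = 30
    n_subpixels: int = 278  # 30-m Landsat subpixels per 500-m cell
    background_loss_rate: float = 0.003
    disturbance_rate: float = 0.01
    disturbance_loss_frac: float = 0.30
    mortality_split: tuple[float, float] = (0.7, 0.3)  # fire year, year+1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.forest_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"forest_fractions sum to {total}, expected 1")
        if self.min_size_km2 <= 0:
            raise ValueError("min_size_km2 must be > 0")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        for name, sd in list(self.background_sd.items()) + list(self.noise_sd.items()):
            if sd < 0:
                raise ValueError(f"negative s.d. for {name}")

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size_m / 1000.0) ** 2

    def with_(self, **kw) -> "SyntheticConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    def zero_noise(self) -> "SyntheticConfig":
        """Copy with all observation noise and background variation off."""
        zeros = {k: 0.0 for k in DEFAULT_NOISE_SD}
        return replace(self, noise_sd=zeros, background_sd=dict(zeros),
                       background_loss_rate=0.0, disturbance_rate=0.0)


@dataclass
class FireEvent:
    """A single burnt patch: contiguous same-year pixel set plus metadata."""

    event_id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    start_date: _dt.date
    end_date: _dt.date
    size_km2: float
    duration_days: int
    spread_rate: float  # km2 day-1
    fire_year: int
    dominant_type: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if self.end_date < self.start_date:
            raise ValueError("end_date before start_date")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


@dataclass(frozen=True)
class ActiveFireDetection:
    """One thermal-anomaly detection (MCD14ML-style record)."""

    x_m: float
    y_m: float
    date: _dt.date
    frp_mw: float
    scan_angle_deg: float

    def __post_init__(self) -> None:
        if self.frp_mw < 0:
            raise ValueError("frp_mw must be >= 0")
        if abs(self.scan_angle_deg) > 65:
            raise ValueError("scan angle beyond sensor swath (|angle| <= 65)")


@dataclass
class GriddedScene:
    """Multi-year stack of seasonal rasters on a regular 500-m-style grid.

    ``fields[name]`` has shape (n_years, n_seasons, ny, nx); seasons are
    ordered ("JJA", "DJF", "annual") with DJF labelled by the year of its
    January–February. ``burn_year`` is -1 for never-burnt pixels (each
    pixel burns at most once in a scene). ``loss_count`` holds per-year
    counts of 30-m subpixels undergoing forest loss; ``forest_subpixels``
    the baseline forest subpixel count per cell.
    """

    years: np.ndarray
    fields: dict[str, np.ndarray]
    forest_type: np.ndarray          # (ny, nx) int8 codes, 0 = non-forest
    burn_year: np.ndarray            # (ny, nx) int32, -1 = unburnt
    loss_count: np.ndarray           # (n_years, ny, nx) int32
    forest_subpixels: np.ndarray     # (ny, nx) int32
    n_subpixels: int
    pixel_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    seasons: tuple[str, ...] = SEASONS

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        shape = (len(self.years), len(self.seasons), *self.forest_type.shape)
        for name, arr in self.fields.items():
            if arr.shape != shape:
                raise ValueError(f"field {name!r} has shape {arr.shape}, expected {shape}")

    # -- indexing helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.forest_type.shape

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in scene ({self.years[0]}..{self.years[-1]})")
        return int(idx[0])

    def season_index(self, season: str) -> int:
        try:
            return self.seasons.index(season)
        except ValueError:
            raise KeyError(f"unknown season {season!r}") from None

    def field(self, variable: str) -> np.ndarray:
        """Raster stack for a stored or derived variable.

        ``"T"`` is the day/night mean surface temperature and
        ``"emissivity"`` the broadband combination of the three stored
        emissivity bands.
        """
        if variable in self.fields:
            return self.fields[variable]
        if variable == "T":
            return 0.5 * (self.fields["T_day"] + self.fields["T_night"])
        if variable == "emissivity":
            w29, w31, w32 = EMIS_WEIGHTS
            return (w29 * self.fields["e29"] + w31 * self.fields["e31"]
                    + w32 * self.fields["e32"])
        raise KeyError(f"unknown variable {variable!r}")

    @property
    def loss_fraction(self) -> np.ndarray:
        """Per-year fractional 30-m loss of each 500-m pixel."""
        return self.loss_count / float(self.n_subpixels)

    def forest_type_name(self, row: int, col: int) -> str:
        return CODE_NAMES[int(self.forest_type[row, col])]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_fire_sizes(n: int, mu: float, sigma: float, min_size: float = 1.0,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw fire sizes (km2) from a base-10 log-normal truncated below.

    log10(size) ~ Normal(mu, sigma); draws below ``min_size`` are
    resampled (truncation by rejection), so every returned size is
    >= ``min_size``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if min_size <= 0:
        raise ValueError("min_size must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    if sigma == 0:
        size = 10.0 ** mu
        if size < min_size:
            raise ValueError("degenerate distribution lies entirely below min_size")
        return np.full(n, size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = 10.0 ** rng.normal(mu, sigma, size=n - filled)
        keep = draw[draw >= min_size]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def _voronoi_types(ny: int, nx: int, fractions: Mapping[str, float],
                   n_patches: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous forest-type mosaic: nearest-seed (Voronoi) assignment
    with seeds allotted to classes in proportion to their target share."""
    names = [k for k in fractions if fractions[k] > 0]
    shares = np.array([fractions[k] for k in names])
    counts = np.maximum(1, np.round(shares * n_patches).astype(int))
    seed_types = np.concatenate([np.full(c, TYPE_CODES[name])
                                 for name, c in zip(names, counts)])
    rng.shuffle(seed_types)
    k = len(seed_types)
    sy = rng.uniform(0, ny, size=k)
    sx = rng.uniform(0, nx, size=k)
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy[..., None] - sy) ** 2 + (xx[..., None] - sx) ** 2
    return seed_types[np.argmin(d2, axis=-1)].astype(np.int8)


def _grow_patch(seed_px: tuple[int, int], n_target: int, allowed: np.ndarray,
                rng: np.random.Generator) -> list[tuple[int, int]] | None:
    """Region-grow a 4-connected patch of ``n_target`` pixels inside the
    ``allowed`` mask; returns None if growth stalls before reaching it."""
    ny, nx = allowed.shape
    patch = [seed_px]
    member = {seed_px}
    frontier = [seed_px]
    while len(patch) < n_target:
        if not frontier:
            return None
        i = rng.integers(len(frontier))
        r, c = frontier[i]
        nbrs = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < ny and 0 <= c + dc < nx
                and (r + dr, c + dc) not in member and allowed[r + dr, c + dc]]
        if not nbrs:
            frontier.pop(i)
            continue
        nxt = nbrs[rng.integers(len(nbrs))]
        patch.append(nxt)
        member.add(nxt)
        frontier.append(nxt)
    return patch


def _event_effect(cfg: SyntheticConfig, variable: str, ftype: str, size_km2: float) -> float:
    slope = cfg.effect_slopes.get(variable, {}).get(ftype, 0.0)
    intercept = cfg.effect_intercepts.get(variable, {}).get(ftype, 0.0)
    return intercept + slope * np.log10(size_km2)


def injected_effect(cfg: SyntheticConfig, variable: str, forest_type: str,
                    size_km2: float, season: str = "JJA", lag: int = 1) -> float:
    """The fire effect the generator injects for one variable.

    ``[intercept(v,f) + slope(v,f) * log10(size)] * season_scale(season)
    * 2**(-(lag-1)/decay_halflife)`` — the quantity the counterfactual
    machinery should recover in the zero-noise limit.
    """
    if lag < 1:
        return 0.0
    return (_event_effect(cfg, variable, forest_type, size_km2)
            * cfg.season_effect_scale.get(season, 1.0)
            * 2.0 ** (-(lag - 1) / cfg.decay_halflife_yr))


def generate_scene(config: SyntheticConfig) -> tuple[GriddedScene, list[FireEvent]]:
    """Build a scene and its fire-event table from a configuration.

    For a burnt pixel of an event with dominant forest type ``f`` the
    postfire value of variable ``v`` at lag ``L`` is::

        baseline(v, type, season) + background(year, season, v)
          + (intercept(v, f) + slope(v, f) * log10(size))
            * season_scale(season) * 2**(-(L-1)/halflife)
          + noise

    The background anomaly is one scalar per (year, season, field) shared
    by every pixel, which makes the counterfactual recovery exact when
    noise is switched off. Fires are compact 4-connected patches, placed
    disjointly (each pixel burns at most once per scene).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.grid_ny, cfg.grid_nx
    years = np.asarray(cfg.years, dtype=np.int64)
    n_years, n_seasons = len(years), len(SEASONS)

    forest_type = _voronoi_types(ny, nx, cfg.forest_fractions, cfg.n_type_patches, rng)

    # baseline + spatially uniform interannual background anomaly
    fields: dict[str, np.ndarray] = {}
    for name in FIELDS:
        base = np.asarray(_BASE[name])[forest_type]          # (ny, nx, 3)
        base = np.moveaxis(base, -1, 0)                      # (3, ny, nx)
        anomaly = rng.normal(0.0, cfg.background_sd.get(name, 0.0),
                             size=(n_years, n_seasons))
        fields[name] = base[None] + anomaly[:, :, None, None]

    # baseline forest subpixels and background (non-fire) loss
    nsub = cfg.n_subpixels
    forest_subpixels = np.where(
        forest_type > 0,
        np.round(nsub * rng.uniform(0.7, 1.0, size=(ny, nx))),
        np.round(nsub * rng.uniform(0.0, 0.10, size=(ny, nx)))).astype(np.int32)
    loss_count = np.zeros((n_years, ny, nx), dtype=np.int32)
    if cfg.background_loss_rate > 0:
        loss_count += rng.binomial(forest_subpixels[None], cfg.background_loss_rate,
                                   size=(n_years, ny, nx)).astype(np.int32)
    if cfg.disturbance_rate > 0:
        disturbed = rng.random((n_years, ny, nx)) < cfg.disturbance_rate
        loss_count += np.where(
            disturbed, np.round(cfg.disturbance_loss_frac * forest_subpixels[None]),
            0).astype(np.int32)

    # place fires (disjoint compact patches on forest) and inject effects
    burn_year = np.full((ny, nx), -1, dtype=np.int32)
    if n_years < 3 and cfg.n_fires > 0:
        raise PlacementError("need at least 3 years (prefire, fire, postfire)")
    if cfg.fire_years is not None:
        fire_years_pool = np.asarray(cfg.fire_years, dtype=np.int64)
        if not (set(fire_years_pool) <= set(years[1:-1].tolist())):
            raise ValueError("fire_years must leave a prefire and a postfire "
                             "year inside the simulated span")
    else:
        fire_years_pool = years[1:-1]  # keep a prefire and a lag-1 year in range
    sizes = generate_fire_sizes(cfg.n_fires, cfg.lognormal_mu, cfg.lognormal_sigma,
                                cfg.min_size_km2, rng)
    px_area = cfg.pixel_area_km2
    available = forest_type > 0
    events: list[FireEvent] = []
    from .characterization import dominant_forest_type  # local: avoids import cycle

    for i, size in enumerate(sizes):
        n_px = max(1, int(round(size / px_area)))
        patch = None
        for _ in range(200):
            cand = np.argwhere(available)
            if cand.size == 0:
                break
            r, c = cand[rng.integers(len(cand))]
            patch = _grow_patch((int(r), int(c)), n_px, available, rng)
            if patch is not None:
                break
        if patch is None:
            raise PlacementError(
                f"could not place fire {i} of {n_px} pixels on a "
                f"{ny}x{nx} grid without overlap; enlarge the grid or "
                f"reduce n_fires / fire sizes")
        rows = np.array([p[0] for p in patch])
        cols = np.array([p[1] for p in patch])
        available[rows, cols] = False
        fire_year = int(rng.choice(fire_years_pool))
        burn_year[rows, cols] = fire_year

        start = _dt.date(fire_year, 6, 1) + _dt.timedelta(days=int(rng.integers(0, 60)))
        actual_size = n_px * px_area
        duration = max(1, int(round(2.0 * np.sqrt(actual_size)
                                    * rng.uniform(0.5, 1.5))))
        event = FireEvent(
            event_id=i, pixels=np.column_stack([rows, cols]),
            start_date=start, end_date=start + _dt.timedelta(days=duration - 1),
            size_km2=actual_size, duration_days=duration,
            spread_rate=actual_size / duration, fire_year=fire_year)
        event.dominant_type = dominant_forest_type(event, forest_type)
        events.append(event)

        ftype = event.dominant_type if event.dominant_type in FOREST_TYPES else "MF"
        effects = {v: _event_effect(cfg, v, ftype, actual_size)
                   for v in cfg.effect_slopes}
        season_scale = np.array([cfg.season_effect_scale.get(s, 1.0)
                                 for s in SEASONS])
        for yi, year in enumerate(years):
            lag = int(year) - fire_year
            if lag < 1:
                continue
            decay = 2.0 ** (-(lag - 1) / cfg.decay_halflife_yr)
            for v, eff in effects.items():
                # advanced indexing puts the pixel axis first: shape (npix, nseasons)
                d = eff * decay * season_scale
                if v == "T":
                    fields["T_day"][yi, :, rows, cols] += d
                    fields["T_night"][yi, :, rows, cols] += d
                elif v == "emissivity":
                    for band in ("e29", "e31", "e32"):
                        fields[band][yi, :, rows, cols] += d / _EMIS_WSUM
                elif v == "mortality":
                    pass  # handled below via loss counts
                else:
                    fields[v][yi, :, rows, cols] += d
        # fire-driven forest loss: mortality fraction split over the fire
        # year and the following year
        mort = float(np.clip(effects.get("mortality", 0.0), 0.0, 1.0))
        for share, year in zip(cfg.mortality_split, (fire_year, fire_year + 1)):
            if year in years:
                yi = int(np.flatnonzero(years == year)[0])
                loss_count[yi, rows, cols] += np.round(
                    share * mort * forest_subpixels[rows, cols]).astype(np.int32)

    # observation noise, then physical clipping
    for name in FIELDS:
        sd = cfg.noise_sd.get(name, 0.0)
        if sd > 0:
            fields[name] += rng.normal(0.0, sd, size=fields[name].shape)
    for name in ("albedo", "e29", "e31", "e32"):
        np.clip(fields[name], 0.0, 1.0, out=fields[name])
    for name in ("ET", "LAI", "SW_in"):
        np.clip(fields[name], 0.0, None, out=fields[name])
    np.minimum(loss_count, nsub, out=loss_count)

    scene = GriddedScene(years=years, fields=fields, forest_type=forest_type,
                         burn_year=burn_year, loss_count=loss_count,
                         forest_subpixels=forest_subpixels, n_subpixels=nsub,
                         pixel_size_m=cfg.pixel_size_m)
    return scene, events


def generate_active_fires(events: Sequence[FireEvent],
                          frp_mu: float = 30.0, frp_sigma: float = 40.0,
                          detections_per_km2: float = 1.0,
                          scan_range_deg: tuple[float, float] = (0.0, 55.0),
                          pixel_size_m: float = 500.0,
                          seed: int | np.random.Generator = 0,
                          ) -> list[ActiveFireDetection]:
    """Scatter active-fire detections over each event's patch.

    Detection counts are Poisson with mean ``detections_per_km2 * size``;
    positions are uniform within the patch pixels, dates uniform within
    the event's burning window, FRP log-normal with mean ``frp_mu`` MW and
    s.d. ``frp_sigma`` MW, and scan angles uniform in ``scan_range_deg``.
    """
    if detections_per_km2 < 0 or frp_mu < 0 or frp_sigma < 0:
        raise ValueError("rates and FRP moments must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # log-normal by moment matching on (mean, sd)
    if frp_mu > 0:
        s2 = np.log1p((frp_sigma / frp_mu) ** 2)
        mu_log, sd_log = np.log(frp_mu) - s2 / 2, np.sqrt(s2)
    out: list[ActiveFireDetection] = []
    for ev in events:
        n = rng.poisson(detections_per_km2 * ev.size_km2)
        if n == 0:
            continue
        idx = rng.integers(len(ev.pixels), size=n)
        jitter = rng.uniform(0.0, 1.0, size=(n, 2))
        rows = ev.pixels[idx, 0] + jitter[:, 0]
        cols = ev.pixels[idx, 1] + jitter[:, 1]
        span = (ev.end_date - ev.start_date).days
        offsets = rng.integers(0, span + 1, size=n)
        frp = (np.exp(rng.normal(mu_log, sd_log, size=n)) if frp_mu > 0
               else np.zeros(n))
        angles = rng.uniform(*scan_range_deg, size=n)
        for k in range(n):
            out.append(ActiveFireDetection(
                x_m=float(cols[k] * pixel_size_m),
                y_m=float(rows[k] * pixel_size_m),
                date=ev.start_date + _dt.timedelta(days=int(offsets[k])),
                frp_mw=float(frp[k]), scan_angle_deg=float(angles[k])))
    return out
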