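"""Readers and writers for scenes, event tables and detections.

Scenes travel as NetCDF (one variable per field, dimensions
year x season x y x x, written through xarray's scipy backend); event
tables and detections as CSV; patch outlines as GeoJSON polygons in the
scene's projected metre coordinates.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping

from .characterization import event_perimeter
from .synthetic import FIELDS, ActiveFireDetection, FireEvent, GriddedScene

__all__ = [
    "scene_to_netcdf", "scene_from_netcdf",
    "events_to_csv", "events_from_csv",
    "detections_to_csv", "detections_from_csv",
    "events_to_geojson",
]


def scene_to_netcdf(scene: GriddedScene, path: str | Path) -> None:
    data = {name: (("year", "season", "y", "x"), arr.astype(np.float32))
            for name, arr in scene.fields.items()}
    data["forest_type"] = (("y", "x"), scene.forest_type.astype(np.int8))
    data["burn_year"] = (("y", "x"), scene.burn_year.astype(np.int32))
    data["loss_count"] = (("year", "y", "x"), scene.loss_count.astype(np.int32))
    data["forest_subpixels"] = (("y", "x"), scene.forest_subpixels.astype(np.int32))
    ds = xr.Dataset(data, coords={"year": scene.years.astype(np.int32)})
    ds.attrs.update({
        "seasons": ",".join(scene.seasons),
        "pixel_size_m": scene.pixel_size_m,
        "n_subpixels": scene.n_subpixels,
        "origin_x": scene.origin[0], "origin_y": scene.origin[1],
    })
    ds.to_netcdf(path, engine="scipy")


def scene_from_netcdf(path: str | Path) -> GriddedScene:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    fields = {name: np.asarray(ds[name].values, dtype=np.float64) for name in FIELDS}
    return GriddedScene(
        years=np.asarray(ds["year"].values, dtype=np.int64),
        fields=fields,
        forest_type=np.asarray(ds["forest_type"].values, dtype=np.int8),
        burn_year=np.asarray(ds["burn_year"].values, dtype=np.int32),
        loss_count=np.asarray(ds["loss_count"].values, dtype=np.int32),
        forest_subpixels=np.asarray(ds["forest_subpixels"].values, dtype=np.int32),
        n_subpixels=int(ds.attrs["n_subpixels"]),
        pixel_size_m=float(ds.attrs["pixel_size_m"]),
        origin=(float(ds.attrs["origin_x"]), float(ds.attrs["origin_y"])),
        seasons=tuple(ds.attrs["seasons"].split(",")))


def _pixels_str(pixels: np.ndarray) -> str:
    return ";".join(f"{r}:{c}" for r, c in pixels)


def _pixels_parse(s: str) -> np.ndarray:
    return np.array([[int(a) for a in p.split(":")] for p in s.split(";")],
                    dtype=np.int64)


def events_to_csv(events: Sequence[FireEvent], path: str | Path) -> None:
    rows = [{
        "event_id": ev.event_id, "fire_year": ev.fire_year,
        "start_date": ev.start_date.isoformat(), "end_date": ev.end_date.isoformat(),
        "size_km2": ev.size_km2, "duration_days": ev.duration_days,
        "spread_rate": ev.spread_rate, "dominant_type": ev.dominant_type or "",
        "pixels": _pixels_str(ev.pixels),
    } for ev in events]
    pd.DataFrame(rows).to_csv(path, index=False)


def events_from_csv(path: str | Path) -> list[FireEvent]:
    df = pd.read_csv(path, dtype={"dominant_type": str}, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(FireEvent(
            event_id=int(r["event_id"]), pixels=_pixels_parse(r["pixels"]),
            start_date=_dt.date.fromisoformat(r["start_date"]),
            end_date=_dt.date.fromisoformat(r["end_date"]),
            size_km2=float(r["size_km2"]), duration_days=int(r["duration_days"]),
            spread_rate=float(r["spread_rate"]), fire_year=int(r["fire_year"]),
            dominant_type=r["dominant_type"] or None))
    return out


def detections_to_csv(detections: Sequence[ActiveFireDetection],
                      path: str | Path) -> None:
    pd.DataFrame([{
        "x_m": d.x_m, "y_m": d.y_m, "date": d.date.isoformat(),
        "frp_mw": d.frp_mw, "scan_angle_deg": d.scan_angle_deg,
    } for d in detections]).to_csv(path, index=False)


def detections_from_csv(path: str | Path) -> list[ActiveFireDetection]:
    df = pd.read_csv(path)
    return [ActiveFireDetection(
        x_m=float(r["x_m"]), y_m=float(r["y_m"]),
        date=_dt.date.fromisoformat(r["date"]),
        frp_mw=float(r["frp_mw"]), scan_angle_deg=float(r["scan_angle_deg"]))
        for _, r in df.iterrows()]


def events_to_geojson(events: Sequence[FireEvent], path: str | Path,
                      pixel_size_m: float = 500.0) -> None:
    """Patch outlines as a GeoJSON FeatureCollection (metre coordinates)."""
    features = [{
        "type": "Feature",
        "geometry": mapping(event_perimeter(ev, pixel_size_m)),
        "properties": {"event_id": ev.event_id, "fire_year": ev.fire_year,
                       "size_km2": ev.size_km2,
                       "dominant_type": ev.dominant_type},
    } for ev in events]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
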