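"""Per-event fire characteristics: intensity, mortality, forest type.

Fire intensity is summarised as FRP density — total fire radiative power
of the event's active-fire detections divided by their total observed
ground area, where each detection's footprint grows with scan angle off
nadir. Forest mortality is the fraction of baseline 30-m forest
subpixels lost within a fixed window after the fire. The dominant forest
type follows a 50%-of-burnt-pixels rule, with a mixed-forest fallback.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .synthetic import CODE_NAMES, FOREST_TYPES, TYPE_CODES, ActiveFireDetection, FireEvent

__all__ = [
    "EventCharacteristics",
    "pixel_ground_area",
    "event_perimeter",
    "assign_detections",
    "event_frp_density",
    "event_mortality",
    "dominant_forest_type",
    "characterize_events",
]


@dataclass
class EventCharacteristics:
    """Summary of one event: FRP density (NaN when no detections were
    assigned), detection count, mortality fraction, dominant type."""

    event_id: int
    frp_density: float  # MW km-2
    n_detections: int
    mortality: float    # fraction in [0, 1], NaN if no baseline forest
    dominant_type: str  # ENF/DNF/DBF/MF/unclassified


def pixel_ground_area(scan_angle_deg: float, nominal_km: float = 1.0,
                      altitude_km: float = 705.0) -> float:
    """Ground footprint (km2) of a detection pixel at a given scan angle.

    Flat-Earth approximation: the along-track length grows as sec(theta)
    and the along-scan length as sec^2(theta), so the area is
    nominal^2 * sec^3(theta). Even in theta, equal to nominal^2 at nadir,
    strictly increasing in |theta|. ``altitude_km`` is accepted for
    interface stability with an Earth-curvature-aware variant but is not
    used by this approximation.
    """
    if abs(scan_angle_deg) >= 90.0:
        raise ValueError("|scan angle| must be < 90 degrees")
    sec = 1.0 / math.cos(math.radians(scan_angle_deg))
    return nominal_km ** 2 * sec ** 3


def event_perimeter(event: FireEvent, pixel_size_m: float = 500.0):
    """Patch outline as a shapely geometry (union of pixel squares)."""
    px = pixel_size_m
    boxes = [box(c * px, r * px, (c + 1) * px, (r + 1) * px)
             for r, c in event.pixels]
    return unary_union(boxes)


def assign_detections(event: FireEvent, detections: Sequence[ActiveFireDetection],
                      buffer_m: float = 500.0, pixel_size_m: float = 500.0,
                      ) -> list[ActiveFireDetection]:
    """Detections belonging to an event.

    A detection is assigned when its centre lies inside the patch or
    within ``buffer_m`` of its perimeter (boundary counts as inside) and
    its date falls in [start_date, end_date], both ends inclusive.
    """
    zone = event_perimeter(event, pixel_size_m).buffer(buffer_m)
    out = []
    for det in detections:
        if not (event.start_date <= det.date <= event.end_date):
            continue
        if zone.covers(Point(det.x_m, det.y_m)):
            out.append(det)
    return out


def event_frp_density(assigned: Sequence[ActiveFireDetection],
                      nominal_km: float = 1.0) -> float:
    """Mean FRP per unit observed area (MW km-2): total FRP of the
    assigned detections over their total scan-angle-corrected area.
    NaN when nothing was assigned."""
    if not assigned:
        return float("nan")
    total_frp = sum(d.frp_mw for d in assigned)
    total_area = sum(pixel_ground_area(d.scan_angle_deg, nominal_km) for d in assigned)
    return total_frp / total_area


def event_mortality(event: FireEvent, loss_count: np.ndarray,
                    forest_subpixels: np.ndarray, years: np.ndarray,
                    window_years: int = 2) -> float:
    """Postfire forest mortality fraction for an event.

    Per burnt 500-m pixel: 30-m subpixels lost during the fire year and
    the following ``window_years - 1`` years, divided by the pixel's
    baseline forest subpixels; the event value is the unweighted mean
    over pixels with at least one baseline forest subpixel. NaN if no
    pixel has baseline forest.
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    years = np.asarray(years)
    yi0 = int(np.flatnonzero(years == event.fire_year)[0])
    yi1 = min(yi0 + window_years, len(years))
    rows, cols = event.pixels[:, 0], event.pixels[:, 1]
    lost = loss_count[yi0:yi1, rows, cols].sum(axis=0).astype(float)
    base = forest_subpixels[rows, cols].astype(float)
    valid = base >= 1
    if not valid.any():
        return float("nan")
    return float(np.clip(lost[valid] / base[valid], 0.0, 1.0).mean())


def dominant_forest_type(event: FireEvent, landcover: np.ndarray) -> str:
    """Dominant forest type of an event from the prefire land-cover map.

    ENF, DNF or DBF when that single type covers at least 50% of the
    event's pixels (ties at exactly 50% resolved in the fixed order
    ENF > DNF > DBF); otherwise MF when all forest classes together
    cover more than 50%; otherwise "unclassified".
    """
    codes = landcover[event.pixels[:, 0], event.pixels[:, 1]]
    n = len(codes)
    counts = {name: int(np.sum(codes == TYPE_CODES[name])) for name in FOREST_TYPES}
    for name in ("ENF", "DNF", "DBF"):
        if counts[name] / n >= 0.5:
            return name
    forest_total = sum(counts.values())
    if forest_total / n > 0.5:
        return "MF"
    return "unclassified"


def characterize_events(events: Sequence[FireEvent],
                        detections: Sequence[ActiveFireDetection],
                        loss_count: np.ndarray, forest_subpixels: np.ndarray,
                        years: np.ndarray, landcover: np.ndarray,
                        buffer_m: float = 500.0, pixel_size_m: float = 500.0,
                        window_years: int = 2) -> list[EventCharacteristics]:
    """Characterise every event (intensity, mortality, dominant type)."""
    out = []
    for ev in events:
        assigned = assign_detections(ev, detections, buffer_m, pixel_size_m)
        out.append(EventCharacteristics(
            event_id=ev.event_id,
            frp_density=event_frp_density(assigned),
            n_detections=len(assigned),
            mortality=event_mortality(ev, loss_count, forest_subpixels, years,
                                      window_years),
            dominant_type=dominant_forest_type(ev, landcover)))
    return out
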