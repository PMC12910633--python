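"""Trip segmentation, rhumb-line trip typing, and trip metrics.

A trip is a maximal run of fixes beyond a buffered colony polygon. Trips
bracketed by at-colony fixes and free of long internal gaps are complete;
only complete trips enter trip statistics. Trip type separates inland
(terrestrial) excursions from offshore (marine) and mixed ones using a fan
of two constant-bearing lines anchored at the colony: birds from an island
colony must cross water, so terrestrial trips are those whose furthest
point is inland and whose inland fixes all fall inside the fan sector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .raster import Raster

__all__ = ["Trip", "RhumbFan", "segment_trips", "classify_trip_type", "trip_metrics", "trips_table"]


class GeometryError(ValueError):
    pass


@dataclass
class RhumbFan:
    """Two azimuths (degrees clockwise from north) bounding the inland sector."""

    colony_xy: tuple[float, float]
    az_low: float
    az_high: float

    def __post_init__(self) -> None:
        if (self.az_low % 360.0) == (self.az_high % 360.0):
            raise ValueError("fan azimuths must be distinct")

    def contains(self, x, y) -> np.ndarray:
        dx = np.asarray(x, float) - self.colony_xy[0]
        dy = np.asarray(y, float) - self.colony_xy[1]
        az = np.degrees(np.arctan2(dx, dy)) % 360.0
        lo, hi = self.az_low % 360.0, self.az_high % 360.0
        if lo <= hi:
            return (az >= lo) & (az <= hi)
        return (az >= lo) | (az <= hi)


@dataclass
class Trip:
    bird_id: str
    trip_id: int
    fixes: pd.DataFrame          # fixes outside the colony buffer, time-sorted
    start: pd.Timestamp
    end: pd.Timestamp
    complete: bool
    type: str | None = None      # terrestrial | marine | mixed

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


def segment_trips(
    track: pd.DataFrame,
    colony: Polygon | Point,
    buffer_m: float = 100.0,
    max_gap_h: float = 5.0,
) -> tuple[list[Trip], np.ndarray]:
    """Split a track into colony-anchored trips.

    Returns ``(trips, at_colony)`` where `at_colony` is a boolean mask over
    the track's rows; trip fixes and at-colony fixes partition the track.
    A trip is complete when it is bracketed by at-colony fixes on both
    sides *and* no consecutive-fix gap inside it exceeds `max_gap_h` hours
    (long gaps mean the device slept mid-trip and the excursion shape is
    unknown).
    """
    if colony is None or getattr(colony, "is_empty", False):
        raise GeometryError("colony polygon is empty")
    buffered = colony.buffer(buffer_m)
    cx, cy = colony.centroid.x, colony.centroid.y
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)
    # a point colony admits a fast radial test; arbitrary outlines go
    # through shapely point-in-polygon
    if colony.geom_type == "Point":
        inside = np.hypot(x - cx, y - cy) <= buffer_m
    else:
        from shapely import contains_xy

        inside = contains_xy(buffered, x, y)
    trips: list[Trip] = []
    ts = pd.to_datetime(track["timestamp"])
    t = ts.astype("int64").to_numpy() / 1e9
    n = len(track)
    i = 0
    trip_no = 0
    while i < n:
        if not inside[i]:
            j = i
            while j + 1 < n and not inside[j + 1]:
                j += 1
            gaps = np.diff(t[i : j + 1])
            bracketed = (i > 0) and (j < n - 1)
            complete = bracketed and (len(gaps) == 0 or gaps.max() <= max_gap_h * 3600.0)
            trips.append(
                Trip(
                    bird_id=str(track["bird_id"].iloc[0]) if "bird_id" in track else "",
                    trip_id=trip_no,
                    fixes=track.iloc[i : j + 1].reset_index(drop=True),
                    start=ts.iloc[i],
                    end=ts.iloc[j],
                    complete=bool(complete),
                )
            )
            trip_no += 1
            i = j + 1
        else:
            i += 1
    return trips, inside


def classify_trip_type(trip: Trip, marine_mask: Raster, fan: RhumbFan) -> str:
    """Label a trip terrestrial, marine or mixed.

    Every fix is first classed marine or inland from the mean-low-water
    mask (points beyond the mask extent are offshore). Then:

    * all fixes marine -> ``marine``;
    * at least one inland fix, the distal (furthest-from-colony) point
      inland, and every inland fix inside the fan -> ``terrestrial``;
    * anything else with an inland fix -> ``mixed``.
    """
    if trip.n_fixes == 0:
        raise ValueError("cannot classify an empty trip")
    x = trip.fixes["x"].to_numpy(float)
    y = trip.fixes["y"].to_numpy(float)
    marine = marine_mask.value_at(x, y, outside=1).astype(bool)
    inland = ~marine
    if not inland.any():
        return "marine"
    cx, cy = fan.colony_xy
    d = np.hypot(x - cx, y - cy)
    distal = int(np.argmax(d))  # argmax takes the earliest fix on ties
    if inland[distal] and fan.contains(x[inland], y[inland]).all():
        return "terrestrial"
    return "mixed"


def trip_metrics(trip: Trip, colony_xy: tuple[float, float]) -> dict | None:
    """Foraging range (km) and duration (h) for a complete trip.

    Incomplete trips yield None: their true extent is unknown, so they are
    excluded from trip statistics (while their fixes remain available to
    habitat analyses).
    """
    if not trip.complete:
        return None
    d = np.hypot(
        trip.fixes["x"].to_numpy(float) - colony_xy[0],
        trip.fixes["y"].to_numpy(float) - colony_xy[1],
    )
    return {
        "bird_id": trip.bird_id,
        "trip_id": trip.trip_id,
        "d_max_km": float(d.max()) / 1000.0,
        "duration_h": (trip.end - trip.start).total_seconds() / 3600.0,
    }


def trips_table(
    trips: list[Trip], colony_xy: tuple[float, float], species: str | None = None
) -> pd.DataFrame:
    """Tidy per-trip summary (metrics only for complete trips)."""
    rows = []
    for tr in trips:
        m = trip_metrics(tr, colony_xy)
        rows.append({
            "bird_id": tr.bird_id,
            "species": species,
            "trip_id": tr.trip_id,
            "start": tr.start,
            "end": tr.end,
            "complete": tr.complete,
            "type": tr.type,
            "d_max_km": m["d_max_km"] if m else np.nan,
            "duration_h": m["duration_h"] if m else np.nan,
        })
    return pd.DataFrame(rows)
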