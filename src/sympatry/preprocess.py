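"""GPS fix reading, quality filtering, thinning and colony-period windowing.

Tracks are tidy pandas DataFrames, one row per fix, with at least
(bird_id, timestamp, x, y) and optionally (species, satellites, fix_valid).
Positions are planar metres; timestamps timezone-aware UTC. A TrackSet is a
dict mapping bird_id to its time-sorted track.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "read_fix_table",
    "clean_fixes",
    "thin_track",
    "window_colony_period",
    "project_lonlat",
    "CleanReport",
]

REQUIRED_COLUMNS = ("bird_id", "timestamp")


class SchemaError(ValueError):
    pass


@dataclass
class CleanReport:
    """Bookkeeping for one track's quality filter."""

    n_in: int = 0
    n_satellites: int = 0
    n_speed: int = 0
    n_invalid: int = 0
    removed_index: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_satellites + self.n_speed + self.n_invalid

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


def project_lonlat(lon, lat, lon0: float, lat0: float):
    """Project lon/lat (degrees) to a local planar metre frame.

    A local transverse-Mercator-style approximation centred on
    (`lon0`, `lat0`): adequate for study regions a few hundred km across,
    which is all the colony-associated analyses require. Synthetic data is
    already planar and never passes through here.
    """
    R = 6_371_000.0
    lam = np.radians(np.asarray(lon) - lon0)
    phi = np.radians(np.asarray(lat))
    phi0 = np.radians(lat0)
    x = R * lam * np.cos(phi)
    y = R * (phi - phi0)
    return x, y


def read_fix_table(path, schema: dict[str, str] | None = None, project: bool = False):
    """Read a Movebank-style fix CSV into a TrackSet.

    `schema` maps source column names onto the canonical ones; pass e.g.
    ``{"individual-local-identifier": "bird_id"}``. With ``project=True``
    the table must carry lon/lat, which are projected to a local plane
    centred on the mean position.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: empty fix table")
        return {}
    n0 = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    bad = df["timestamp"].isna()
    if bad.any():
        log.warning("%s: dropped %d malformed rows", path, int(bad.sum()))
        df = df[~bad]
    df = df.drop_duplicates()
    if len(df) < n0 - int(bad.sum()):
        warnings.warn(f"{path}: removed {n0 - int(bad.sum()) - len(df)} duplicated rows")
    if project:
        if not {"lon", "lat"} <= set(df.columns):
            raise SchemaError("projection requested but lon/lat columns absent")
        x, y = project_lonlat(df["lon"], df["lat"], df["lon"].mean(), df["lat"].mean())
        df["x"], df["y"] = x, y
    if not {"x", "y"} <= set(df.columns):
        raise SchemaError("missing required columns: ['x', 'y']")
    tracks = {}
    for bird, sub in df.groupby("bird_id", sort=True):
        tracks[str(bird)] = sub.sort_values("timestamp").reset_index(drop=True)
    return tracks


def clean_fixes(
    track: pd.DataFrame,
    max_speed: float = 30.0,
    min_satellites: int = 4,
    require_valid: bool = True,
) -> tuple[pd.DataFrame, CleanReport]:
    """Remove inaccurate positions from a time-sorted track.

    Three filters, applied in one forward pass:

    * fixes with fewer than `min_satellites` satellites (i.e. three or
      fewer at the default);
    * fixes flagged invalid by the device (`fix_valid` False), when that
      column exists and `require_valid`;
    * fixes whose ground speed from the *last retained* fix exceeds
      `max_speed` m/s — recomputing against the last retained fix stops a
      single position spike from cascading into removal of its neighbours.
    """
    report = CleanReport(n_in=len(track))
    if len(track) < 2:
        warnings.warn("track has fewer than 2 fixes; returned unchanged")
        return track.reset_index(drop=True), report
    t = pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 1e9
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)
    sats = track["satellites"].to_numpy() if "satellites" in track.columns else None
    valid = track["fix_valid"].to_numpy() if ("fix_valid" in track.columns and require_valid) else None

    keep = np.ones(len(track), dtype=bool)
    last = None
    for i in range(len(track)):
        if sats is not None and sats[i] < min_satellites:
            keep[i] = False
            report.n_satellites += 1
            continue
        if valid is not None and not valid[i]:
            keep[i] = False
            report.n_invalid += 1
            continue
        if last is not None:
            dt = t[i] - t[last]
            if dt > 0 and np.hypot(x[i] - x[last], y[i] - y[last]) / dt > max_speed:
                keep[i] = False
                report.n_speed += 1
                continue
        last = i
    report.removed_index = list(track.index[~keep])
    return track[keep].reset_index(drop=True), report


def thin_track(
    track: pd.DataFrame, target_interval: float = 1800.0, tolerance: float = 0.4
) -> pd.DataFrame:
    """Thin a dense track towards a target sampling interval (seconds).

    Greedy forward selection: from the last accepted fix, accept the future
    fix whose gap is closest to `target_interval` among those within
    ``target_interval * (1 ± tolerance)`` (±12 min at the 30-min default).
    Where the data are already sparser than the upper window edge the next
    fix passes through unchanged, so low-resolution devices are untouched.
    """
    if target_interval <= 0:
        raise ValueError("target_interval must be positive")
    if len(track) <= 1:
        return track.reset_index(drop=True)
    t = pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 1e9
    lo = target_interval * (1.0 - tolerance)
    hi = target_interval * (1.0 + tolerance)
    keep = [0]
    i = 0
    n = len(t)
    while True:
        t_last = t[keep[-1]]
        j_lo = np.searchsorted(t, t_last + lo, side="left")
        j_hi = np.searchsorted(t, t_last + hi, side="right")
        if j_lo < j_hi:  # candidates inside the acceptance window
            cand = np.arange(j_lo, j_hi)
            best = cand[np.argmin(np.abs(t[cand] - t_last - target_interval))]
        elif j_lo < n:   # data sparser than the window: pass through
            best = j_lo
        else:
            break
        keep.append(int(best))
        i = best
        if i >= n - 1:
            break
    return track.iloc[keep].reset_index(drop=True)


def window_colony_period(
    track: pd.DataFrame,
    period: tuple | None = None,
    colony_xy: tuple[float, float] | None = None,
    buffer_m: float = 100.0,
    max_trip_days: float = 10.0,
    exclude_windows: list[tuple] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Restrict a track to its colony-associated period and drop outliers.

    `period` is a half-open UTC window [start, end); when None it defaults
    to the track's own span (the bird is assumed colony-associated for the
    data supplied, overridable per bird via configuration). Excursions that
    stay beyond `buffer_m` of the colony for more than `max_trip_days` are
    outlier trips (pre/post-breeding movements) and removed wholesale, as
    are any explicitly configured `exclude_windows`.
    """
    info = {"n_in": len(track), "n_outside_period": 0, "n_outlier_trip": 0, "n_excluded": 0}
    if len(track) == 0:
        return track, info
    ts = pd.to_datetime(track["timestamp"])
    keep = np.ones(len(track), dtype=bool)
    if period is not None:
        start, end = (pd.Timestamp(period[0]), pd.Timestamp(period[1]))
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
        if end.tzinfo is None:
            end = end.tz_localize("UTC")
        if end <= start:
            raise ValueError("period end must be after start")
        inside = (ts >= start) & (ts < end)
        info["n_outside_period"] = int((~inside).sum())
        keep &= inside.to_numpy()
    if colony_xy is not None:
        away = (
            np.hypot(track["x"].to_numpy(float) - colony_xy[0],
                     track["y"].to_numpy(float) - colony_xy[1])
            > buffer_m
        )
        # maximal away-runs lasting longer than max_trip_days are outliers
        t = ts.astype("int64").to_numpy() / 1e9
        i = 0
        n = len(track)
        while i < n:
            if away[i]:
                j = i
                while j + 1 < n and away[j + 1]:
                    j += 1
                if (t[j] - t[i]) > max_trip_days * 86400.0:
                    info["n_outlier_trip"] += int(keep[i : j + 1].sum())
                    keep[i : j + 1] = False
                i = j + 1
            else:
                i += 1
    for win in exclude_windows or []:
        s, e = pd.Timestamp(win[0]), pd.Timestamp(win[1])
        if s.tzinfo is None:
            s = s.tz_localize("UTC")
        if e.tzinfo is None:
            e = e.tz_localize("UTC")
        hit = ((ts >= s) & (ts < e)).to_numpy() & keep
        info["n_excluded"] += int(hit.sum())
        keep &= ~hit
    return track[keep].reset_index(drop=True), info
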