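"""Synthetic landscapes and GPS tracks with known ground truth.

The generator emulates the data structure of a multi-year gull-tracking
study at an offshore breeding colony: a categorical land-cover raster with
LCM-style integer codes, landfill and harbour site layers, a colony polygon
on the marine side of a coastline, and per-individual GPS fix tables from
devices with heterogeneous sampling intervals. Birds perform central-place
foraging trips with distinct commuting (fast, straight) and area-restricted
search (slow, tortuous) kinematics; trip destinations are drawn with
probability proportional to ``exp(beta_habitat)``, so habitat-selection
coefficients can be recovered downstream. Every fix carries a truth record
(behavioural state, trip membership, planted-corruption flag, habitat).

All coordinates are planar metres; timestamps are UTC. A single integer
seed fixes the full output bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, mapping

from .habitat import CATEGORY_CODES, CODE_CATEGORIES, build_priority_overlay, reclassify_landcover
from .raster import Raster

__all__ = [
    "LandscapeSpec",
    "SimConfig",
    "Landscape",
    "TruthRecord",
    "generate_landscape",
    "simulate_tracks",
    "simulate_rsf_fixes",
    "simulate_ssf_strata",
    "simulate_ssf_track",
    "write_fixes_csv",
    "read_truth_csv",
]

# Raw land-cover codes available per broad category (LCM-style numbering).
RAW_CODES = {
    "agricultural": [3, 4],
    "coastal": [13, 15, 16, 17, 18, 19],
    "urban": [20, 21],
    "other": [1, 2, 5, 6, 7, 8, 9, 10, 11, 12, 14],
}

#: Per-species true log-selection strengths (reference: agricultural = 0).
DEFAULT_SPECIES_COEFFICIENTS = {
    # large generalist with strong anthropogenic-subsidy use
    "LBBGU": {"landfill": 2.0, "coastal": 1.0, "urban": 0.5, "marine": -1.0,
              "other": 0.0, "harbour": 1.0},
    # coastal/harbour forager
    "HERGU": {"landfill": 1.0, "coastal": 1.5, "urban": 1.0, "marine": -0.5,
              "other": -0.5, "harbour": 1.5},
    # marine/coastal specialist avoiding built habitat
    "GBBGU": {"landfill": 0.0, "coastal": 1.5, "urban": -1.0, "marine": 1.0,
              "other": -1.0, "harbour": 0.5},
}


class InvalidSpecError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass
class LandscapeSpec:
    """Geometry and composition of the synthetic study area.

    The coastline is the vertical line ``x = coast_x``: cells west of it are
    marine, cells east of it land. The colony sits on the marine side (a
    rock smaller than one raster cell), so birds cross water to reach land.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 80_000.0, 80_000.0)
    cell_size: float = 500.0
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"agricultural": 0.45, "other": 0.30, "urban": 0.15, "coastal": 0.10}
    )
    n_landfills: int = 3
    n_harbours: int = 3
    colony_xy: tuple[float, float] = (17_000.0, 40_000.0)
    coast_x: float = 20_000.0
    colony_radius: float = 50.0
    smooth_cells: float = 3.0
    site_range_m: float = 25_000.0

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise InvalidSpecError("zero-area extent")
        if self.cell_size <= 0:
            raise InvalidSpecError("cell_size must be > 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise InvalidSpecError("class_mix must sum to 1")
        unknown = set(self.class_mix) - set(RAW_CODES)
        if unknown:
            raise InvalidSpecError(f"unknown land classes in mix: {sorted(unknown)}")
        if self.colony_xy[0] >= self.coast_x:
            raise InvalidSpecError("colony must lie on the marine side of the coastline")


@dataclass
class Landscape:
    """Bundle returned by :func:`generate_landscape`."""

    landcover: Raster            # raw integer land-cover codes (0 = unclassified sea)
    habitat: Raster              # seven-level habitat overlay (analysis-ready)
    sites: dict[str, np.ndarray]  # {"landfill": (n,2), "harbour": (n,2)} planar points
    colony: Point                # colony polygon (buffered point)
    marine_mask: Raster          # 1 = marine, 0 = land
    spec: LandscapeSpec = None

    @property
    def colony_xy(self) -> tuple[float, float]:
        c = self.colony.centroid
        return (c.x, c.y)

    def write(self, outdir) -> None:
        """Write landscape layers as text rasters and GeoJSON."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.landcover.write_ascii(outdir / "landcover.asc")
        self.habitat.write_ascii(outdir / "habitat.asc")
        self.marine_mask.write_ascii(outdir / "marine_mask.asc")
        feats = []
        for kind, pts in self.sites.items():
            for x, y in np.atleast_2d(pts):
                feats.append(
                    {"type": "Feature", "properties": {"kind": kind},
                     "geometry": mapping(Point(x, y))}
                )
        feats.append(
            {"type": "Feature", "properties": {"kind": "colony"},
             "geometry": mapping(self.colony)}
        )
        with open(outdir / "sites.geojson", "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class SimConfig:
    """Study conditions for the track simulator.

    Defaults mirror the tracked 2021 samples of the three study species
    (10 great black-backed, 12 herring, 31 lesser black-backed gulls) with
    device sampling intervals spanning the deployed device classes, and
    kinematic regimes whose commuting and foraging speed ranges are disjoint
    so behavioural recovery is well-posed.
    """

    species_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SPECIES_COEFFICIENTS.items()}
    )
    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"GBBGU": 10, "HERGU": 12, "LBBGU": 31}
    )
    sampling_interval_s: dict[str, float] = field(
        default_factory=lambda: {"GBBGU": 300.0, "HERGU": 120.0, "LBBGU": 60.0}
    )
    p_bad_fix: float = 0.02
    n_bad_fixes_per_track: int | None = None  # overrides p_bad_fix when set
    commuting_speed_range: tuple[float, float] = (8.0, 14.0)
    foraging_speed_range: tuple[float, float] = (0.1, 3.0)
    kappa_commute: float = 50.0
    kappa_search: float = 0.5
    trip_rate_per_day: float = 3.0
    trip_type_mix: dict[str, float] = field(
        default_factory=lambda: {"terrestrial": 0.85, "marine": 0.065, "mixed": 0.085}
    )
    max_range_m: float = 25_000.0
    search_duration_h: tuple[float, float] = (0.5, 2.0)
    search_radius_m: float = 600.0
    n_days: float = 4.0
    fan_azimuths: tuple[float, float] = (45.0, 135.0)
    sim_step_s: float = 10.0
    start: str = "2021-06-01T00:00:00Z"
    seed: int = 0

    def validate(self) -> None:
        if min(self.commuting_speed_range) < 0 or min(self.foraging_speed_range) < 0:
            raise InvalidSpecError("speeds must be >= 0")
        if max(self.foraging_speed_range) >= min(self.commuting_speed_range):
            raise InvalidSpecError(
                "foraging and commuting speed ranges must be disjoint "
                "(foraging max below commuting min)"
            )
        if not (0 <= self.p_bad_fix < 1):
            raise InvalidSpecError("p_bad_fix must be in [0, 1)")
        if self.n_days <= 0 or self.sim_step_s <= 0:
            raise InvalidSpecError("n_days and sim_step_s must be positive")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the fix tables.

    fixes
        One row per emitted fix (same order as the fix table): true state in
        {commute, search, rest}, trip id (-1 at colony), planted bad-fix
        flag with its corruption kind, and true habitat at the fix.
    trips
        One row per trip: bird, trip id, scheduled start/end, type,
        destination, true foraging range (km).
    habitat_counts
        Realised per-individual habitat-use counts over non-corrupted
        search-state fixes.
    beta
        The per-species true selection coefficients used.
    """

    fixes: pd.DataFrame
    trips: pd.DataFrame
    habitat_counts: pd.DataFrame
    beta: dict[str, dict[str, float]]


# --------------------------------------------------------------------------
# landscape generation
# --------------------------------------------------------------------------

def generate_landscape(spec: LandscapeSpec, seed: int) -> Landscape:
    """Build a seeded landscape with autocorrelated land-cover patches.

    A smoothed Gaussian random field is thresholded at the class-mix
    quantiles to carve the land side into contiguous patches of the four
    terrestrial categories; each patch cell receives a raw LCM-style code of
    its category. Harbours sit on coast-adjacent land cells and landfills on
    interior land cells, both within foraging reach of the colony.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = spec.extent
    ncol = int(round((xmax - xmin) / spec.cell_size))
    nrow = int(round((ymax - ymin) / spec.cell_size))
    if ncol < 2 or nrow < 2:
        raise InvalidSpecError("extent too small for the requested cell size")

    field_ = ndimage.gaussian_filter(rng.standard_normal((nrow, ncol)), spec.smooth_cells)
    xs = xmin + (np.arange(ncol) + 0.5) * spec.cell_size
    ys = ymax - (np.arange(nrow) + 0.5) * spec.cell_size
    X, Y = np.meshgrid(xs, ys)
    land = X >= spec.coast_x

    codes = np.zeros((nrow, ncol), dtype=int)  # 0 = unclassified (marine)
    classes = [c for c in ("agricultural", "other", "urban", "coastal") if spec.class_mix.get(c, 0) > 0]
    probs = np.array([spec.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    land_vals = field_[land]
    edges = np.quantile(land_vals, np.cumsum(probs)[:-1]) if len(classes) > 1 else []
    assign = np.digitize(field_, edges) if len(classes) > 1 else np.zeros_like(codes)
    for k, cname in enumerate(classes):
        cells = land & (assign == k)
        codes[cells] = rng.choice(RAW_CODES[cname], size=int(cells.sum()))

    landcover = Raster(codes, x0=xmin, y0=ymax, cell=spec.cell_size)
    marine = Raster((~land).astype(int), x0=xmin, y0=ymax, cell=spec.cell_size)

    cx, cy = spec.colony_xy
    dist2 = (X - cx) ** 2 + (Y - cy) ** 2
    in_range = dist2 <= spec.site_range_m**2

    # harbours: land cells with a marine 4-neighbour (the coastal strip)
    sea = ~land
    coast_adjacent = land & (
        np.roll(sea, 1, 1) | np.roll(sea, -1, 1) | np.roll(sea, 1, 0) | np.roll(sea, -1, 0)
    )
    harbour_pool = np.argwhere(coast_adjacent & in_range)
    if len(harbour_pool) < spec.n_harbours:
        raise InvalidSpecError("not enough coastal cells for the requested harbours")
    idx = rng.choice(len(harbour_pool), size=spec.n_harbours, replace=False)
    harbours = np.column_stack([X[tuple(harbour_pool[idx].T)], Y[tuple(harbour_pool[idx].T)]])

    interior = land & ~coast_adjacent & in_range & (X >= spec.coast_x + 2 * spec.cell_size)
    lf_pool = np.argwhere(interior)
    if len(lf_pool) < spec.n_landfills:
        raise InvalidSpecError("not enough interior land cells for the requested landfills")
    idx = rng.choice(len(lf_pool), size=spec.n_landfills, replace=False)
    landfills = np.column_stack([X[tuple(lf_pool[idx].T)], Y[tuple(lf_pool[idx].T)]])

    habitat5 = reclassify_landcover(landcover)
    overlay = build_priority_overlay(habitat5, landfills, harbours)
    colony = Point(cx, cy).buffer(spec.colony_radius, quad_segs=16)
    return Landscape(
        landcover=landcover,
        habitat=overlay,
        sites={"landfill": landfills, "harbour": harbours},
        colony=colony,
        marine_mask=marine,
        spec=spec,
    )


# --------------------------------------------------------------------------
# track simulation
# --------------------------------------------------------------------------

def _azimuth_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Bearing in degrees clockwise from north, in [0, 360)."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def _in_fan(az, fan):
    lo, hi = fan
    lo %= 360.0
    hi %= 360.0
    az = np.asarray(az) % 360.0
    if lo <= hi:
        return (az >= lo) & (az <= hi)
    return (az >= lo) | (az <= hi)


def _destination_pools(landscape: Landscape, config: SimConfig):
    """Candidate destination cells per trip type, with habitat codes."""
    hab = landscape.habitat
    X, Y = hab.cell_centres()
    cx, cy = landscape.colony_xy
    dx, dy = X - cx, Y - cy
    dist = np.hypot(dx, dy)
    az = _azimuth_deg(dx, dy)
    land = landscape.marine_mask.values == 0
    reach = (dist <= config.max_range_m) & (dist >= 2_000.0)
    margin = 8.0
    lo, hi = config.fan_azimuths
    inner_fan = _in_fan(az, (lo + margin, hi - margin))
    outer_fan = ~_in_fan(az, (lo - margin, hi + margin))
    pools = {
        "terrestrial": land & reach & inner_fan,
        "mixed": land & reach & outer_fan,
        "marine": ~land & reach,
    }
    out = {}
    for kind, mask in pools.items():
        rows, cols = np.nonzero(mask)
        if len(rows) == 0:
            out[kind] = None
            continue
        out[kind] = {
            "xy": np.column_stack([X[rows, cols], Y[rows, cols]]),
            "code": hab.values[rows, cols],
        }
    return out


def _trip_leg_commute(rng, a, b, speed_range, step_s):
    """Positions along a straight commute from a to b at commuting speed."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = float(np.hypot(*(b - a)))
    speed = rng.uniform(*speed_range)
    n = max(int(np.ceil(d / (speed * step_s))), 1)
    frac = np.arange(1, n + 1) / n
    pos = a[None, :] + frac[:, None] * (b - a)[None, :]
    # small lateral wobble, far below the bad-fix speed threshold
    perp = np.array([-(b - a)[1], (b - a)[0]]) / max(d, 1.0)
    pos += perp[None, :] * rng.normal(0.0, 10.0, size=n)[:, None]
    return pos


def _trip_leg_search(rng, centre, n, speed_range, kappa, radius, step_s):
    """Area-restricted search: slow, tortuous walk tethered to the centre."""
    centre = np.asarray(centre, float)
    pos = np.empty((n, 2))
    cur = centre.copy()
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(n):
        heading += rng.vonmises(0.0, kappa)
        step = rng.uniform(*speed_range) * step_s
        cand = cur + step * np.array([np.sin(heading), np.cos(heading)])
        if np.hypot(*(cand - centre)) > radius:
            heading = np.arctan2(*(centre - cur)) + rng.normal(0, 0.3)
            cand = cur + step * np.array([np.sin(heading), np.cos(heading)])
        cur = cand
        pos[i] = cur
    return pos


def simulate_tracks(config: SimConfig, landscape: Landscape):
    """Simulate central-place foraging tracks for every configured bird.

    Returns ``(fixes, truth)`` where `fixes` is a tidy table with columns
    (bird_id, species, timestamp, x, y, satellites, fix_valid) and `truth`
    a :class:`TruthRecord` aligned row-for-row with `fixes`.
    """
    from shapely import contains_xy

    config.validate()
    rng = np.random.default_rng(config.seed)
    pools = _destination_pools(landscape, config)
    # trip membership in the truth record follows the analysis convention:
    # a fix belongs to a trip only while outside the 100 m-buffered colony
    colony_buffered = landscape.colony.buffer(100.0)
    beta = config.species_coefficients
    cx, cy = landscape.colony_xy
    t0 = pd.Timestamp(config.start)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    horizon = config.n_days * 86400.0
    step = config.sim_step_s

    kinds = list(config.trip_type_mix)
    kind_p = np.array([config.trip_type_mix[k] for k in kinds], float)
    kind_p /= kind_p.sum()

    fix_rows = []
    truth_rows = []
    trip_rows = []

    for species, n_birds in config.n_individuals.items():
        interval = float(config.sampling_interval_s.get(species, 120.0))
        b = beta.get(species, {})
        for bi in range(n_birds):
            bird_id = f"{species}_{bi + 1:02d}"
            # --- continuous-time truth path --------------------------------
            times, xs, ys, states, trip_ids = [], [], [], [], []
            t = 0.0
            trip_no = 0
            # mean at-colony dwell chosen so trips/day matches trip_rate
            trip_mean_h = np.mean(config.search_duration_h) + 2 * config.max_range_m / 2 / 11.0 / 3600
            dwell_mean = max(24.0 / config.trip_rate_per_day - trip_mean_h, 1.0) * 3600.0
            dwell_min = max(4 * interval, 1200.0)
            while t < horizon:
                dwell = max(rng.exponential(dwell_mean), dwell_min)
                n_rest = int(dwell / step)
                if n_rest:
                    tt = t + step * np.arange(1, n_rest + 1)
                    keep = tt < horizon
                    tt = tt[keep]
                    jitter = rng.normal(0, 15.0, size=(len(tt), 2))
                    times.append(tt)
                    xs.append(cx + jitter[:, 0])
                    ys.append(cy + jitter[:, 1])
                    states.append(np.full(len(tt), "rest"))
                    trip_ids.append(np.full(len(tt), -1))
                t += dwell
                if t >= horizon:
                    break
                # ----- one trip
                kind = kinds[rng.choice(len(kinds), p=kind_p)]
                pool = pools[kind]
                if pool is None:
                    raise SimulationError(
                        f"no reachable destination for a {kind} trip of {bird_id}"
                    )
                w = np.exp([b.get(CODE_CATEGORIES[c], 0.0) for c in pool["code"]])
                w = np.asarray(w) / np.sum(w)
                di = rng.choice(len(w), p=w)
                dest = pool["xy"][di] + rng.uniform(
                    -0.4 * landscape.habitat.cell, 0.4 * landscape.habitat.cell, 2
                )
                t_depart = t
                out = _trip_leg_commute(rng, (cx, cy), dest, config.commuting_speed_range, step)
                dur_h = rng.uniform(*config.search_duration_h)
                n_search = max(int(dur_h * 3600 / step), 1)
                search = _trip_leg_search(
                    rng, dest, n_search, config.foraging_speed_range,
                    config.kappa_search, config.search_radius_m, step,
                )
                back = _trip_leg_commute(rng, search[-1], (cx, cy), config.commuting_speed_range, step)
                pos = np.vstack([out, search, back])
                st = np.concatenate([
                    np.full(len(out), "commute"),
                    np.full(len(search), "search"),
                    np.full(len(back), "commute"),
                ])
                tt = t + step * np.arange(1, len(pos) + 1)
                keep = tt < horizon
                times.append(tt[keep])
                xs.append(pos[keep, 0])
                ys.append(pos[keep, 1])
                states.append(st[keep])
                trip_ids.append(np.full(int(keep.sum()), trip_no))
                t_arrive = t + step * len(pos)
                d_true = float(np.max(np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)))
                trip_rows.append({
                    "bird_id": bird_id, "species": species, "trip_id": trip_no,
                    "t_start": t0 + pd.to_timedelta(t_depart, unit="s"),
                    "t_end": t0 + pd.to_timedelta(min(t_arrive, horizon), unit="s"),
                    "type": kind, "dest_x": dest[0], "dest_y": dest[1],
                    "d_max_km": d_true / 1000.0,
                    "complete": bool(t_arrive < horizon),
                })
                trip_no += 1
                t = t_arrive

            times = np.concatenate(times)
            xs = np.concatenate(xs)
            ys = np.concatenate(ys)
            states = np.concatenate(states)
            trip_ids = np.concatenate(trip_ids)

            # --- resample to the device interval ---------------------------
            want = np.arange(0.0, horizon, interval)
            sel = np.searchsorted(times, want, side="left")
            sel = np.unique(sel[sel < len(times)])
            times, xs, ys = times[sel], xs[sel], ys[sel]
            states, trip_ids = states[sel], trip_ids[sel]
            inside_colony = contains_xy(colony_buffered, xs, ys)
            trip_ids = np.where((trip_ids >= 0) & inside_colony, -1, trip_ids)
            n = len(times)
            sats = rng.integers(5, 13, size=n)
            valid = np.ones(n, dtype=bool)
            bad = np.zeros(n, dtype=bool)
            bad_kind = np.array([""] * n, dtype=object)

            # --- plant corrupted fixes -------------------------------------
            if config.n_bad_fixes_per_track is not None:
                n_bad = min(config.n_bad_fixes_per_track, max(n - 2, 0))
            else:
                n_bad = int(round(config.p_bad_fix * n))
            if n_bad > 0:
                cand = rng.permutation(np.arange(1, n))
                chosen: list[int] = []
                for c in cand:
                    if all(abs(c - k) >= 2 for k in chosen):
                        chosen.append(int(c))
                    if len(chosen) == n_bad:
                        break
                for j, c in enumerate(chosen):
                    bad[c] = True
                    mode = j % 5
                    if mode in (0, 1):          # too few satellites
                        sats[c] = rng.integers(0, 4)
                        bad_kind[c] = "satellites"
                    elif mode in (2, 3):        # position spike > 30 m/s
                        dt_prev = times[c] - times[c - 1]
                        shift = 30.0 * dt_prev * 1.5 + 500.0
                        ang = rng.uniform(0, 2 * np.pi)
                        xs[c] += shift * np.sin(ang)
                        ys[c] += shift * np.cos(ang)
                        bad_kind[c] = "speed"
                    else:                        # manufacturer invalid flag
                        valid[c] = False
                        bad_kind[c] = "invalid_flag"

            hab = landscape.habitat.value_at(xs, ys, outside=CATEGORY_CODES["marine"])
            ts = t0 + pd.to_timedelta(times, unit="s")
            fix_rows.append(pd.DataFrame({
                "bird_id": bird_id, "species": species, "timestamp": ts,
                "x": xs, "y": ys, "satellites": sats, "fix_valid": valid,
            }))
            truth_rows.append(pd.DataFrame({
                "bird_id": bird_id, "species": species, "timestamp": ts,
                "state": states, "trip_id": trip_ids, "bad_fix": bad,
                "bad_kind": bad_kind,
                "habitat": [CODE_CATEGORIES[int(c)] for c in hab],
            }))

    fixes = pd.concat(fix_rows, ignore_index=True)
    truth_fixes = pd.concat(truth_rows, ignore_index=True)
    trips = pd.DataFrame(trip_rows)
    # trips too brief to leave an outside-buffer fix at the device interval
    # are unobservable and dropped from the truth table
    if len(trips):
        realised = truth_fixes[truth_fixes.trip_id >= 0].groupby("bird_id")["trip_id"].unique()
        keep = [
            row.trip_id in set(realised.get(row.bird_id, []))
            for row in trips.itertuples()
        ]
        trips = trips[np.asarray(keep, bool)].reset_index(drop=True)
    use = truth_fixes[(truth_fixes.state == "search") & (~truth_fixes.bad_fix)]
    habitat_counts = (
        use.groupby(["bird_id", "habitat"]).size().unstack(fill_value=0)
        if len(use)
        else pd.DataFrame()
    )
    return fixes, TruthRecord(truth_fixes, trips, habitat_counts, beta)


# --------------------------------------------------------------------------
# focused parameter-recovery harnesses
# --------------------------------------------------------------------------

def simulate_rsf_fixes(
    landscape: Landscape,
    beta: dict[str, float],
    n_birds: int,
    n_fixes: int,
    seed: int,
    max_range_m: float | None = None,
    species: str = "SIM",
) -> pd.DataFrame:
    """Independent use fixes for resource-selection recovery experiments.

    Each fix is an i.i.d. draw from the density proportional to
    ``exp(beta_habitat(x))`` over the disc of reachable locations around
    the colony (rejection sampling from a uniform proposal) — the exact
    point process a resource selection function models, with the disc as
    the availability domain.
    """
    rng = np.random.default_rng(seed)
    hab = landscape.habitat
    cx, cy = landscape.colony_xy
    rmax = max_range_m if max_range_m is not None else landscape.spec.site_range_m
    wmax = np.exp(max([0.0] + [v for v in beta.values()]))

    def draw(n):
        out = np.empty((0, 2))
        while len(out) < n:
            m = max(int((n - len(out)) * wmax * 1.3), 64)
            r = rmax * np.sqrt(rng.uniform(size=m))
            th = rng.uniform(0, 2 * np.pi, size=m)
            pts = np.column_stack([cx + r * np.sin(th), cy + r * np.cos(th)])
            codes = hab.value_at(pts[:, 0], pts[:, 1], outside=CATEGORY_CODES["marine"])
            w = np.exp([beta.get(CODE_CATEGORIES[int(c)], 0.0) for c in np.atleast_1d(codes)])
            keep = rng.uniform(size=m) * wmax < np.asarray(w)
            out = np.vstack([out, pts[keep]])
        return out[:n]

    out = []
    t0 = pd.Timestamp("2021-06-01", tz="UTC")
    for bi in range(n_birds):
        pts = draw(n_fixes)
        out.append(pd.DataFrame({
            "bird_id": f"{species}_{bi + 1:02d}", "species": species,
            "timestamp": t0 + pd.to_timedelta(np.arange(n_fixes) * 1800, unit="s"),
            "x": pts[:, 0], "y": pts[:, 1],
        }))
    return pd.concat(out, ignore_index=True)


def simulate_ssf_strata(
    landscape: Landscape,
    beta: dict[str, float],
    n_strata: int,
    seed: int,
    n_available: int = 20,
    start_xy: tuple[float, float] | None = None,
    gamma_shape: float = 2.0,
    gamma_scale: float = 300.0,
    bird_id: str = "SIM_01",
) -> pd.DataFrame:
    """Step-selection strata with a known selection coefficient vector.

    At each step, ``n_available + 1`` candidate end points are proposed from
    a gamma step-length kernel around the current location; one is chosen as
    the observed step with probability proportional to
    ``exp(beta_habitat(end))`` — the exact data-generating process of a
    habitat-only conditional-logistic step-selection model. Returns a tidy
    step table (stratum, used, habitat, x, y).
    """
    rng = np.random.default_rng(seed)
    hab = landscape.habitat
    cur = np.asarray(start_xy if start_xy is not None else landscape.sites["landfill"][0], float)
    rows = []
    for s in range(n_strata):
        k = n_available + 1
        lengths = rng.gamma(gamma_shape, gamma_scale, size=k)
        angles = rng.uniform(0, 2 * np.pi, size=k)
        ends = cur[None, :] + np.column_stack(
            [lengths * np.sin(angles), lengths * np.cos(angles)]
        )
        codes = hab.value_at(ends[:, 0], ends[:, 1], outside=CATEGORY_CODES["marine"])
        w = np.exp([beta.get(CODE_CATEGORIES[int(c)], 0.0) for c in np.atleast_1d(codes)])
        w = np.asarray(w) / np.sum(w)
        obs = rng.choice(k, p=w)
        for j in range(k):
            rows.append({
                "bird_id": bird_id, "stratum": s, "used": int(j == obs),
                "habitat": CODE_CATEGORIES[int(np.atleast_1d(codes)[j])],
                "x": ends[j, 0], "y": ends[j, 1],
            })
        cur = ends[obs]
    return pd.DataFrame(rows)


def simulate_ssf_track(
    landscape: Landscape,
    beta: dict[str, float],
    n_steps: int,
    seed: int,
    start_xy: tuple[float, float] | None = None,
    n_candidates: int = 50,
    gamma_shape: float = 2.0,
    gamma_scale: float = 300.0,
    interval_s: float = 1800.0,
    bird_id: str = "SIM_01",
    species: str = "SIM",
) -> pd.DataFrame:
    """A positional track whose steps follow a habitat-weighted kernel.

    Unlike :func:`simulate_ssf_strata` this returns only the chosen
    positions, for end-to-end tests of step-table construction.
    """
    rng = np.random.default_rng(seed)
    hab = landscape.habitat
    cur = np.asarray(start_xy if start_xy is not None else landscape.sites["landfill"][0], float)
    pos = [cur.copy()]
    for _ in range(n_steps):
        lengths = rng.gamma(gamma_shape, gamma_scale, size=n_candidates)
        angles = rng.uniform(0, 2 * np.pi, size=n_candidates)
        ends = cur[None, :] + np.column_stack(
            [lengths * np.sin(angles), lengths * np.cos(angles)]
        )
        codes = hab.value_at(ends[:, 0], ends[:, 1], outside=CATEGORY_CODES["marine"])
        w = np.exp([beta.get(CODE_CATEGORIES[int(c)], 0.0) for c in np.atleast_1d(codes)])
        w = np.asarray(w) / np.sum(w)
        cur = ends[rng.choice(n_candidates, p=w)]
        pos.append(cur.copy())
    pos = np.asarray(pos)
    t0 = pd.Timestamp("2021-06-01", tz="UTC")
    return pd.DataFrame({
        "bird_id": bird_id, "species": species,
        "timestamp": t0 + pd.to_timedelta(np.arange(len(pos)) * interval_s, unit="s"),
        "x": pos[:, 0], "y": pos[:, 1],
        "satellites": 9, "fix_valid": True,
    })


# --------------------------------------------------------------------------
# plain-text I/O
# --------------------------------------------------------------------------

def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df
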