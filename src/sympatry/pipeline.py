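"""End-to-end orchestration: simulate/load -> preprocess -> trips ->
behaviour -> home ranges -> habitat selection -> niche statistics.

Each stage is a pure function over tidy tables plus the landscape layers,
so stages can be run (and tested) independently; :func:`run_pipeline`
chains them, keeps an exact row-count ledger across every filter, and
writes all stage outputs, a machine-readable manifest and a summary report
under a run directory. A single seed drives every stochastic stage.
"""

from __future__ import annotations

import json
import logging
import pathlib
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from . import behaviour as bh
from . import homerange as hr
from . import niche_stats as ns
from . import preprocess as pp
from . import selection as sel
from . import synthetic as syn
from . import trips as tr
from .habitat import extract_habitat

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 1
    # simulation (used when fixes_csv is None)
    landscape: syn.LandscapeSpec = field(default_factory=syn.LandscapeSpec)
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    fixes_csv: str | None = None
    landscape_dir: str | None = None
    # stage parameters
    max_speed_ms: float = 30.0
    min_satellites: int = 4
    thin_interval_min: float = 30.0
    thin_tolerance: float = 0.4
    max_trip_days: float = 10.0
    colony_buffer_m: float = 100.0
    max_gap_h: float = 5.0
    fan_azimuths: tuple[float, float] = (45.0, 135.0)
    embc_min_group: int = 50
    n_avail: int = 20
    min_rsf_fixes: int = 100
    min_issf_steps: int = 30
    ps_replicates: int = 999
    ud_method: str = "binned"
    ud_max_points: int = 4000

    def validate(self) -> None:
        if self.fixes_csv is not None and not pathlib.Path(self.fixes_csv).exists():
            raise FileNotFoundError(self.fixes_csv)
        if self.landscape_dir is not None:
            d = pathlib.Path(self.landscape_dir)
            for f in ("habitat.asc", "marine_mask.asc", "sites.geojson"):
                if not (d / f).exists():
                    raise FileNotFoundError(d / f)


def _load_landscape(dirpath) -> syn.Landscape:
    from shapely.geometry import shape

    d = pathlib.Path(dirpath)
    habitat = syn.Raster.read_ascii(d / "habitat.asc")
    marine = syn.Raster.read_ascii(d / "marine_mask.asc")
    landcover = (
        syn.Raster.read_ascii(d / "landcover.asc")
        if (d / "landcover.asc").exists()
        else habitat
    )
    sites: dict[str, list] = {"landfill": [], "harbour": []}
    colony = None
    with open(d / "sites.geojson") as fh:
        fc = json.load(fh)
    for feat in fc["features"]:
        kind = feat["properties"].get("kind")
        geom = shape(feat["geometry"])
        if kind == "colony":
            colony = geom
        elif kind in sites:
            sites[kind].append([geom.x, geom.y])
    return syn.Landscape(
        landcover=landcover,
        habitat=habitat,
        sites={k: np.asarray(v) for k, v in sites.items()},
        marine_mask=marine,
        colony=colony,
        spec=None,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report bundle (also written to disk)."""
    config.validate()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sympatry_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "stages": {},
    }
    t_start = time.time()

    # ---------------------------------------------------------------- data
    truth = None
    if config.fixes_csv is None:
        config.sim.seed = config.seed
        landscape = syn.generate_landscape(config.landscape, seed=config.seed)
        fixes, truth = syn.simulate_tracks(config.sim, landscape)
        landscape.write(outdir / "landscape")
        syn.write_fixes_csv(fixes, outdir / "fixes_raw.csv")
        tmp = truth.fixes.copy()
        tmp["timestamp"] = tmp["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        tmp.to_csv(outdir / "truth_fixes.csv", index=False)
        truth.trips.to_csv(outdir / "truth_trips.csv", index=False)
    else:
        landscape = _load_landscape(config.landscape_dir)
        tracks_in = pp.read_fix_table(config.fixes_csv)
        fixes = pd.concat(tracks_in.values(), ignore_index=True)
    colony_xy = landscape.colony_xy
    manifest["stages"]["input"] = {"n_fixes": int(len(fixes)), "elapsed_s": time.time() - t_start}

    # ---------------------------------------------------------- preprocess
    t0 = time.time()
    ledger_rows = []
    clean_tracks: dict[str, pd.DataFrame] = {}
    for bird, track in fixes.groupby("bird_id", sort=True):
        track = track.sort_values("timestamp").reset_index(drop=True)
        n_raw = len(track)
        cleaned, rep = pp.clean_fixes(
            track, max_speed=config.max_speed_ms, min_satellites=config.min_satellites
        )
        windowed, winfo = pp.window_colony_period(
            cleaned, colony_xy=colony_xy,
            buffer_m=config.colony_buffer_m, max_trip_days=config.max_trip_days,
        )
        thinned = pp.thin_track(
            windowed, target_interval=config.thin_interval_min * 60.0,
            tolerance=config.thin_tolerance,
        )
        clean_tracks[str(bird)] = thinned
        ledger_rows.append({
            "bird_id": bird, "n_raw": n_raw,
            "removed_satellites": rep.n_satellites, "removed_speed": rep.n_speed,
            "removed_invalid": rep.n_invalid,
            "removed_window": winfo["n_outside_period"] + winfo["n_outlier_trip"]
            + winfo["n_excluded"],
            "removed_thinning": len(windowed) - len(thinned),
            "n_retained": len(thinned),
        })
    ledger = pd.DataFrame(ledger_rows)
    ledger.to_csv(outdir / "preprocess_ledger.csv", index=False)
    manifest["stages"]["preprocess"] = {
        "n_retained": int(ledger["n_retained"].sum()), "elapsed_s": time.time() - t0,
    }

    # --------------------------------------------------------------- trips
    t0 = time.time()
    fan = tr.RhumbFan(colony_xy, *config.fan_azimuths)
    all_trips: list[tr.Trip] = []
    fix_frames = []
    for bird, track in clean_tracks.items():
        trips_b, inside = tr.segment_trips(
            track, landscape.colony, buffer_m=config.colony_buffer_m,
            max_gap_h=config.max_gap_h,
        )
        track = track.copy()
        track["at_colony"] = inside
        track["trip_id"] = -1
        for t_ in trips_b:
            t_.type = tr.classify_trip_type(t_, landscape.marine_mask, fan)
        # map trip membership back onto the track rows
        pos = 0
        i = 0
        n = len(track)
        ti = 0
        while i < n:
            if not inside[i]:
                j = i
                while j + 1 < n and not inside[j + 1]:
                    j += 1
                track.loc[i:j, "trip_id"] = trips_b[ti].trip_id
                ti += 1
                i = j + 1
            else:
                i += 1
        fix_frames.append(track)
        all_trips.extend(trips_b)
    fixes_trips = pd.concat(fix_frames, ignore_index=True)
    sp_of = fixes_trips.groupby("bird_id")["species"].first() if "species" in fixes_trips else None
    trip_table = pd.concat(
        [
            tr.trips_table(
                [t_ for t_ in all_trips if t_.bird_id == b],
                colony_xy,
                species=(sp_of.get(b) if sp_of is not None else None),
            )
            for b in sorted({t_.bird_id for t_ in all_trips})
        ],
        ignore_index=True,
    ) if all_trips else pd.DataFrame()
    trip_table.to_csv(outdir / "trips.csv", index=False)
    type_pct = (
        trip_table["type"].value_counts(normalize=True).mul(100).round(1).to_dict()
        if len(trip_table)
        else {}
    )
    manifest["stages"]["trips"] = {
        "n_trips": int(len(trip_table)),
        "n_complete": int(trip_table["complete"].sum()) if len(trip_table) else 0,
        "trip_type_pct": type_pct, "elapsed_s": time.time() - t0,
    }

    # ----------------------------------------------------------- behaviour
    t0 = time.time()
    kin_by_group: dict = {}
    trip_kin: dict = {}
    for t_ in all_trips:
        kin = bh.compute_kinematics(t_.fixes)
        trip_kin[(t_.bird_id, t_.trip_id)] = kin
        if len(kin) == 0:
            continue
        sp = t_.fixes["species"].iloc[0] if "species" in t_.fixes else ""
        kin_by_group.setdefault((sp, t_.type), []).append(kin)
    kin_by_group = {k: pd.concat(v, ignore_index=True) for k, v in kin_by_group.items()}
    models = bh.fit_embc_groups(kin_by_group, min_group_size=config.embc_min_group, seed=config.seed)
    with open(outdir / "embc_models.json", "w") as fh:
        json.dump({f"{k[0]}|{k[1]}": m.summary() for k, m in models.items()}, fh, indent=1)

    state = np.array([""] * len(fixes_trips), dtype=object)
    state[fixes_trips["at_colony"].to_numpy(bool)] = "at_colony"
    for t_ in all_trips:
        sp = t_.fixes["species"].iloc[0] if "species" in t_.fixes else ""
        model = models.get((sp, t_.type))
        if model is None:
            continue
        labels, _ = bh.annotate_and_drop_commuting(t_.fixes, model, kin=trip_kin[(t_.bird_id, t_.trip_id)])
        sel_rows = (
            (fixes_trips["bird_id"] == t_.bird_id)
            & (fixes_trips["trip_id"] == t_.trip_id)
        ).to_numpy()
        state[sel_rows] = labels
    fixes_trips["state"] = state
    out_csv = fixes_trips.copy()
    out_csv["timestamp"] = pd.to_datetime(out_csv["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out_csv.to_csv(outdir / "fixes_annotated.csv", index=False)
    analysed = fixes_trips[
        (~fixes_trips["at_colony"]) & (~fixes_trips["state"].isin(["HL", ""]))
    ].copy()
    n_colony = int(fixes_trips["at_colony"].sum())
    n_commute = int((fixes_trips["state"] == "HL").sum())
    manifest["stages"]["behaviour"] = {
        "n_at_colony": n_colony, "n_commuting_removed": n_commute,
        "n_unmodelled": int(((state == "") & (~fixes_trips["at_colony"])).sum()),
        "n_analysed": int(len(analysed)), "elapsed_s": time.time() - t0,
    }

    # ------------------------------------------------------------ habitat
    analysed["habitat"] = extract_habitat(
        landscape.habitat, analysed["x"].to_numpy(float), analysed["y"].to_numpy(float)
    )
    analysed_csv = analysed.copy()
    analysed_csv["timestamp"] = pd.to_datetime(analysed_csv["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    analysed_csv.to_csv(outdir / "fixes_analysed.csv", index=False)

    # ----------------------------------------------------------- homerange
    t0 = time.time()
    rng = np.random.default_rng(config.seed + 1)
    ud_by_species = {}
    hmin_by_species = {}
    for sp, sub in analysed.groupby("species", sort=True):
        pts = sub[["x", "y"]].to_numpy(float)
        if len(pts) < 5:
            continue
        if len(pts) > config.ud_max_points:
            pts = pts[rng.choice(len(pts), config.ud_max_points, replace=False)]
        res = hr.min_stable_bandwidth(pts, method=config.ud_method)
        grid = hr.make_grid(pts, res["h_ref"])
        ud_by_species[sp] = hr.estimate_ud(pts, res["h_min"], grid, method=config.ud_method)
        hmin_by_species[sp] = res
    ba_rows = []
    sps = sorted(ud_by_species)
    for i, a in enumerate(sps):
        for b in sps[i + 1 :]:
            ba_rows.append({
                "species_a": a, "species_b": b,
                "ba": hr.bhattacharyya_affinity(ud_by_species[a], ud_by_species[b]),
            })
    ba_table = pd.DataFrame(ba_rows)
    ba_table.to_csv(outdir / "ba_matrix.csv", index=False)
    manifest["stages"]["homerange"] = {
        "h": {sp: {"h_ref": r["h_ref"], "h_min": r["h_min"]} for sp, r in hmin_by_species.items()},
        "elapsed_s": time.time() - t0,
    }

    # ----------------------------------------------------------- selection
    t0 = time.time()
    rsf_fit = rsf_metrics = None
    contrasts = None
    try:
        design = sel.build_rsf_design(
            analysed, landscape.habitat, n_avail=config.n_avail,
            seed=config.seed + 2, min_fixes=config.min_rsf_fixes,
        )
        multi_species = design["species"].nunique() > 1
        rsf_fit = sel.fit_rsf(design, group_col="species" if multi_species else None)
        rsf_metrics = sel.fit_metrics(rsf_fit, design)
        contrasts = sel.marginal_means_contrasts(rsf_fit)
        rsf_fit.params.to_csv(outdir / "rsf_coefficients.csv", header=["estimate"])
        contrasts["means"].to_csv(outdir / "rsf_marginal_means.csv", index=False)
    except ValueError as e:
        log.warning("RSF skipped: %s", e)

    issf_rows = []
    for bird, sub in analysed.groupby("bird_id", sort=True):
        table = sel.build_issf_design(
            sub, landscape.habitat, n_steps=config.n_avail,
            seed=config.seed + 3, min_steps=config.min_issf_steps,
        )
        if len(table) == 0:
            continue
        fit = sel.fit_issf(table)
        for name, val in fit["params"].items():
            issf_rows.append({
                "bird_id": bird, "term": name, "estimate": val,
                "se": fit["se"][name],
                "lo": fit["conf_int"].loc[name, "lo"], "hi": fit["conf_int"].loc[name, "hi"],
                "converged": fit["converged"],
            })
    issf_table = pd.DataFrame(issf_rows)
    issf_table.to_csv(outdir / "issf_coefficients.csv", index=False)
    manifest["stages"]["selection"] = {
        "rsf_metrics": rsf_metrics, "n_issf_birds": int(issf_table["bird_id"].nunique()) if len(issf_table) else 0,
        "elapsed_s": time.time() - t0,
    }

    # ---------------------------------------------------------- niche stats
    t0 = time.time()
    psi_by_species = {}
    profiles = {}
    ps_results = {}
    for k, (sp, sub) in enumerate(analysed.groupby("species", sort=True)):
        if sub["bird_id"].nunique() < 2:
            continue
        prof = ns.habitat_use_profile(sub)
        profiles[sp] = prof
        ps = ns.proportional_similarity(prof, n_replicates=config.ps_replicates,
                                        seed=config.seed + 10 + k)
        ps_results[sp] = {"mean_ps": ps["mean_ps"], "p_value": ps["p_value"]}
        psi_by_species[sp] = ps["psi"].to_numpy()
    pianka_rows = []
    cats = sorted({c for p in profiles.values() for c in p.categories})
    for i, a in enumerate(sorted(profiles)):
        for b in sorted(profiles)[i + 1 :]:
            pa = profiles[a].q.reindex(cats, fill_value=0.0).to_numpy()
            pb = profiles[b].q.reindex(cats, fill_value=0.0).to_numpy()
            o, band = ns.pianka_overlap(pa, pb)
            pianka_rows.append({"species_a": a, "species_b": b, "pianka": o, "band": band})
    pianka_table = pd.DataFrame(pianka_rows)
    pianka_table.to_csv(outdir / "pianka.csv", index=False)
    kw = (
        ns.compare_specialization(psi_by_species)
        if len(psi_by_species) >= 2 and all(len(v) >= 2 for v in psi_by_species.values())
        else None
    )
    fr = None
    if len(trip_table) and trip_table["species"].nunique() >= 2:
        fr = ns.foraging_range_model(trip_table)
        fr["contrasts"].to_csv(outdir / "foraging_range_contrasts.csv", index=False)
    manifest["stages"]["niche_stats"] = {
        "ps": ps_results, "kruskal_wallis": kw, "elapsed_s": time.time() - t0,
    }

    # ------------------------------------------------------------- ledger
    n_removed = int(
        ledger[["removed_satellites", "removed_speed", "removed_invalid",
                "removed_window", "removed_thinning"]].to_numpy().sum()
    )
    balance = {
        "fixes_in": int(len(fixes)),
        "removed_preprocess": n_removed,
        "at_colony": n_colony,
        "commuting_removed": n_commute,
        "unmodelled": manifest["stages"]["behaviour"]["n_unmodelled"],
        "analysed": int(len(analysed)),
    }
    balance["sum"] = (
        balance["removed_preprocess"] + balance["at_colony"]
        + balance["commuting_removed"] + balance["unmodelled"] + balance["analysed"]
    )
    balance["balanced"] = balance["sum"] == balance["fixes_in"]
    manifest["row_ledger"] = balance
    manifest["elapsed_s"] = time.time() - t_start

    report = {
        "trip_type_pct": type_pct,
        "foraging_range_contrasts": fr["contrasts"].to_dict("records") if fr else None,
        "ba": ba_table.to_dict("records"),
        "rsf": {
            "coefficients": rsf_fit.params.to_dict() if rsf_fit else None,
            "metrics": rsf_metrics,
        },
        "pianka": pianka_table.to_dict("records"),
        "ps": ps_results,
        "kruskal_wallis": kw,
        "row_ledger": balance,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    report["manifest"] = manifest
    report["_objects"] = {
        "truth": truth, "trip_table": trip_table, "analysed": analysed,
        "rsf_fit": rsf_fit, "profiles": profiles, "ud_by_species": ud_by_species,
        "contrasts": contrasts, "issf": issf_table, "ledger": ledger,
    }
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Timestamp,)):
        return obj.isoformat()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)
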