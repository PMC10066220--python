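"""End-to-end two-season pipeline and the season-contrast report.

Runs simulate (or load) → trips → dives → acoustics → environment/breeding →
PERMANOVA, and assembles one row per endpoint: season means, pseudo-F with
its degrees of freedom, permutation p, and the direction of the "poor"
season relative to the "good" one (``higher`` / ``lower`` / ``ns``).

The expected direction map encodes the study's contrast structure for a
season of low krill availability: longer trips, fewer complete dives,
deeper maximum dives, higher capture effort, lower breeding success, lower
and deeper krill, weaker aggregation, lower CHL and winter sea ice, stronger
wind; mean dive duration, mean bottom depth and PAR are expected not to
differ.
"""
from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acoustics, dives, enviro, permstats, synthetic, trips
from .synthetic import DEFAULT_COLONY, GOOD_SEASON, POOR_SEASON, SeasonScenario

log = logging.getLogger(__name__)

#: endpoint -> expected direction of the poor season relative to the good one
EXPECTED_DIRECTIONS = {
    "trip_duration_h": "higher",
    "cumulative_distance_km": "higher",
    "freq_complete_dives": "lower",
    "mean_dive_duration_min": "ns",
    "cumulative_dive_duration_min": "higher",
    "mean_bottom_depth_m": "ns",
    "max_bottom_depth_m": "higher",
    "capture_effort": "higher",
    "breeding_success": "lower",
    "nasc": "lower",
    "swarm_depth_m": "higher",
    "aggregation_index": "lower",
    "chl": "lower",
    "par": "ns",
    "wsic": "lower",
    "sws": "higher",
}

ENDPOINTS = list(EXPECTED_DIRECTIONS)


@dataclass
class PipelineConfig:
    good: SeasonScenario = GOOD_SEASON
    poor: SeasonScenario = POOR_SEASON
    colony: tuple = DEFAULT_COLONY
    transect_length_nmi: float = 270.0
    n_perm: int = 999
    seed: int = 0
    alpha: float = 0.05
    simulate: bool = True
    input_dirs: tuple | None = None       # (good_dir, poor_dir) when simulate=False
    out_dir: str | None = None
    fix_interval_s: float = 300.0
    speed_vmax: float = 10.0
    colony_buffer_m: float = 250.0
    min_trip_duration_h: float = 1.0
    dive_threshold_m: float = 3.0
    bottom_fraction: float = 0.8
    wiggle_amplitude_m: float = 1.0
    min_bottom_s: float = 5.0
    radius_km: float = 75.0
    corridor_width_km: float = 10.0


def default_config(seed=0, **kwargs):
    """Default two-scenario config with scenario seeds derived from ``seed``."""
    good = dataclasses.replace(GOOD_SEASON, seed=seed)
    poor = dataclasses.replace(POOR_SEASON, seed=seed + 10007)
    return PipelineConfig(good=good, poor=poor, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_season_dir(path, season_name):
    """Load one season's input CSVs (as written by ``write_bundle``)."""
    gps_files = sorted(glob.glob(os.path.join(path, "gps_*.csv")))
    tdr_files = sorted(glob.glob(os.path.join(path, "tdr_*.csv")))
    if not gps_files:
        raise FileNotFoundError(f"no gps_*.csv tables in {path!r}")
    if not tdr_files:
        raise FileNotFoundError(f"no tdr_*.csv tables in {path!r}")
    gps = {}
    for f in gps_files:
        bird = os.path.basename(f)[4:-4]
        df = pd.read_csv(f, parse_dates=["time"])
        gps[bird] = df
    tdr = {}
    for f in tdr_files:
        bird = os.path.basename(f)[4:-4]
        tdr[bird] = pd.read_csv(f, parse_dates=["time"])
    ac_path = os.path.join(path, "acoustic_samples.csv")
    if not os.path.exists(ac_path):
        raise FileNotFoundError(f"missing acoustic_samples.csv in {path!r}")
    acoustic = pd.read_csv(ac_path)
    env = {}
    for f in sorted(glob.glob(os.path.join(path, "env_*.csv"))):
        stem = os.path.basename(f)[4:-4]          # e.g. CHL_2019-11
        var, month = stem.split("_", 1)
        env[(var, month)] = pd.read_csv(f)
    br_path = os.path.join(path, "breeding.csv")
    if not os.path.exists(br_path):
        raise FileNotFoundError(f"missing breeding.csv in {path!r}")
    breeding = pd.read_csv(br_path)
    scenario = SeasonScenario(name=season_name)
    return synthetic.SyntheticBundle(scenario=scenario, gps_tables=gps,
                                     tdr_tables=tdr, acoustic_samples=acoustic,
                                     env_grids=env, breeding=breeding)


# ---------------------------------------------------------------------------
# Per-season stages
# ---------------------------------------------------------------------------

def _season_trips(bundle, cfg):
    all_trips = []
    for bird, gps in bundle.gps_tables.items():
        all_trips.extend(trips.process_gps_table(
            gps, cfg.colony, cfg.fix_interval_s, cfg.speed_vmax,
            cfg.colony_buffer_m, cfg.min_trip_duration_h, bird_id=bird))
    table = trips.trips_table(all_trips)
    table["season"] = bundle.scenario.name
    return table


def _season_dives(bundle, trips_df, cfg):
    """Dive analysis per bird, with dives assigned to trips by start time."""
    per_dive = []
    for bird, tdr in bundle.tdr_tables.items():
        depth = tdr["depth_m"].to_numpy()
        t0 = tdr["time"].iloc[0]
        corrected = dives.zero_offset_correct(depth)
        df = dives.process_depth_series(
            corrected, cfg.dive_threshold_m, cfg.bottom_fraction,
            cfg.wiggle_amplitude_m, cfg.min_bottom_s)
        if len(df) == 0:
            continue
        df["bird_id"] = bird
        df["start_time"] = t0 + pd.to_timedelta(df["start_idx"], unit="s")
        per_dive.append(df)
    if not per_dive:
        return pd.DataFrame(), pd.DataFrame()
    dive_df = pd.concat(per_dive, ignore_index=True)

    dive_df["trip_id"] = None
    for _, tr in trips_df.iterrows():
        m = ((dive_df["bird_id"] == tr["bird_id"])
             & (dive_df["start_time"] >= tr["start"])
             & (dive_df["start_time"] <= tr["end"]))
        dive_df.loc[m, "trip_id"] = tr["trip_id"]
    assigned = dive_df.dropna(subset=["trip_id"])

    metrics = [dives.trip_dive_metrics(sub, trip_id=tid)
               for tid, sub in assigned.groupby("trip_id")]
    metrics_df = pd.DataFrame(metrics)
    merged = trips_df.merge(metrics_df, on="trip_id", how="left")
    return dive_df, merged


def _season_acoustics(bundle, cfg):
    grid = acoustics.echo_integrate(bundle.acoustic_samples,
                                    transect_length_nmi=cfg.transect_length_nmi)
    nasc_by_bin = grid.groupby("along_bin", as_index=False)["nasc"].sum()
    swarm = acoustics.swarm_depth_selection(grid) if (grid["nasc"] > 0).any() else grid.iloc[0:0]
    profile = acoustics.vertical_profile(grid)
    agg_df, _ = acoustics.aggregation_by_depth(
        grid, corridor_width_km=cfg.corridor_width_km)
    return {"grid": grid, "nasc_by_bin": nasc_by_bin, "swarm": swarm,
            "profile": profile, "aggregation": agg_df}


def _window_months(env_grids, var):
    """Month labels present for a variable, restricted to its seasonal window."""
    window = enviro.SEASON_WINDOWS[var]
    want = {11, 12, 1} if window == "summer" else {6, 7, 8, 9}
    return sorted(m for (v, m) in env_grids if v == var
                  and int(m.split("-")[1]) in want)


def _season_env(bundle, cfg):
    out = {}
    for var in ("CHL", "PAR", "SWS", "SIC"):
        months = _window_months(bundle.env_grids, var)
        if not months:
            continue
        month_grids = {m: bundle.env_grids[(var, m)] for m in months}
        mean = enviro.seasonal_means(month_grids, months)
        out[var] = enviro.extract_radius(mean, cfg.colony, cfg.radius_km)
    return out


# ---------------------------------------------------------------------------
# Contrast assembly
# ---------------------------------------------------------------------------

def _contrast(values_good, values_poor, cfg, seed_offset, source):
    vg = np.asarray(values_good, dtype=float)
    vp = np.asarray(values_poor, dtype=float)
    vg = vg[np.isfinite(vg)]
    vp = vp[np.isfinite(vp)]
    row = {"mean_good": float(vg.mean()) if vg.size else np.nan,
           "mean_poor": float(vp.mean()) if vp.size else np.nan,
           "n_good": int(vg.size), "n_poor": int(vp.size), "source": source}
    if vg.size < 2 or vp.size < 2 or np.concatenate([vg, vp]).std(ddof=1) == 0:
        row.update(pseudo_F=np.nan, df1=np.nan, df2=np.nan, p=np.nan,
                   direction="skipped")
        return row
    x = np.concatenate([vg, vp])
    labels = np.r_[np.zeros(vg.size), np.ones(vp.size)]
    z = (x - x.mean()) / x.std(ddof=1)
    r = permstats.permanova_one_way(z[:, None], labels, cfg.n_perm,
                                    cfg.seed + seed_offset)
    if r.p_value < cfg.alpha:
        direction = "higher" if row["mean_poor"] > row["mean_good"] else "lower"
    else:
        direction = "ns"
    row.update(pseudo_F=r.pseudo_f, df1=r.df_between, df2=r.df_within,
               p=r.p_value, direction=direction)
    return row


def run_pipeline(config=None):
    """Execute every stage and return a dict of results keyed by stage.

    The returned dict holds the contrast ``report`` (one row per endpoint)
    and all intermediate tables; when ``config.out_dir`` is set everything is
    also written to CSV along with a markdown report, the echoed config and
    a run log.
    """
    cfg = config or default_config()
    timings = []

    def _stage(name, fn, *args):
        t0 = time.perf_counter()
        out = fn(*args)
        dt = time.perf_counter() - t0
        timings.append((name, dt))
        log.info("stage %-12s %.1fs", name, dt)
        return out

    if cfg.simulate:
        bundles = _stage("simulate", synthetic.simulate_bundle, cfg.good,
                         cfg.poor, cfg.colony, cfg.transect_length_nmi)
        good_b = bundles[cfg.good.name]
        poor_b = bundles[cfg.poor.name]
    else:
        if not cfg.input_dirs or len(cfg.input_dirs) != 2:
            raise ValueError("simulate=False requires input_dirs=(good_dir, poor_dir)")
        good_b = _stage("load_good", load_season_dir, cfg.input_dirs[0], cfg.good.name)
        poor_b = _stage("load_poor", load_season_dir, cfg.input_dirs[1], cfg.poor.name)

    trips_g = _stage("trips_good", _season_trips, good_b, cfg)
    trips_p = _stage("trips_poor", _season_trips, poor_b, cfg)
    dives_g, tm_g = _stage("dives_good", _season_dives, good_b, trips_g, cfg)
    dives_p, tm_p = _stage("dives_poor", _season_dives, poor_b, trips_p, cfg)
    ac_g = _stage("acoustics_good", _season_acoustics, good_b, cfg)
    ac_p = _stage("acoustics_poor", _season_acoustics, poor_b, cfg)
    env_g = _stage("env_good", _season_env, good_b, cfg)
    env_p = _stage("env_poor", _season_env, poor_b, cfg)
    breeding = _stage("breeding", enviro.breeding_success,
                      pd.concat([good_b.breeding, poor_b.breeding], ignore_index=True))

    br_g = breeding.loc[breeding["season"] == good_b.scenario.name, "success"]
    br_p = breeding.loc[breeding["season"] == poor_b.scenario.name, "success"]

    endpoint_values = {
        "trip_duration_h": (trips_g["duration_h"], trips_p["duration_h"], "trips.csv"),
        "cumulative_distance_km": (trips_g["cum_dist_km"], trips_p["cum_dist_km"], "trips.csv"),
        "freq_complete_dives": (tm_g.get("freq_complete", pd.Series(dtype=float)),
                                tm_p.get("freq_complete", pd.Series(dtype=float)),
                                "trip_dive_metrics.csv"),
        "mean_dive_duration_min": (tm_g.get("mean_dive_duration_min", pd.Series(dtype=float)),
                                   tm_p.get("mean_dive_duration_min", pd.Series(dtype=float)),
                                   "trip_dive_metrics.csv"),
        "cumulative_dive_duration_min": (tm_g.get("cumulative_dive_duration_min", pd.Series(dtype=float)),
                                         tm_p.get("cumulative_dive_duration_min", pd.Series(dtype=float)),
                                         "trip_dive_metrics.csv"),
        "mean_bottom_depth_m": (tm_g.get("mean_bottom_depth_m", pd.Series(dtype=float)),
                                tm_p.get("mean_bottom_depth_m", pd.Series(dtype=float)),
                                "trip_dive_metrics.csv"),
        "max_bottom_depth_m": (tm_g.get("max_bottom_depth_m", pd.Series(dtype=float)),
                               tm_p.get("max_bottom_depth_m", pd.Series(dtype=float)),
                               "trip_dive_metrics.csv"),
        "capture_effort": (tm_g.get("mean_capture_effort", pd.Series(dtype=float)),
                           tm_p.get("mean_capture_effort", pd.Series(dtype=float)),
                           "trip_dive_metrics.csv"),
        "breeding_success": (br_g, br_p, "breeding_success.csv"),
        "nasc": (ac_g["nasc_by_bin"]["nasc"], ac_p["nasc_by_bin"]["nasc"], "nasc_grid.csv"),
        "swarm_depth_m": (ac_g["swarm"]["depth_mid_m"], ac_p["swarm"]["depth_mid_m"],
                          "nasc_grid.csv"),
        "aggregation_index": (ac_g["aggregation"]["aggregation_index"],
                              ac_p["aggregation"]["aggregation_index"],
                              "aggregation_by_depth.csv"),
        "chl": (env_g.get("CHL", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                env_p.get("CHL", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                "env_seasonal_means.csv"),
        "par": (env_g.get("PAR", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                env_p.get("PAR", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                "env_seasonal_means.csv"),
        "wsic": (env_g.get("SIC", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                 env_p.get("SIC", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                 "env_seasonal_means.csv"),
        "sws": (env_g.get("SWS", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                env_p.get("SWS", pd.DataFrame(columns=["mean_value"]))["mean_value"],
                "env_seasonal_means.csv"),
    }

    rows = []
    t0 = time.perf_counter()
    for i, ep in enumerate(ENDPOINTS):
        vg, vp, source = endpoint_values[ep]
        row = {"endpoint": ep}
        row.update(_contrast(vg, vp, cfg, 7919 * i, source))
        rows.append(row)
    timings.append(("permanova", time.perf_counter() - t0))
    report = pd.DataFrame(rows)

    results = {
        "config": cfg,
        "report": report,
        "trips": pd.concat([trips_g, trips_p], ignore_index=True),
        "trip_dive_metrics": pd.concat([tm_g, tm_p], ignore_index=True),
        "dives": pd.concat([d for d in (dives_g, dives_p) if len(d)],
                           ignore_index=True) if len(dives_g) or len(dives_p) else pd.DataFrame(),
        "acoustics": {"good": ac_g, "poor": ac_p},
        "env": {"good": env_g, "poor": env_p},
        "breeding": breeding,
        "timings": timings,
    }
    if cfg.out_dir:
        _write_outputs(results, cfg)
    return results


def _write_outputs(results, cfg):
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    results["report"].to_csv(os.path.join(out, "report.csv"), index=False)
    results["trips"].to_csv(os.path.join(out, "trips.csv"), index=False)
    results["trip_dive_metrics"].to_csv(os.path.join(out, "trip_dive_metrics.csv"), index=False)
    if len(results["dives"]):
        results["dives"].to_csv(os.path.join(out, "dives.csv"), index=False)
    for season in ("good", "poor"):
        ac = results["acoustics"][season]
        ac["grid"].to_csv(os.path.join(out, f"nasc_grid_{season}.csv"), index=False)
        ac["profile"].to_csv(os.path.join(out, f"vertical_profile_{season}.csv"), index=False)
        ac["aggregation"].to_csv(os.path.join(out, f"aggregation_by_depth_{season}.csv"), index=False)
        env = results["env"][season]
        if env:
            frames = [df.assign(variable=v) for v, df in env.items()]
            pd.concat(frames, ignore_index=True).to_csv(
                os.path.join(out, f"env_seasonal_means_{season}.csv"), index=False)
    results["breeding"].to_csv(os.path.join(out, "breeding_success.csv"), index=False)
    with open(os.path.join(out, "report.md"), "w") as fh:
        fh.write(results["report"].to_markdown(index=False))
    with open(os.path.join(out, "config.echo"), "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, default=str)
    with open(os.path.join(out, "run.log"), "w") as fh:
        for name, dt in results["timings"]:
            fh.write(f"{name}\t{dt:.2f}s\n")


def effect_direction_check(report, expected=None, alpha=0.05):
    """Compare a contrast report's directions against the expected map.

    Directional endpoints pass when the observed direction matches;
    ``ns`` endpoints pass when the contrast is not significant.
    """
    expected = expected or EXPECTED_DIRECTIONS
    rows = []
    for ep, want in expected.items():
        obs = report.loc[report["endpoint"] == ep, "direction"]
        observed = obs.iloc[0] if len(obs) else "missing"
        rows.append({"endpoint": ep, "expected": want, "observed": observed,
                     "passed": observed == want})
    return pd.DataFrame(rows)
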