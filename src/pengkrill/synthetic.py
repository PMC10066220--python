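"""Synthetic two-season study generator.

Emulates the inputs of a central-place-forager vs. krill-availability study:
GPS tracks of breeding penguins (5-min fixes), 1 Hz time-depth-recorder (TDR)
series with U/V-shaped dives and bottom-phase wiggles, a clustered krill
acoustic sample field along a survey transect, gridded environmental fields
(CHL, PAR, surface wind, winter sea-ice fraction) on a 5 km grid, and
nest/chick counts per sub-colony.

Two named scenarios describe contrasting seasons: a "good" season (high krill
biomass, shallow swarms, tight aggregation, short trips, high breeding
success) and a "poor" season (low, deep, diffuse krill; long trips; higher
per-dive capture effort; lower breeding success). The generator's couplings
are intentionally simple — they reproduce the *directions* of the seasonal
contrasts, not mechanistic effect sizes:

* probability that a dive is "complete" (has a bottom phase) increases with
  krill biomass: ``p = 0.45 + 0.35 * krill_biomass_scale``;
* a small fraction (3%) of complete dives target the krill depth mode,
  deepening maximum (but barely mean) dive depth when krill sit deep;
* wiggles per complete dive ~ Poisson(wiggle_rate_base), clipped to [2, 17]
  and fitted to an independently drawn bottom duration, so dive duration
  itself carries no season signal;
* PAR fields depend on the calendar month only (identical across seasons —
  irradiance has no year-to-year contrast here);
* chicks per nest ~ Normal(0.98 * krill_biomass_scale**0.42, 0.09), which
  puts the configured good/poor breeding-success ratio at ~1.4.

Identical scenario (including seed) gives bit-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km, offset_lonlat

NMI_KM = 1.852

#: Harmony Point, Nelson Island (South Shetland Islands), approximate position.
DEFAULT_COLONY = (-59.22, -62.30)

#: PAR does not differ between the two default seasons (mol photons m^-2 day^-1 scale).
PAR_MEAN = 45.0

_ENV_SD = {"CHL": 0.35, "PAR": 3.0, "SWS": 1.2, "SIC": 0.08}

#: depth scatter (m) of swarm parents and of samples around their parent
_PARENT_DEPTH_SD = 10.0
_OFFSPRING_DEPTH_SD = 6.0
_OFFSPRING_MEAN = 40  # samples per swarm parent (Poisson mean)
_DENSITY_MEANLOG = math.log(50.0)
_DENSITY_SDLOG = 0.75


@dataclass(frozen=True)
class SeasonScenario:
    """Parameters of one simulated breeding season.

    Depths in metres, durations in hours, intensities per km of transect,
    CHL in mg m^-3, wind in m s^-1, sea-ice cover as a fraction.
    """

    name: str
    krill_depth_mode: float = 50.0
    krill_biomass_scale: float = 1.0
    cluster_parent_intensity: float = 0.10
    cluster_offspring_sd: float = 1.0
    trip_duration_mean: float = 8.0
    dive_depth_mode: float = 40.0
    wiggle_rate_base: float = 6.0
    chl_mean: float = 1.2
    wind_mean: float = 6.0
    sic_mean: float = 0.55
    n_birds: int = 17
    n_trips_per_bird: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.name:
            raise ValueError("scenario needs a name")
        if not (20.0 <= self.krill_depth_mode <= 150.0):
            raise ValueError("krill_depth_mode must lie in [20, 150] m")
        for f in ("trip_duration_mean", "dive_depth_mode", "wiggle_rate_base",
                  "chl_mean", "wind_mean", "cluster_parent_intensity",
                  "cluster_offspring_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("krill_biomass_scale", "sic_mean"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.n_birds < 0 or self.n_trips_per_bird < 0:
            raise ValueError("counts must be non-negative")


GOOD_SEASON = SeasonScenario(name="good", seed=20)
POOR_SEASON = SeasonScenario(
    name="poor",
    krill_depth_mode=90.0,
    krill_biomass_scale=0.45,
    cluster_parent_intensity=0.14,
    cluster_offspring_sd=2.5,
    trip_duration_mean=12.0,
    wiggle_rate_base=9.0,
    chl_mean=0.6,
    wind_mean=8.0,
    sic_mean=0.30,
    n_birds=10,
    seed=21,
)


@dataclass
class SyntheticBundle:
    """All generated inputs for one season, plus the generating truth."""

    scenario: SeasonScenario
    gps_tables: dict
    tdr_tables: dict
    acoustic_samples: pd.DataFrame
    env_grids: dict  # (variable, "YYYY-MM") -> DataFrame(cell_id, lon, lat, value)
    breeding: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GPS tracks
# ---------------------------------------------------------------------------

def simulate_track(scenario, colony=DEFAULT_COLONY, rng=None, duration_h=None,
                   start_time=None, fix_interval_s=300.0,
                   time_jitter_s=20.0, dropout=0.02):
    """Simulate one out-and-back foraging trip as a GPS fix table.

    A correlated random walk heads away from the colony for roughly the first
    half of the trip (straight-line range capped near 35 km), then homes.
    The first and last fixes lie < 250 m from the colony. Fix times sit on a
    nominal 5-min cadence with small jitter and a few dropped fixes, to give
    the interpolation step something to do.

    Returns a DataFrame with columns ``time`` (UTC), ``lon``, ``lat``.
    """
    lon0, lat0 = float(colony[0]), float(colony[1])
    if not (np.isfinite(lon0) and np.isfinite(lat0)):
        raise ValueError("colony coordinates must be finite")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if start_time is None:
        start_time = pd.Timestamp("2020-01-01T00:00:00")
    if duration_h is None:
        duration_h = _draw_trip_duration(scenario, rng)
    n_steps = int(round(duration_h * 3600.0 / fix_interval_s))
    if n_steps < 2:
        # degenerate (sub-cadence) trip: two colony fixes; downstream >1 h filter drops it
        times = [pd.Timestamp(start_time), pd.Timestamp(start_time) + pd.Timedelta(seconds=fix_interval_s)]
        lon, lat = offset_lonlat(lon0, lat0, np.zeros(2), np.zeros(2))
        return pd.DataFrame({"time": times, "lon": lon, "lat": lat})

    speed = rng.uniform(2.0, 2.6)               # ground speed, m/s
    step = speed * fix_interval_s / 1000.0      # km per fix interval
    n_out = max(1, int(n_steps * rng.uniform(0.40, 0.52)))
    # straight-line range cap: one step of slack keeps the track under 35 km
    cap = min(35.0 - step, 0.55 * n_out * step)

    xs = [0.0]
    ys = [0.0]
    x = y = 0.0
    heading = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(1, n_steps):
        if i <= n_out:
            heading += rng.normal(0.0, 0.35)
        else:
            # homing bias ramps up through the inbound half so the bird
            # meanders on the way back and arrives near the planned end time
            home = math.atan2(-y, -x)
            w = ((i - n_out) / max(n_steps - n_out, 1)) ** 2.0
            d = math.hypot(x, y)
            if d <= (n_steps - i) * step * 0.6:
                w = min(w, 0.4)                 # early: keep wandering
            hx = (1.0 - w) * math.cos(heading) + 1.4 * w * math.cos(home)
            hy = (1.0 - w) * math.sin(heading) + 1.4 * w * math.sin(home)
            heading = math.atan2(hy, hx) + rng.normal(0.0, 0.25)
            if d <= 0.8 * step and i > n_out + 1:
                break
        if math.hypot(x, y) > cap:
            heading = math.atan2(-y, -x) + rng.normal(0.0, 0.3)
        x += step * math.cos(heading)
        y += step * math.sin(heading)
        xs.append(x)
        ys.append(y)
    # walk straight home so the trip ends < 250 m from the colony
    while math.hypot(x, y) > 0.15:
        d = math.hypot(x, y)
        frac = min(step, d) / d
        x += -x * frac
        y += -y * frac
        xs.append(x)
        ys.append(y)

    xs = np.asarray(xs)
    ys = np.asarray(ys)
    n = len(xs)
    t = np.arange(n) * fix_interval_s
    if time_jitter_s > 0 and n > 2:
        t[1:-1] = t[1:-1] + rng.uniform(-time_jitter_s, time_jitter_s, n - 2)
    keep = np.ones(n, dtype=bool)
    if dropout > 0 and n > 4:
        keep[1:-1] = rng.random(n - 2) >= dropout
    lon, lat = offset_lonlat(lon0, lat0, xs[keep], ys[keep])
    times = pd.Timestamp(start_time) + pd.to_timedelta(np.round(t[keep]), unit="s")
    return pd.DataFrame({"time": times, "lon": lon, "lat": lat})


def _draw_trip_duration(scenario, rng):
    shape = 16.0
    d = rng.gamma(shape, scenario.trip_duration_mean / shape)
    return float(np.clip(d, 1.5, 24.0))


# ---------------------------------------------------------------------------
# Dive profiles
# ---------------------------------------------------------------------------

def simulate_dive_profile(max_depth, bottom_duration_s, n_wiggles,
                          wiggle_amplitude=2.0, cadence_s=1.0,
                          vertical_rate=1.2):
    """Build one dive depth profile (m, positive down) sampled at ``cadence_s``.

    Piecewise shape: linear descent at ``vertical_rate`` m/s, a bottom phase
    at ``max_depth`` carrying exactly ``n_wiggles`` upward excursions (local
    depth minima) of prominence ``wiggle_amplitude``, then a linear ascent.
    The profile starts and ends at the surface (0 m). The bottom phase is
    extended, if needed, to ``4 * n_wiggles + 1`` samples so the requested
    wiggle count always fits.
    """
    if max_depth <= 0:
        raise ValueError("max_depth must be positive")
    if n_wiggles < 0:
        raise ValueError("n_wiggles must be >= 0")
    if wiggle_amplitude <= 0:
        raise ValueError("wiggle_amplitude must be positive")
    if wiggle_amplitude >= max_depth:
        raise ValueError("wiggle_amplitude must be smaller than max_depth")
    n_wiggles = int(n_wiggles)
    n_desc = max(1, math.ceil(max_depth / (vertical_rate * cadence_s)))
    desc = np.minimum(np.arange(1, n_desc + 1) * vertical_rate * cadence_s, max_depth)
    b = max(int(round(bottom_duration_s / cadence_s)), 4 * n_wiggles + 1, 1)
    bottom = np.full(b, float(max_depth))
    if n_wiggles > 0:
        centers = np.clip(((np.arange(n_wiggles) + 0.5) * b / n_wiggles).astype(int), 1, b - 2)
        bottom[centers] = max_depth - wiggle_amplitude
        bottom[centers - 1] = max_depth - wiggle_amplitude / 2.0
        bottom[centers + 1] = max_depth - wiggle_amplitude / 2.0
    return np.concatenate([[0.0], desc, bottom, desc[::-1], [0.0]])


def simulate_bounce_dive(rng, vertical_rate=2.4, cadence_s=1.0):
    """Build one incomplete ("bounce") dive: a fast, shallow V with no bottom.

    The bird drops to a 13–17 m apex at ~2.4 m/s, rises to 8–10 m and
    wanders there (gentle 0.6 m undulation, below any wiggle threshold)
    before surfacing. Time spent within 80% of the apex depth stays under
    5 s, so the dive has no bottom phase by the completeness rule, while its
    total duration matches a typical complete dive.
    """
    apex = rng.uniform(13.0, 17.0)
    wander_depth = rng.uniform(8.0, 10.0)
    wander_s = int(rng.uniform(62.0, 126.0))
    step = vertical_rate * cadence_s
    down = np.minimum(np.arange(1, math.ceil(apex / step) + 1) * step, apex)
    up = np.arange(apex - step, wander_depth, -step)
    t = np.arange(wander_s)
    wander = wander_depth + 0.3 * np.sin(2.0 * np.pi * t / 8.0)
    out = np.arange(wander[-1] - step, 0.0, -step)
    return np.concatenate([[0.0], down, up, wander, out, [0.0]])


# ---------------------------------------------------------------------------
# Krill acoustic field (Thomas cluster process along a transect)
# ---------------------------------------------------------------------------

def simulate_krill_field(scenario, transect_length_nmi=270.0, rng=None):
    """Simulate sample-level acoustic densities along a survey transect.

    Swarm parents follow a 1-D Poisson process along the transect
    (``cluster_parent_intensity`` parents per km); samples scatter around each
    parent with horizontal sd ``cluster_offspring_sd`` (km) and Gaussian depth
    around ``krill_depth_mode``. Per-sample density is lognormal, scaled by
    ``krill_biomass_scale``. Returns a DataFrame sorted by distance with
    columns ``distance_nmi``, ``depth_m``, ``density``.
    """
    if transect_length_nmi <= 0:
        raise ValueError("transect_length_nmi must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    empty = pd.DataFrame({"distance_nmi": pd.Series(dtype=float),
                          "depth_m": pd.Series(dtype=float),
                          "density": pd.Series(dtype=float)})
    if scenario.krill_biomass_scale == 0:
        return empty
    length_km = transect_length_nmi * NMI_KM
    n_parents = rng.poisson(scenario.cluster_parent_intensity * length_km)
    if n_parents == 0:
        return empty
    px = rng.uniform(0.0, length_km, n_parents)
    pz = rng.normal(scenario.krill_depth_mode, _PARENT_DEPTH_SD, n_parents)
    counts = rng.poisson(_OFFSPRING_MEAN, n_parents)
    x = np.repeat(px, counts) + rng.normal(0.0, scenario.cluster_offspring_sd, counts.sum())
    z = np.repeat(pz, counts) + rng.normal(0.0, _OFFSPRING_DEPTH_SD, counts.sum())
    x = np.clip(x, 0.0, length_km)
    z = np.clip(z, 5.0, 495.0)
    dens = rng.lognormal(_DENSITY_MEANLOG, _DENSITY_SDLOG, counts.sum()) * scenario.krill_biomass_scale
    out = pd.DataFrame({"distance_nmi": x / NMI_KM, "depth_m": z, "density": dens})
    return out.sort_values("distance_nmi", kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# Dive sequences within trips (TDR series)
# ---------------------------------------------------------------------------

def _complete_probability(scenario):
    return float(np.clip(0.45 + 0.35 * scenario.krill_biomass_scale, 0.05, 0.95))


def _simulate_trip_dive_series(scenario, trip_duration_s, rng):
    """1 Hz depth series for one trip, plus per-dive truth records."""
    mu_trip = float(np.clip(rng.normal(scenario.dive_depth_mode, 9.0), 15.0, 60.0))
    dur_jitter = rng.normal(0.0, 4.0)   # per-trip surface-interval random effect (s)
    bot_jitter = rng.normal(0.0, 10.0)  # per-trip bottom-duration random effect (s)
    p_complete = _complete_probability(scenario)
    segs = []
    truth = []
    t = 0
    while True:
        gap = int(round(np.clip(rng.uniform(120.0, 360.0) + dur_jitter, 60.0, 420.0)))
        complete = rng.random() < p_complete
        if complete:
            if rng.random() < 0.03:
                depth = rng.normal(scenario.krill_depth_mode, 10.0)
            else:
                depth = rng.normal(mu_trip, 6.0)
            depth = float(np.clip(depth, 12.0, 133.0))
            amp = float(rng.uniform(1.5, min(3.0, 0.18 * depth)))
            # bottom duration is drawn independently of the wiggle count and
            # the count is fitted to it, so dive duration carries no season
            # signal of its own
            bottom = max(10.0, rng.uniform(30.0, 60.0) + bot_jitter)
            n_w = int(np.clip(rng.poisson(scenario.wiggle_rate_base), 2, 17))
            n_w = min(n_w, int((bottom - 2.0) // 4.0))
            # transit rate grows with target depth, keeping dive duration
            # roughly depth-independent
            vrate = float(np.clip(1.2 * depth / 40.0, 1.0, 3.0))
            profile = simulate_dive_profile(depth, bottom, n_w, amp,
                                            vertical_rate=vrate)
        else:
            n_w = 0
            amp = np.nan
            profile = simulate_bounce_dive(rng)
            depth = float(profile.max())
        if t + gap + len(profile) > trip_duration_s - 60:
            break
        segs.append(np.zeros(gap))
        segs.append(profile)
        truth.append({"t_start_s": t + gap, "max_depth": depth, "n_wiggles": n_w,
                      "complete": complete, "amplitude": amp,
                      "duration_s": len(profile)})
        t += gap + len(profile)
    tail = int(trip_duration_s) - t
    if tail > 0:
        segs.append(np.zeros(tail))
    depths = np.concatenate(segs) if segs else np.zeros(int(trip_duration_s))
    return depths, truth


# ---------------------------------------------------------------------------
# Environmental grids and breeding counts
# ---------------------------------------------------------------------------

def _grid_geometry(colony, half_extent_km=80.0, cell_km=5.0):
    g = np.arange(-half_extent_km, half_extent_km + cell_km / 2, cell_km)
    gx, gy = np.meshgrid(g, g)
    lon, lat = offset_lonlat(colony[0], colony[1], gx.ravel(), gy.ravel())
    return pd.DataFrame({"cell_id": np.arange(lon.size), "lon": lon, "lat": lat})


def _env_months(scenario_start):
    """Summer (Nov–Jan) and previous-winter (Jun–Sep) month labels."""
    y = pd.Timestamp(scenario_start).year
    summer = [f"{y}-11", f"{y}-12", f"{y + 1}-01"]
    winter = [f"{y}-06", f"{y}-07", f"{y}-08", f"{y}-09"]
    return summer, winter


def _simulate_env_grids(scenario, geometry, season_start, rng):
    summer, winter = _env_months(season_start)
    means = {"CHL": scenario.chl_mean, "PAR": PAR_MEAN, "SWS": scenario.wind_mean,
             "SIC": scenario.sic_mean}
    grids = {}
    for var, months in (("CHL", summer), ("PAR", summer), ("SWS", summer), ("SIC", winter)):
        for m in months:
            if var == "PAR":
                # solar irradiance is treated as an inter-annual climatology:
                # the field depends on the calendar month only, so the two
                # seasons see identical PAR (no seasonal contrast by design)
                par_rng = np.random.default_rng(910_000 + int(m.split("-")[1]))
                v = par_rng.normal(means[var], _ENV_SD[var], len(geometry))
            else:
                v = rng.normal(means[var], _ENV_SD[var], len(geometry))
            if var == "SIC":
                v = np.clip(v, 0.0, 1.0)
            else:
                v = np.clip(v, 0.01, None)
            g = geometry.copy()
            g["value"] = v
            grids[(var, m)] = g
    return grids


def _simulate_breeding(scenario, rng, n_subcolonies=12):
    rate_mean = 0.98 * scenario.krill_biomass_scale ** 0.42 if scenario.krill_biomass_scale > 0 else 0.05
    nests = rng.integers(60, 221, n_subcolonies)
    rates = np.clip(rng.normal(rate_mean, 0.09, n_subcolonies), 0.05, 2.0)
    chicks = np.round(nests * rates).astype(int)
    return pd.DataFrame({
        "subcolony": [f"{scenario.name}_sc{i:02d}" for i in range(n_subcolonies)],
        "nests_incubation": nests,
        "chicks_creche": chicks,
        "season": scenario.name,
    })


def expected_breeding_ratio(good=GOOD_SEASON, poor=POOR_SEASON):
    """Configured ratio of mean chicks/nest between two scenarios (~1.4 by default)."""
    return (good.krill_biomass_scale / poor.krill_biomass_scale) ** 0.42


# ---------------------------------------------------------------------------
# Full bundles
# ---------------------------------------------------------------------------

def simulate_season(scenario, colony=DEFAULT_COLONY, season_start=None,
                    transect_length_nmi=270.0):
    """Generate one season's full input bundle from its scenario."""
    rng = np.random.default_rng(scenario.seed)
    if season_start is None:
        season_start = pd.Timestamp("2020-12-18")
    season_start = pd.Timestamp(season_start)

    gps_tables = {}
    tdr_tables = {}
    trip_truth = []
    dive_truth = []
    for b in range(scenario.n_birds):
        bird = f"{scenario.name}_b{b:02d}"
        deploy = season_start + pd.Timedelta(days=float(rng.uniform(0, 6)))
        gps_parts = [_colony_dwell(colony, deploy, 0.5, rng)]
        depth_parts = []
        tdr_start = deploy
        t_cursor = deploy + pd.Timedelta(minutes=30)
        for k in range(scenario.n_trips_per_bird):
            dur_h = _draw_trip_duration(scenario, rng)
            track = simulate_track(scenario, colony, rng, duration_h=dur_h,
                                   start_time=t_cursor)
            trip_start, trip_end = track["time"].iloc[0], track["time"].iloc[-1]
            realized_s = (trip_end - trip_start).total_seconds()
            # 1 Hz depths for this trip; pad the pre-trip colony dwell with zeros
            pre_gap = int((trip_start - tdr_start).total_seconds()) - sum(len(p) for p in depth_parts)
            if pre_gap > 0:
                depth_parts.append(np.zeros(pre_gap))
            depths, dives = _simulate_trip_dive_series(scenario, realized_s, rng)
            offset_s = int((trip_start - tdr_start).total_seconds())
            for d in dives:
                d.update(bird=bird, trip_idx=k,
                         t_start=trip_start + pd.Timedelta(seconds=d["t_start_s"]))
            dive_truth.extend(dives)
            depth_parts.append(depths)
            trip_truth.append({"bird": bird, "trip_idx": k, "start": trip_start,
                               "end": trip_end, "duration_h": realized_s / 3600.0})
            gps_parts.append(track)
            rest_h = float(rng.uniform(2.0, 5.0))
            gps_parts.append(_colony_dwell(colony, trip_end + pd.Timedelta(minutes=5), rest_h, rng))
            t_cursor = trip_end + pd.Timedelta(hours=rest_h, minutes=10)
        gps = pd.concat(gps_parts, ignore_index=True)
        gps = gps.sort_values("time", kind="mergesort", ignore_index=True)
        gps = gps[~gps["time"].duplicated()].reset_index(drop=True)
        gps_tables[bird] = gps
        depth = np.concatenate(depth_parts) if depth_parts else np.zeros(1)
        # sensor offset + noise: exercises the zero-offset correction
        offset = rng.uniform(0.2, 0.8)
        depth = depth + offset + rng.normal(0.0, 0.05, len(depth))
        tdr_tables[bird] = pd.DataFrame({
            "time": tdr_start + pd.to_timedelta(np.arange(len(depth)), unit="s"),
            "depth_m": depth,
        })

    acoustic = simulate_krill_field(scenario, transect_length_nmi, rng)
    geometry = _grid_geometry(colony)
    env = _simulate_env_grids(scenario, geometry, season_start - pd.DateOffset(months=1), rng)
    breeding = _simulate_breeding(scenario, rng)

    truth = {
        "scenario": dataclasses.asdict(scenario),
        "colony": list(colony),
        "season_start": str(season_start),
        "transect_length_nmi": transect_length_nmi,
        "n_trips": len(trip_truth),
        "trips": pd.DataFrame(trip_truth),
        "dives": pd.DataFrame(dive_truth),
        "expected_complete_probability": _complete_probability(scenario),
    }
    return SyntheticBundle(scenario=scenario, gps_tables=gps_tables,
                           tdr_tables=tdr_tables, acoustic_samples=acoustic,
                           env_grids=env, breeding=breeding, truth=truth)


def _colony_dwell(colony, start, duration_h, rng):
    n = max(2, int(duration_h * 12))  # 5-min cadence
    jitter = rng.normal(0.0, 0.05, (n, 2))  # ~50 m scatter, inside the 250 m buffer
    lon, lat = offset_lonlat(colony[0], colony[1], jitter[:, 0], jitter[:, 1])
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * 300, unit="s")
    return pd.DataFrame({"time": times, "lon": lon, "lat": lat})


def simulate_bundle(good=GOOD_SEASON, poor=POOR_SEASON, colony=DEFAULT_COLONY,
                    transect_length_nmi=270.0,
                    season_starts=("2019-12-18", "2021-12-18")):
    """Generate both seasons' bundles. Scenario names must differ."""
    if good.name == poor.name:
        raise ValueError("scenario names must differ")
    return {
        good.name: simulate_season(good, colony, season_starts[0], transect_length_nmi),
        poor.name: simulate_season(poor, colony, season_starts[1], transect_length_nmi),
    }


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_bundle(bundle, out_dir):
    """Write one bundle to CSV files plus a truth.json of generating parameters."""
    os.makedirs(out_dir, exist_ok=True)
    for bird, df in bundle.gps_tables.items():
        out = df.copy()
        out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(os.path.join(out_dir, f"gps_{bird}.csv"), index=False)
    for bird, df in bundle.tdr_tables.items():
        out = df.copy()
        out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(os.path.join(out_dir, f"tdr_{bird}.csv"), index=False,
                   float_format="%.3f")
    bundle.acoustic_samples.to_csv(os.path.join(out_dir, "acoustic_samples.csv"), index=False)
    for (var, month), df in bundle.env_grids.items():
        df.to_csv(os.path.join(out_dir, f"env_{var}_{month}.csv"), index=False)
    bundle.breeding.to_csv(os.path.join(out_dir, "breeding.csv"), index=False)
    truth = dict(bundle.truth)
    for key in ("trips", "dives"):
        df = truth.get(key)
        if isinstance(df, pd.DataFrame):
            d = df.copy()
            for c in d.columns:
                if pd.api.types.is_datetime64_any_dtype(d[c]):
                    d[c] = d[c].dt.strftime("%Y-%m-%dT%H:%M:%S")
            truth[key] = d.to_dict(orient="records")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
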