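"""GPS track regularisation and central-place foraging-trip segmentation.

Processing order follows standard biologging practice for central-place
foragers: linear interpolation onto a fixed 5-min lattice, an iterative
10 m/s speed filter, removal of fixes within 250 m of the colony, splitting
the remainder into temporally contiguous excursions, and discarding trips
of one hour or less. Distances are great-circle (haversine, R = 6371 km).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_km


@dataclass
class ForagingTrip:
    """One colony excursion: ordered fixes plus summary metrics."""

    bird_id: str
    fixes: pd.DataFrame
    duration_h: float
    cumulative_distance_km: float
    max_range_km: float

    @property
    def start(self):
        return self.fixes["time"].iloc[0]

    @property
    def end(self):
        return self.fixes["time"].iloc[-1]


def _check_track(df):
    if len(df) < 2:
        raise ValueError("need at least 2 fixes")
    t = df["time"].to_numpy()
    dt = np.diff(t).astype("timedelta64[ns]").astype(np.int64)
    if (dt <= 0).any():
        raise ValueError("fix times must be strictly increasing (no duplicates)")


def interpolate_track(df, interval_s=300.0):
    """Resample a fix table onto an exact ``interval_s`` lattice.

    New times are multiples of the interval from the first fix; lon/lat are
    linearly interpolated. No extrapolation beyond the last fix. A track
    already on the lattice is returned unchanged (up to float round-trip).
    """
    _check_track(df)
    t0 = df["time"].iloc[0]
    secs = (df["time"] - t0).dt.total_seconds().to_numpy()
    new_secs = np.arange(0.0, secs[-1] + 1e-9, interval_s)
    lon = np.interp(new_secs, secs, df["lon"].to_numpy())
    lat = np.interp(new_secs, secs, df["lat"].to_numpy())
    times = t0 + pd.to_timedelta(new_secs, unit="s")
    return pd.DataFrame({"time": times, "lon": lon, "lat": lat})


def speed_filter(df, vmax=10.0):
    """Iteratively drop fixes whose incoming segment speed exceeds ``vmax`` m/s.

    Forward pass keeping a running "last retained" fix: each fix is tested
    against the previous retained one, so speeds are effectively recomputed
    after every removal. The first fix is never removed.
    """
    if len(df) == 0:
        return df.copy()
    _check_track(df) if len(df) >= 2 else None
    secs = (df["time"] - df["time"].iloc[0]).dt.total_seconds().to_numpy()
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    keep = [0]
    for i in range(1, len(df)):
        j = keep[-1]
        dt = secs[i] - secs[j]
        speed = haversine_km(lon[j], lat[j], lon[i], lat[i]) * 1000.0 / dt
        if speed <= vmax:
            keep.append(i)
    return df.iloc[keep].reset_index(drop=True)


def segment_trips(df, colony, buffer_m=250.0, min_duration_h=1.0,
                  interval_s=300.0, bird_id=""):
    """Split a regularised track into foraging trips.

    Fixes closer than ``buffer_m`` to the colony are removed; the remaining
    fixes are split wherever the time gap exceeds the interpolation interval;
    runs lasting ``min_duration_h`` or less are discarded.
    """
    if not (np.isfinite(colony[0]) and np.isfinite(colony[1])):
        raise ValueError("colony coordinates must be finite")
    if len(df) == 0:
        return []
    dist_km = haversine_km(df["lon"].to_numpy(), df["lat"].to_numpy(), colony[0], colony[1])
    away = df.loc[dist_km >= buffer_m / 1000.0].reset_index(drop=True)
    if len(away) == 0:
        return []
    secs = (away["time"] - away["time"].iloc[0]).dt.total_seconds().to_numpy()
    breaks = np.flatnonzero(np.diff(secs) > interval_s + 1e-6)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(away) - 1]
    trips = []
    for s, e in zip(starts, ends):
        run = away.iloc[s:e + 1].reset_index(drop=True)
        if len(run) < 2:
            continue
        dur_h = (run["time"].iloc[-1] - run["time"].iloc[0]).total_seconds() / 3600.0
        if dur_h <= min_duration_h:
            continue
        dur, cum, rng = trip_metrics(run, colony)
        trips.append(ForagingTrip(bird_id=bird_id, fixes=run, duration_h=dur,
                                  cumulative_distance_km=cum, max_range_km=rng))
    return trips


def trip_metrics(fixes, colony):
    """(duration h, cumulative haversine distance km, max range from colony km)."""
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes for trip metrics")
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    duration_h = (fixes["time"].iloc[-1] - fixes["time"].iloc[0]).total_seconds() / 3600.0
    cumulative = float(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]).sum())
    max_range = float(haversine_km(lon, lat, colony[0], colony[1]).max())
    return duration_h, cumulative, max_range


def process_gps_table(df, colony, interval_s=300.0, vmax=10.0,
                      buffer_m=250.0, min_duration_h=1.0, bird_id=""):
    """interpolate → speed filter → segment, returning a list of trips."""
    reg = interpolate_track(df, interval_s)
    filt = speed_filter(reg, vmax)
    return segment_trips(filt, colony, buffer_m, min_duration_h, interval_s, bird_id)


def trips_table(trips):
    """Summary DataFrame for a list of trips (one row per trip)."""
    counters: dict = {}
    rows = []
    for t in trips:
        i = counters.get(t.bird_id, 0)
        counters[t.bird_id] = i + 1
        rows.append({
            "bird_id": t.bird_id,
            "trip_id": f"{t.bird_id}_t{i:02d}",
            "start": t.start,
            "end": t.end,
            "duration_h": t.duration_h,
            "cum_dist_km": t.cumulative_distance_km,
            "max_range_km": t.max_range_km,
        })
    cols = ["bird_id", "trip_id", "start", "end", "duration_h", "cum_dist_km", "max_range_km"]
    return pd.DataFrame(rows, columns=cols)
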