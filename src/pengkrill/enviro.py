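"""Environmental extraction around the colony, climatologies, breeding success.

Gridded fields (5 km cells) are subset to cells whose centres lie within a
75 km haversine radius of the colony. Spring–summer variables (CHL, PAR,
surface wind) are averaged over November–January; winter sea-ice cover over
June–September of the immediately previous winter. Breeding success is
chicks counted at crèche divided by nests counted at incubation, per
sub-colony.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .geo import haversine_km

log = logging.getLogger(__name__)

#: which seasonal window each variable uses
SEASON_WINDOWS = {"CHL": "summer", "PAR": "summer", "SWS": "summer", "SIC": "winter"}


def extract_radius(grid, colony, radius_km=75.0):
    """Cells whose centres lie within ``radius_km`` of the colony."""
    if len(grid) == 0:
        raise ValueError("empty grid")
    d = haversine_km(grid["lon"].to_numpy(), grid["lat"].to_numpy(),
                     colony[0], colony[1])
    sub = grid.loc[d <= radius_km].copy()
    if len(sub) == 0:
        raise ValueError(f"no cells within {radius_km} km of the colony")
    return sub


def season_window_months(season_start_year, window):
    """Month labels for a breeding season starting in ``season_start_year``.

    ``summer`` → Nov, Dec of the start year and Jan of the next;
    ``winter`` → Jun–Sep of the start year (the immediately previous winter).
    """
    y = int(season_start_year)
    if window == "summer":
        return [f"{y}-11", f"{y}-12", f"{y + 1}-01"]
    if window == "winter":
        return [f"{y}-06", f"{y}-07", f"{y}-08", f"{y}-09"]
    raise ValueError(f"unknown window {window!r}")


def seasonal_means(month_grids, months):
    """Per-cell mean over a window's months.

    ``month_grids`` maps month label → DataFrame(cell_id, lon, lat, value).
    Missing months raise a warning and the mean is taken over those present.
    """
    have = [m for m in months if m in month_grids]
    missing = [m for m in months if m not in month_grids]
    if missing:
        warnings.warn(f"missing months {missing}; averaging over {have}")
    if not have:
        raise ValueError("no months of data in the window")
    frames = [month_grids[m][["cell_id", "lon", "lat", "value"]] for m in have]
    cat = pd.concat(frames, ignore_index=True)
    out = cat.groupby(["cell_id", "lon", "lat"], as_index=False)["value"].mean()
    return out.rename(columns={"value": "mean_value"})


def monthly_climatology(series):
    """Per-calendar-month mean and sd across years.

    ``series`` is a DataFrame with a ``month`` column (datetime-like or
    "YYYY-MM" strings) and a ``value`` column. Months observed in a single
    year get a missing sd.
    """
    df = series.copy()
    ts = pd.to_datetime(df["month"])
    df["_m"] = ts.dt.month
    g = df.groupby("_m")["value"].agg(["mean", lambda x: x.std(ddof=1), "count"])
    g.columns = ["mean", "sd", "n_years"]
    g.loc[g["n_years"] < 2, "sd"] = np.nan
    g = g.reset_index().rename(columns={"_m": "month"})
    return g.sort_values("month", ignore_index=True)


def breeding_success(records):
    """Per-sub-colony chicks-per-nest, excluding zero-nest records (logged).

    Returns a DataFrame with a ``success`` column appended.
    """
    if len(records) == 0:
        raise ValueError("no breeding records")
    df = records.copy()
    bad = df["nests_incubation"] <= 0
    if bad.any():
        log.info("breeding_success: excluding %d zero-nest records", int(bad.sum()))
        df = df.loc[~bad].copy()
    if len(df) == 0:
        raise ValueError("all records had zero nests")
    df["success"] = df["chicks_creche"] / df["nests_incubation"]
    return df


def breeding_season_ratio(success_df, numerator_season, denominator_season):
    """Ratio of season-mean breeding success between two seasons."""
    means = success_df.groupby("season")["success"].mean()
    return float(means[numerator_season] / means[denominator_season])
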