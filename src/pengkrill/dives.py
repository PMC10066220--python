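"""Dive detection and phase analysis for 1 Hz time-depth-recorder series.

A dive is a maximal run of samples deeper than a threshold (3 m default).
Its bottom phase is the contiguous span from the first to the last sample at
or beyond 80% of the dive's maximum depth; descent precedes it and ascent
follows. A dive is "complete" when the bottom phase lasts at least 5 s —
the operational reading of "a dive with a bottom phase", i.e. one where the
bird stopped to search rather than just bounced. Capture effort is counted
as wiggles: prominent (≥ 1 m) local depth minima within the bottom phase,
a standard depth-only proxy for prey pursuit events.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass
class DiveRecord:
    """One detected dive; sample indices are inclusive and series-relative."""

    start_idx: int
    end_idx: int
    max_depth: float
    duration_s: float
    descent: tuple | None = None   # (first, last) sample index, inclusive
    bottom: tuple | None = None
    ascent: tuple | None = None
    bottom_mean_depth: float = math.nan
    bottom_max_depth: float = math.nan
    n_wiggles: int = 0
    is_complete: bool = False

    def bottom_duration_s(self, cadence_s=1.0):
        if self.bottom is None:
            return 0.0
        return (self.bottom[1] - self.bottom[0] + 1) * cadence_s


def zero_offset_correct(depths, window_s=1800.0, quantile=0.05, cadence_s=1.0,
                        smooth_quantile=0.25):
    """Remove slow surface-baseline drift from a depth series.

    The baseline is a low quantile of the series on non-overlapping blocks
    (block = window/30), smoothed by a centred rolling lower quartile across
    blocks and linearly interpolated back to sample resolution — an O(n)
    surface-line estimate that tracks slow drift with little lag, provided
    each window contains some surface time. Corrected depths are clipped at
    >= 0.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth series")
    block = max(1, int(round(window_s / cadence_s / 30)))
    n_blocks = math.ceil(depths.size / block)
    pad = n_blocks * block - depths.size
    padded = np.pad(depths, (0, pad), mode="edge") if pad else depths
    block_q = np.quantile(padded.reshape(n_blocks, block), quantile, axis=1)
    bq = pd.Series(block_q).rolling(30, center=True, min_periods=1).quantile(smooth_quantile).to_numpy()
    centers = (np.arange(n_blocks) + 0.5) * block
    baseline = np.interp(np.arange(depths.size), centers, bq)
    return np.clip(depths - baseline, 0.0, None)


def detect_dives(depths, threshold_m=3.0, cadence_s=1.0):
    """Detect dives as maximal runs with depth > threshold.

    Returns DiveRecords with start/end/max/duration set and phases unset.
    """
    depths = np.asarray(depths, dtype=float)
    wet = depths > threshold_m
    if not wet.any():
        return []
    edges = np.diff(wet.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if wet[0]:
        starts = np.r_[0, starts]
    if wet[-1]:
        ends = np.r_[ends, depths.size - 1]
    return [
        DiveRecord(start_idx=int(s), end_idx=int(e),
                   max_depth=float(depths[s:e + 1].max()),
                   duration_s=float((e - s + 1) * cadence_s))
        for s, e in zip(starts, ends)
    ]


def segment_phases(dive, depths, bottom_fraction=0.8):
    """Assign descent/bottom/ascent phases to a detected dive (in place).

    The bottom phase spans from the first to the last sample with depth
    >= bottom_fraction * max_depth. Dives shorter than 3 samples get no
    bottom phase and are marked incomplete.
    """
    depths = np.asarray(depths, dtype=float)
    s, e = dive.start_idx, dive.end_idx
    seg = depths[s:e + 1]
    if seg.size < 3:
        dive.descent = (s, e)
        dive.bottom = None
        dive.ascent = None
        dive.is_complete = False
        return dive
    deep = np.flatnonzero(seg >= bottom_fraction * dive.max_depth)
    b0, b1 = int(deep[0]), int(deep[-1])
    dive.bottom = (s + b0, s + b1)
    dive.descent = (s, s + b0 - 1) if b0 > 0 else None
    dive.ascent = (s + b1 + 1, e) if b1 < seg.size - 1 else None
    bseg = seg[b0:b1 + 1]
    dive.bottom_mean_depth = float(bseg.mean())
    dive.bottom_max_depth = float(bseg.max())
    return dive


def count_wiggles(dive, depths, min_amplitude_m=1.0):
    """Count wiggles: local depth minima of prominence >= min_amplitude_m
    within the bottom phase. A dive without a bottom phase has 0 wiggles."""
    if dive.bottom is None:
        return 0
    depths = np.asarray(depths, dtype=float)
    seg = depths[dive.bottom[0]:dive.bottom[1] + 1]
    if seg.size < 3:
        return 0
    peaks, _ = find_peaks(-seg, prominence=min_amplitude_m)
    return int(peaks.size)


def classify_complete(dive, min_bottom_s=5.0, cadence_s=1.0):
    """A dive is complete iff its bottom phase lasts >= min_bottom_s."""
    dive.is_complete = dive.bottom_duration_s(cadence_s) >= min_bottom_s
    return dive.is_complete


def process_depth_series(depths, threshold_m=3.0, bottom_fraction=0.8,
                         min_amplitude_m=1.0, min_bottom_s=5.0, cadence_s=1.0):
    """Full per-series dive analysis; returns a DataFrame, one row per dive."""
    records = detect_dives(depths, threshold_m, cadence_s)
    rows = []
    for d in records:
        segment_phases(d, depths, bottom_fraction)
        d.n_wiggles = count_wiggles(d, depths, min_amplitude_m)
        classify_complete(d, min_bottom_s, cadence_s)
        rows.append({
            "start_idx": d.start_idx,
            "end_idx": d.end_idx,
            "duration_s": d.duration_s,
            "max_depth_m": d.max_depth,
            "bottom_mean_m": d.bottom_mean_depth,
            "bottom_max_m": d.bottom_max_depth,
            "bottom_duration_s": d.bottom_duration_s(cadence_s),
            "n_wiggles": d.n_wiggles,
            "complete": d.is_complete,
        })
    cols = ["start_idx", "end_idx", "duration_s", "max_depth_m", "bottom_mean_m",
            "bottom_max_m", "bottom_duration_s", "n_wiggles", "complete"]
    return pd.DataFrame(rows, columns=cols)


def trip_dive_metrics(dive_df, trip_id=""):
    """Aggregate one trip's dives into the standard effort metrics.

    Bottom depths and capture effort are taken over complete dives only
    (wiggles are defined within bottom phases). Durations are reported in
    minutes. With zero dives all metrics are 0 and freq_complete is NaN.
    """
    n = len(dive_df)
    if n == 0:
        return {"trip_id": trip_id, "n_dives": 0, "freq_complete": math.nan,
                "mean_dive_duration_min": 0.0, "cumulative_dive_duration_min": 0.0,
                "mean_bottom_depth_m": 0.0, "max_bottom_depth_m": 0.0,
                "mean_capture_effort": 0.0, "total_wiggles": 0}
    comp = dive_df[dive_df["complete"]]
    return {
        "trip_id": trip_id,
        "n_dives": n,
        "freq_complete": len(comp) / n,
        "mean_dive_duration_min": float(dive_df["duration_s"].mean()) / 60.0,
        "cumulative_dive_duration_min": float(dive_df["duration_s"].sum()) / 60.0,
        "mean_bottom_depth_m": float(comp["bottom_mean_m"].mean()) if len(comp) else 0.0,
        "max_bottom_depth_m": float(comp["bottom_max_m"].max()) if len(comp) else 0.0,
        "mean_capture_effort": float(comp["n_wiggles"].mean()) if len(comp) else 0.0,
        "total_wiggles": int(dive_df["n_wiggles"].sum()),
    }


def vertical_effort_profile(trip_metrics_df, bin_m=5.0):
    """Per 5-m stratum of trip mean bottom depth: total wiggles across trips.

    Supports season comparisons of where in the water column capture effort
    concentrates. Returns (stratum_lo, stratum_mid, total_wiggles, n_trips).
    """
    cols = ["stratum_lo_m", "stratum_mid_m", "total_wiggles", "n_trips"]
    if len(trip_metrics_df) == 0:
        return pd.DataFrame(columns=cols)
    df = trip_metrics_df.copy()
    lo = (np.floor(df["mean_bottom_depth_m"].to_numpy() / bin_m) * bin_m)
    df["stratum_lo_m"] = lo
    g = df.groupby("stratum_lo_m", as_index=False).agg(
        total_wiggles=("total_wiggles", "sum"), n_trips=("trip_id", "count"))
    g["stratum_mid_m"] = g["stratum_lo_m"] + bin_m / 2.0
    return g[cols].sort_values("stratum_lo_m", ignore_index=True)
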