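"""Dive detection, phase segmentation, wiggle counting and trip aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pengkrill import dives, synthetic as syn


def _series_with_dives(n_dives=12, wiggles=5, gap=400):
    prof = syn.simulate_dive_profile(40.0, 60.0, wiggles, 2.0)
    parts = []
    for _ in range(n_dives):
        parts.append(np.zeros(gap))
        parts.append(prof)
    parts.append(np.zeros(gap))
    return np.concatenate(parts)


class TestZeroOffset:
    def test_constant_offset_removed(self):
        s = _series_with_dives(6)
        c = dives.zero_offset_correct(s + 0.8)
        assert abs(np.median(c[s == 0])) < 0.05

    def test_already_zeroed_unchanged(self):
        s = _series_with_dives(6)
        c = dives.zero_offset_correct(s)
        assert np.abs(c - s).max() <= 0.01

    def test_linear_drift_tracked(self):
        s = _series_with_dives(16)[:7200]  # ~2 h
        drift = np.linspace(0.0, 1.0, len(s))
        c = dives.zero_offset_correct(s + drift)
        assert abs(np.median(c[s == 0])) < 0.1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dives.zero_offset_correct(np.array([]))


class TestDetection:
    def test_shallow_series_has_no_dives(self):
        s = np.concatenate([np.zeros(50), np.full(30, 2.0), np.zeros(50)])
        assert dives.detect_dives(s, threshold_m=3.0) == []

    def test_generated_dive_count_recovered(self):
        s = _series_with_dives(12)
        assert len(dives.detect_dives(s)) == 12

    def test_most_default_scenario_dives_under_two_minutes(self, mini_bundle):
        tdr = next(iter(mini_bundle.tdr_tables.values()))
        c = dives.zero_offset_correct(tdr["depth_m"].to_numpy())
        df = dives.process_depth_series(c)
        assert (df["duration_s"] < 120).mean() > 0.5


class TestPhases:
    def test_v_dive_single_sample_bottom(self):
        s = np.array([0.0, 20.0, 40.0, 20.0, 0.0])
        d = dives.detect_dives(s)[0]
        dives.segment_phases(d, s)
        assert d.bottom_duration_s() == 1.0

    def test_square_dive_bottom_matches_plateau(self):
        s = np.concatenate([[0.0], np.full(60, 40.0), [0.0]])
        d = dives.detect_dives(s)[0]
        dives.segment_phases(d, s)
        assert d.bottom_duration_s() == 60.0

    def test_triangle_dive_bottom_is_80pct_span(self):
        up = np.arange(0.0, 50.0, 2.0)
        s = np.concatenate([up, [50.0], up[::-1]])
        d = dives.detect_dives(s)[0]
        dives.segment_phases(d, s)
        b0, b1 = d.bottom
        assert (s[b0:b1 + 1] >= 40.0).all()
        assert s[b0 - 1] < 40.0 and s[b1 + 1] < 40.0

    def test_short_dive_marked_incomplete(self):
        s = np.array([0.0, 40.0, 40.0, 0.0])[1:3]  # 2-sample dive
        full = np.array([0.0, 40.0, 40.0, 0.0])
        d = dives.detect_dives(full)[0]
        assert d.end_idx - d.start_idx + 1 == 2
        dives.segment_phases(d, full)
        assert d.bottom is None and not d.is_complete

    @given(st.integers(0, 10), st.floats(15.0, 120.0), st.floats(5.0, 90.0))
    def test_phases_partition_every_sample(self, n, depth, bottom_s):
        prof = syn.simulate_dive_profile(depth, bottom_s, n, min(2.0, 0.19 * depth))
        d = dives.detect_dives(prof)[0]
        dives.segment_phases(d, prof)
        spans = [sp for sp in (d.descent, d.bottom, d.ascent) if sp is not None]
        covered = sorted(i for sp in spans for i in range(sp[0], sp[1] + 1))
        assert covered == list(range(d.start_idx, d.end_idx + 1))

    def test_raising_bottom_fraction_never_lengthens_bottom(self):
        prof = syn.simulate_dive_profile(50.0, 40.0, 4, 2.0)
        d = dives.detect_dives(prof)[0]
        lengths = []
        for frac in (0.6, 0.7, 0.8, 0.9):
            dives.segment_phases(d, prof, bottom_fraction=frac)
            lengths.append(d.bottom_duration_s())
        assert lengths == sorted(lengths, reverse=True)


class TestWiggles:
    def test_sawtooth_five_oscillations(self):
        prof = syn.simulate_dive_profile(40.0, 40.0, 5, 2.0)
        d = dives.detect_dives(prof)[0]
        dives.segment_phases(d, prof)
        assert dives.count_wiggles(d, prof, min_amplitude_m=1.0) == 5

    def test_flat_bottom_counts_zero(self):
        prof = syn.simulate_dive_profile(40.0, 40.0, 0, 2.0)
        d = dives.detect_dives(prof)[0]
        dives.segment_phases(d, prof)
        assert dives.count_wiggles(d, prof) == 0

    def test_subthreshold_oscillations_ignored(self):
        prof = syn.simulate_dive_profile(40.0, 40.0, 6, 0.4)
        d = dives.detect_dives(prof)[0]
        dives.segment_phases(d, prof)
        assert dives.count_wiggles(d, prof, min_amplitude_m=1.0) == 0

    @given(st.integers(0, 12), st.floats(1.2, 3.0))
    def test_raising_threshold_never_increases_count(self, n, amp):
        prof = syn.simulate_dive_profile(60.0, 80.0, n, amp)
        d = dives.detect_dives(prof)[0]
        dives.segment_phases(d, prof)
        counts = [dives.count_wiggles(d, prof, min_amplitude_m=a)
                  for a in (0.5, 1.0, amp, amp + 0.1, 5.0)]
        assert counts == sorted(counts, reverse=True)


class TestCompleteness:
    def test_u_dive_complete_v_dive_not(self):
        u = syn.simulate_dive_profile(40.0, 60.0, 0, 2.0)
        v = np.array([0.0, 20.0, 40.0, 20.0, 0.0])
        for s, expect in ((u, True), (v, False)):
            d = dives.detect_dives(s)[0]
            dives.segment_phases(d, s)
            assert dives.classify_complete(d) is expect

    def test_boundary_exactly_five_seconds_is_complete(self):
        s = np.concatenate([[0.0], np.full(5, 40.0), [0.0]])
        d = dives.detect_dives(s)[0]
        dives.segment_phases(d, s)
        assert d.bottom_duration_s() == 5.0
        assert dives.classify_complete(d, min_bottom_s=5.0)


class TestTripAggregation:
    def _dive_df(self):
        return pd.DataFrame({
            "duration_s": [60.0, 80.0, 100.0, 120.0],
            "bottom_mean_m": [40.0, 42.0, 38.0, np.nan],
            "bottom_max_m": [45.0, 44.0, 41.0, np.nan],
            "n_wiggles": [2, 4, 6, 0],
            "complete": [True, True, True, False],
        })

    def test_frequency_and_capture_effort(self):
        m = dives.trip_dive_metrics(self._dive_df(), "t0")
        assert m["freq_complete"] == 0.75
        assert m["mean_capture_effort"] == 4.0

    def test_cumulative_is_exact_sum(self):
        df = self._dive_df()
        m = dives.trip_dive_metrics(df, "t0")
        assert m["cumulative_dive_duration_min"] * 60.0 == df["duration_s"].sum()

    def test_zero_dives_flagged(self):
        m = dives.trip_dive_metrics(self._dive_df().iloc[0:0], "t0")
        assert m["n_dives"] == 0 and np.isnan(m["freq_complete"])

    def test_vertical_effort_single_stratum(self):
        tm = pd.DataFrame({"trip_id": ["a", "b"],
                           "mean_bottom_depth_m": [41.0, 43.5],
                           "total_wiggles": [6, 4]})
        prof = dives.vertical_effort_profile(tm)
        assert len(prof) == 1
        assert prof["stratum_lo_m"].iloc[0] == 40.0
        assert prof["total_wiggles"].iloc[0] == 10

    def test_vertical_effort_empty(self):
        assert len(dives.vertical_effort_profile(pd.DataFrame(
            columns=["trip_id", "mean_bottom_depth_m", "total_wiggles"]))) == 0

    def test_poor_season_effort_shifts_below_60m(self, default_pipeline):
        # when krill sit deep, a clearly larger share of capture effort
        # (wiggles) happens below 60 m — the depth band where the seasons'
        # krill distributions actually separate
        dv = default_pipeline["dives"]
        dv = dv[dv["complete"]].copy()
        dv["season"] = dv["bird_id"].str.split("_").str[0]
        share = {s: sub.loc[sub["bottom_mean_m"] > 60.0, "n_wiggles"].sum()
                    / sub["n_wiggles"].sum()
                 for s, sub in dv.groupby("season")}
        assert share["poor"] > 2.0 * share["good"]
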