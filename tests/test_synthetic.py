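"""Generator behaviour: determinism, sanity ranges, recoverable ground truth."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pengkrill import dives, synthetic as syn, trips
from pengkrill.geo import haversine_km


class TestTrack:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_out_and_back_geometry(self, seed):
        tr = syn.simulate_track(syn.GOOD_SEASON, rng=np.random.default_rng(seed))
        d_km = haversine_km(tr["lon"].to_numpy(), tr["lat"].to_numpy(),
                            *syn.DEFAULT_COLONY)
        assert d_km.max() <= 35.0
        assert d_km[0] * 1000 < 250 and d_km[-1] * 1000 < 250
        assert tr["time"].is_monotonic_increasing

    def test_same_seed_identical(self):
        a = syn.simulate_track(syn.GOOD_SEASON, rng=np.random.default_rng(9))
        b = syn.simulate_track(syn.GOOD_SEASON, rng=np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_trip_rejected_downstream(self):
        tr = syn.simulate_track(syn.GOOD_SEASON, rng=np.random.default_rng(0),
                                duration_h=0.01)
        assert len(tr) == 2
        reg = trips.interpolate_track(tr)
        assert trips.segment_trips(reg, syn.DEFAULT_COLONY) == []

    def test_nonfinite_colony_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_track(syn.GOOD_SEASON, colony=(np.nan, -62.0),
                               rng=np.random.default_rng(0))


class TestDiveProfile:
    def test_constructed_wiggles_are_counted(self):
        prof = syn.simulate_dive_profile(40.0, 60.0, 5, 2.0)
        df = dives.process_depth_series(prof)
        assert len(df) == 1
        assert df["n_wiggles"].iloc[0] == 5
        assert df["complete"].iloc[0]

    def test_flat_bottom_zero_wiggles(self):
        prof = syn.simulate_dive_profile(40.0, 60.0, 0, 2.0)
        df = dives.process_depth_series(prof)
        assert df["n_wiggles"].iloc[0] == 0

    def test_deepest_allowed_dive(self):
        prof = syn.simulate_dive_profile(133.0, 40.0, 3, 2.0)
        assert prof.max() == 133.0
        assert prof[0] == 0.0 and prof[-1] == 0.0

    @pytest.mark.parametrize("bad", [dict(n_wiggles=-1), dict(wiggle_amplitude=0.0),
                                     dict(wiggle_amplitude=-2.0), dict(max_depth=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(max_depth=40.0, bottom_duration_s=30.0, n_wiggles=3,
                  wiggle_amplitude=2.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            syn.simulate_dive_profile(kw["max_depth"], kw["bottom_duration_s"],
                                      kw["n_wiggles"], kw["wiggle_amplitude"])

    @given(st.integers(0, 17), st.floats(18.0, 133.0), st.floats(1.0, 3.0),
           st.floats(10.0, 120.0))
    def test_wiggle_count_recovered_exactly(self, n, depth, amp, bottom):
        amp = min(amp, 0.19 * depth)
        prof = syn.simulate_dive_profile(depth, bottom, n, amp)
        df = dives.process_depth_series(prof, min_amplitude_m=amp - 1e-9)
        assert df["n_wiggles"].iloc[0] == n

    def test_bounce_dive_is_incomplete_with_no_wiggles(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            prof = syn.simulate_bounce_dive(rng)
            df = dives.process_depth_series(prof)
            assert len(df) == 1
            assert not df["complete"].iloc[0]
            assert df["n_wiggles"].iloc[0] == 0


class TestKrillField:
    def test_same_seed_identical(self):
        a = syn.simulate_krill_field(syn.GOOD_SEASON, rng=np.random.default_rng(5))
        b = syn.simulate_krill_field(syn.GOOD_SEASON, rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_biomass_gives_empty_table(self):
        sc = dataclasses.replace(syn.GOOD_SEASON, krill_biomass_scale=0.0)
        out = syn.simulate_krill_field(sc, rng=np.random.default_rng(0))
        assert len(out) == 0
        assert list(out.columns) == ["distance_nmi", "depth_m", "density"]

    def test_poor_season_samples_sit_deeper(self):
        # density-weighted mean depth contrast across replicates
        wg, wp = [], []
        for s in range(20):
            g = syn.simulate_krill_field(syn.GOOD_SEASON, rng=np.random.default_rng(s))
            p = syn.simulate_krill_field(syn.POOR_SEASON, rng=np.random.default_rng(1000 + s))
            wg.append(np.average(g["depth_m"], weights=g["density"]))
            wp.append(np.average(p["depth_m"], weights=p["density"]))
        assert np.mean(wg) + 20.0 < np.mean(wp)

    def test_depth_mode_recovered_from_large_sample(self):
        sc = dataclasses.replace(syn.GOOD_SEASON, cluster_parent_intensity=0.6)
        kf = syn.simulate_krill_field(sc, rng=np.random.default_rng(3))
        assert len(kf) >= 10_000
        wmean = np.average(kf["depth_m"], weights=kf["density"])
        assert abs(wmean - sc.krill_depth_mode) <= 5.0


class TestBundle:
    def test_identical_names_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_bundle(syn.GOOD_SEASON,
                                dataclasses.replace(syn.POOR_SEASON, name="good"))

    def test_no_birds_still_produces_env_grids(self):
        sc = dataclasses.replace(syn.GOOD_SEASON, n_birds=0, seed=3)
        b = syn.simulate_season(sc)
        assert b.gps_tables == {} and b.tdr_tables == {}
        assert len(b.env_grids) == 3 * 3 + 4  # CHL/PAR/SWS x 3 months + SIC x 4
        assert len(b.breeding) == 12

    def test_configured_breeding_contrast_near_1_4(self):
        assert abs(syn.expected_breeding_ratio() - 1.4) < 0.05

    def test_tdr_cadence_is_one_second(self, mini_bundle):
        tdr = next(iter(mini_bundle.tdr_tables.values()))
        dt = tdr["time"].diff().dropna().dt.total_seconds().unique()
        assert list(dt) == [1.0]

    def test_truth_wiggles_within_sanity_range(self, mini_bundle):
        d = mini_bundle.truth["dives"]
        assert d["n_wiggles"].between(0, 17).all()
        assert d.loc[d["complete"], "n_wiggles"].between(2, 17).all()
        assert (d["max_depth"] <= 133.0).all()

    def test_csv_outputs_byte_identical_across_runs(self, mini_scenario, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        syn.write_bundle(syn.simulate_season(mini_scenario), d1)
        syn.write_bundle(syn.simulate_season(mini_scenario), d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        for name in names:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
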