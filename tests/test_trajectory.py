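"""Trajectory unit tests: distances, roosts, migration rules, seasons."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ciconia.accel import InputError
from ciconia.trajectory import (
    EARTH_RADIUS_KM,
    ConsistencyError,
    Geography,
    MigrationWindows,
    clean_track,
    classify_strategy,
    daily_roosts,
    detect_migration_windows,
    haversine_km,
    nest_occupation_date,
    partition_seasons,
    total_displacement,
)


def fix_frame(rows):
    """rows: (individual, iso_ts, lon, lat)."""
    df = pd.DataFrame(rows, columns=["individual", "timestamp", "lon", "lat"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km((-8.0, 38.8), (-8.0, 38.8)) == 0.0

    def test_antipodal_half_circumference(self):
        assert haversine_km((0.0, 0.0), (180.0, 0.0)) == pytest.approx(
            np.pi * EARTH_RADIUS_KM, rel=1e-12
        )

    def test_one_degree_at_equator(self):
        # closed form: (pi/180) * R
        assert haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(
            np.pi / 180 * EARTH_RADIUS_KM, rel=1e-9
        )
        assert haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(111.195, abs=0.001)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = (float(rng.uniform(-180, 180)), float(rng.uniform(-90, 90)))
        b = (float(rng.uniform(-180, 180)), float(rng.uniform(-90, 90)))
        assert haversine_km(a, b) >= 0.0
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a), abs=1e-9)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(InputError):
            haversine_km((0.0, 95.0), (0.0, 0.0))


class TestCleanTrack:
    def test_clean_track_unchanged(self):
        df = fix_frame(
            [("a", f"2019-01-01T{h:02d}:00:00Z", -8.0 + 0.001 * h, 38.8) for h in range(10)]
        )
        out = clean_track(df)
        assert len(out) == len(df)

    def test_teleport_fix_removed(self):
        rows = [("a", f"2019-01-01T{h:02d}:00:00Z", -8.0, 38.8) for h in range(6)]
        rows[3] = ("a", "2019-01-01T03:00:00Z", 2.0, 48.0)  # ~1300 km in 1 h
        out = clean_track(fix_frame(rows))
        assert len(out) == 5
        assert not ((out["lat"] > 40).any())

    def test_duplicate_timestamp_keeps_first(self):
        rows = [
            ("a", "2019-01-01T00:00:00Z", -8.0, 38.8),
            ("a", "2019-01-01T00:00:00Z", -8.1, 38.9),
            ("a", "2019-01-01T01:00:00Z", -8.0, 38.8),
        ]
        out = clean_track(fix_frame(rows))
        assert len(out) == 2
        assert out.iloc[0]["lon"] == -8.0


class TestDisplacement:
    def test_stationary_track_zero(self):
        df = fix_frame([("a", f"2019-01-01T{h:02d}:00:00Z", -8.0, 38.8) for h in range(5)])
        assert total_displacement(df) == 0.0

    def test_collinear_equatorial_fixes(self):
        df = fix_frame(
            [
                ("a", "2019-01-01T00:00:00Z", 0.0, 0.0),
                ("a", "2019-01-01T06:00:00Z", 1.0, 0.0),
                ("a", "2019-01-01T12:00:00Z", 2.0, 0.0),
            ]
        )
        assert total_displacement(df) == pytest.approx(2 * np.pi / 180 * EARTH_RADIUS_KM, rel=1e-9)
        assert total_displacement(df) == pytest.approx(222.39, abs=0.01)

    def test_concatenation_additivity(self):
        a = fix_frame(
            [
                ("a", "2019-01-01T00:00:00Z", 0.0, 0.0),
                ("a", "2019-01-01T06:00:00Z", 1.0, 0.5),
            ]
        )
        b = fix_frame(
            [
                ("a", "2019-01-02T00:00:00Z", 2.0, 1.0),
                ("a", "2019-01-02T06:00:00Z", 3.0, 0.0),
            ]
        )
        link = haversine_km((1.0, 0.5), (2.0, 1.0))
        whole = total_displacement(pd.concat([a, b], ignore_index=True))
        assert whole == pytest.approx(total_displacement(a) + total_displacement(b) + link)

    @given(st.integers(0, 2**31 - 1))
    def test_at_least_straight_line_and_subset_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        df = fix_frame(
            [
                ("a", (datetime(2019, 1, 1, tzinfo=timezone.utc) + timedelta(hours=h)).isoformat(),
                 float(rng.uniform(-10, 10)), float(rng.uniform(30, 45)))
                for h in range(n)
            ]
        )
        total = total_displacement(df)
        first, last = df.iloc[0], df.iloc[-1]
        straight = haversine_km((first["lon"], first["lat"]), (last["lon"], last["lat"]))
        assert total >= straight - 1e-9
        # removing interior fixes never increases the sum (triangle inequality)
        thinned = df.iloc[[0, len(df) - 1]]
        assert total_displacement(thinned) <= total + 1e-9

    def test_single_fix_returns_zero(self):
        df = fix_frame([("a", "2019-01-01T00:00:00Z", 0.0, 0.0)])
        assert total_displacement(df) == 0.0


class TestRoosts:
    def test_stationary_bird_roost_is_that_point(self):
        rows = [
            ("a", f"2019-03-01T{h:02d}:30:00Z", -8.0, 38.8)
            for h in (22, 23)
        ] + [("a", f"2019-03-02T{h:02d}:30:00Z", -8.0, 38.8) for h in (0, 1, 2)]
        roosts = daily_roosts(fix_frame(rows))
        assert len(roosts) == 1
        assert roosts.iloc[0]["date"] == date(2019, 3, 1)
        assert roosts.iloc[0]["lon"] == pytest.approx(-8.0)

    def test_single_nocturnal_fix_is_the_roost(self):
        roosts = daily_roosts(fix_frame([("a", "2019-03-01T23:00:00Z", -8.0, 38.8)]))
        assert len(roosts) == 1
        assert roosts.iloc[0]["lat"] == pytest.approx(38.8)

    def test_daytime_fixes_are_ignored(self):
        roosts = daily_roosts(fix_frame([("a", "2019-03-01T12:00:00Z", -8.0, 38.8)]))
        assert len(roosts) == 0

    def test_post_midnight_fix_assigned_to_evening_date(self):
        roosts = daily_roosts(fix_frame([("a", "2019-03-02T02:00:00Z", -8.0, 38.8)]))
        assert roosts.iloc[0]["date"] == date(2019, 3, 1)


def roost_frame(latlons, start=date(2019, 8, 10)):
    return pd.DataFrame(
        {
            "individual": "a",
            "date": [start + timedelta(days=i) for i in range(len(latlons))],
            "lon": [p[0] for p in latlons],
            "lat": [p[1] for p in latlons],
        }
    )


class TestMigrationWindows:
    def test_resident_returns_none(self):
        roosts = roost_frame([(-8.0, 38.8)] * 30)
        assert detect_migration_windows(roosts) is None

    def test_two_big_days_is_not_migration(self):
        # 1 deg lat ~ 111 km > 60 km threshold, but only 2 consecutive days
        lats = [38.8] * 5 + [37.8, 36.8] + [36.8] * 5
        roosts = roost_frame([(-8.0, lat) for lat in lats])
        assert detect_migration_windows(roosts) is None

    def test_three_day_run_detected_with_correct_dates(self):
        lats = [38.8] * 5 + [37.7, 36.6, 35.5] + [35.5] * 10
        roosts = roost_frame([(-8.0, lat) for lat in lats])
        w = detect_migration_windows(roosts)
        assert w is not None and w.autumn is not None
        assert w.autumn == (date(2019, 8, 15), date(2019, 8, 17))
        assert w.spring is None

    def test_gap_in_dates_breaks_run(self):
        lats = [38.8] * 5 + [37.7, 36.6, 35.5]
        roosts = roost_frame([(-8.0, lat) for lat in lats])
        roosts = roosts.drop(index=6)  # remove the middle travel day
        assert detect_migration_windows(roosts) is None

    def test_outbound_and_return_runs_split_into_seasons(self):
        south = [38.8 - i for i in range(5)]  # 4 move-days out
        north = [34.8 + i for i in range(5)]  # 4 move-days back
        lats = [38.8] * 3 + south + [34.8] * 20 + north + [38.8] * 3
        roosts = roost_frame([(-8.0, lat) for lat in lats])
        w = detect_migration_windows(roosts)
        assert w.autumn is not None and w.spring is not None
        assert w.autumn[1] < w.spring[0]


class TestClassifyStrategy:
    def _track(self, roost_lats_lons, start=date(2019, 8, 10)):
        rows = []
        for i, (lon, lat) in enumerate(roost_lats_lons):
            d = start + timedelta(days=i)
            rows.append(("a", f"{d}T23:30:00Z", lon, lat))
        return fix_frame(rows)

    def test_all_near_nest_is_local(self):
        track = self._track([(-8.0, 38.8)] * 40)
        assert classify_strategy(track, (-8.0, 38.8)) == "local"

    def test_far_but_north_of_gibraltar_is_regional(self):
        points = [(-8.0, 38.8)] * 20 + [(-5.0, 40.0)] * 20  # ~290 km away
        assert classify_strategy(self._track(points), (-8.0, 38.8)) == "regional"

    def test_south_of_gibraltar_wintering_north_of_sahara_is_nw_africa(self):
        lats = [38.8] * 5 + [37.0, 35.5, 34.0] + [33.0] * 60 + [34.5, 36.0, 37.5] + [38.8] * 5
        points = [(-7.0, lat) for lat in lats]
        assert classify_strategy(self._track(points), (-8.0, 38.8)) == "nw_africa"

    def test_wintering_south_of_sahara_is_sub_saharan(self):
        south = list(np.linspace(38.8, 15.0, 13))
        north = list(np.linspace(15.0, 38.8, 13))
        lats = [38.8] * 5 + south + [15.0] * 60 + north + [38.8] * 5
        points = [(-9.0, lat) for lat in lats]
        assert classify_strategy(self._track(points), (-8.0, 38.8)) == "sub_saharan"

    def test_missing_nest_rejected(self):
        with pytest.raises(InputError):
            classify_strategy(self._track([(-8.0, 38.8)] * 5), None)


class TestSeasonPartition:
    def test_resident_printed_dates(self):
        part = partition_seasons("regional", None, 2018)
        assert part.segments["autumn"] == [(date(2018, 8, 4), date(2018, 9, 5))]
        assert part.segments["wintering"] == [(date(2018, 9, 6), date(2018, 12, 12))]
        assert part.segments["spring"] == [(date(2018, 12, 13), date(2019, 1, 22))]
        assert part.segments["breeding"] == [(date(2019, 1, 23), date(2019, 8, 3))]

    @pytest.mark.parametrize("strategy", ["local", "regional"])
    def test_resident_partition_tiles_cycle(self, strategy):
        part = partition_seasons(strategy, None, 2019)
        part.validate()  # raises on overlap or gap

    def test_migrant_partition_from_windows(self):
        w = MigrationWindows(
            autumn=(date(2018, 8, 20), date(2018, 9, 2)),
            spring=(date(2019, 1, 5), date(2019, 1, 18)),
        )
        part = partition_seasons("sub_saharan", w, 2018)
        part.validate()
        assert part.segments["autumn"] == [(date(2018, 8, 20), date(2018, 9, 2))]
        assert part.segments["wintering"] == [(date(2018, 9, 3), date(2019, 1, 4))]
        # breeding wraps around the 4 Aug anchor
        assert part.segments["breeding"][0] == (date(2018, 8, 4), date(2018, 8, 19))
        assert part.segments["breeding"][1] == (date(2019, 1, 19), date(2019, 8, 3))
        assert part.season_of(date(2018, 12, 25)) == "wintering"

    def test_out_of_order_windows_rejected(self):
        w = MigrationWindows(
            autumn=(date(2019, 1, 5), date(2019, 1, 18)),
            spring=(date(2018, 8, 20), date(2018, 9, 2)),
        )
        with pytest.raises(ConsistencyError):
            partition_seasons("sub_saharan", w, 2018)

    def test_migrant_without_windows_rejected(self):
        with pytest.raises(ConsistencyError):
            partition_seasons(
                "sub_saharan",
                MigrationWindows(autumn=None, spring=None),
                2018,
            )


class TestNestOccupation:
    def _nest_track(self, visit_days, nest=(-8.0, 38.8)):
        rows = []
        for d in visit_days:
            rows.append(("a", f"{d}T10:00:00Z", nest[0], nest[1]))
        # away fix each day so the track is not empty elsewhere
        return fix_frame(rows)

    def test_present_from_day_one(self):
        days = [date(2019, 1, 10) + timedelta(days=i) for i in range(5)]
        got = nest_occupation_date(self._nest_track(days), (-8.0, 38.8))
        assert got == date(2019, 1, 10)

    def test_nonconsecutive_visits_do_not_qualify(self):
        days = [date(2019, 1, 10), date(2019, 1, 12), date(2019, 1, 14)]
        assert nest_occupation_date(self._nest_track(days), (-8.0, 38.8)) is None

    def test_visit_outside_radius_does_not_count(self):
        days = [date(2019, 1, 10) + timedelta(days=i) for i in range(3)]
        track = self._nest_track(days, nest=(-8.0, 38.8))
        # nest 200 m away from every fix; default radius is 75 m
        assert nest_occupation_date(track, (-8.0, 38.8018)) is None

    def test_later_run_found_after_failed_early_visits(self):
        days = [date(2019, 1, 1), date(2019, 1, 2)] + [
            date(2019, 2, 1) + timedelta(days=i) for i in range(4)
        ]
        got = nest_occupation_date(self._nest_track(days), (-8.0, 38.8))
        assert got == date(2019, 2, 1)
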