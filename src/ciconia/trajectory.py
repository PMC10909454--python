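"""GPS trajectory analysis: displacement, roosts, migration phenology.

The annual movement record of each bird is reduced to a daily roost series
(median nocturnal position), from which migration is detected with a
rule-based criterion: a migration bout is a run of at least three
consecutive calendar days each with a roost-to-roost displacement above
60 km.  Birds are classified into four strategies by their wintering
grounds:

* ``local`` — resident, every roost within 50 km of the nest;
* ``regional`` — resident, ranging beyond 50 km but never crossing the
  Strait of Gibraltar;
* ``nw_africa`` — migrant wintering between the Gibraltar and Sahara
  latitude lines;
* ``sub_saharan`` — migrant wintering south of the Sahara, in the Sahel.

Geography is abstracted to two configurable latitude lines (Gibraltar,
default 35.9° N; Sahara, default 20.0° N) plus the nest point: at the
scale of these rules, coastline polygons add nothing.

Each annual cycle (anchored 4 August – 3 August) is partitioned into four
seasons.  For migrants the autumn and spring seasons are the detected
migration windows; for residents fixed calendar dates are used (the
population-median dates of the migrants): autumn 4 Aug – 5 Sep, wintering
6 Sep – 12 Dec, spring 13 Dec – 22 Jan, breeding 23 Jan – 3 Aug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .accel import BEHAVIORS, InputError, behavioral_budget

__all__ = [
    "EARTH_RADIUS_KM",
    "STRATEGIES",
    "RESIDENT_STRATEGIES",
    "MIGRANT_STRATEGIES",
    "Geography",
    "MigrationWindows",
    "SeasonPartition",
    "BreedingRecord",
    "haversine_km",
    "clean_track",
    "total_displacement",
    "local_solar_time",
    "daily_roosts",
    "detect_migration_windows",
    "classify_strategy",
    "is_migrant",
    "partition_seasons",
    "nest_occupation_date",
    "seasonal_summary",
]

EARTH_RADIUS_KM = 6371.0088

STRATEGIES: tuple[str, ...] = ("local", "regional", "nw_africa", "sub_saharan")
RESIDENT_STRATEGIES = frozenset({"local", "regional"})
MIGRANT_STRATEGIES = frozenset({"nw_africa", "sub_saharan"})

SEASONS: tuple[str, ...] = ("autumn", "wintering", "spring", "breeding")

#: Columns a fix table must carry.
FIX_COLUMNS = ("individual", "timestamp", "lon", "lat")


class ConsistencyError(ValueError):
    """Raised when derived quantities contradict each other."""


@dataclass
class Geography:
    """Thresholds and latitude lines for the classification rules."""

    gibraltar_lat: float = 35.9  # deg N; any roost south of it => migrant
    sahara_lat: float = 20.0  # deg N; wintering centroid south => sub-Saharan
    local_radius_km: float = 50.0  # resident local/regional split
    migration_daily_km: float = 60.0  # roost-to-roost displacement threshold
    migration_run_days: int = 3  # consecutive days required
    nest_radius_m: float = 75.0  # nest-visit radius
    speed_cap_kmh: float = 120.0  # outlier speed filter


def is_migrant(strategy: str) -> bool:
    if strategy not in STRATEGIES:
        raise InputError(f"unknown strategy {strategy!r}")
    return strategy in MIGRANT_STRATEGIES


def haversine_km(a: Sequence[float], b: Sequence[float]) -> float:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1 = float(a[0]), float(a[1])
    lon2, lat2 = float(b[0]), float(b[1])
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            raise InputError(f"invalid coordinates lon={lon}, lat={lat}")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def _haversine_vec(lon1, lat1, lon2, lat2) -> np.ndarray:
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def clean_track(fixes: pd.DataFrame, speed_cap_kmh: float = 120.0) -> pd.DataFrame:
    """Remove duplicate timestamps and speed-implausible outlier fixes.

    Duplicated timestamps keep the first record.  A forward pass then drops
    any fix implying a sustained speed above ``speed_cap_kmh`` from the
    last retained fix.  Deterministic; an empty result is allowed.
    """
    out = []
    for _, track in fixes.groupby("individual", sort=False):
        track = track.sort_values("timestamp")
        track = track[~track["timestamp"].duplicated(keep="first")]
        if len(track) <= 1:
            out.append(track)
            continue
        # fast path: no consecutive-pair speed violation means nothing to drop
        lon_a = track["lon"].to_numpy()
        lat_a = track["lat"].to_numpy()
        dt_h = np.diff(track["timestamp"].to_numpy()) / np.timedelta64(1, "h")
        step = _haversine_vec(lon_a[:-1], lat_a[:-1], lon_a[1:], lat_a[1:])
        if not (step / np.maximum(dt_h, 1e-12) > speed_cap_kmh).any():
            out.append(track)
            continue
        lon = track["lon"].to_numpy()
        lat = track["lat"].to_numpy()
        t = track["timestamp"].to_numpy()
        keep = [0]
        for i in range(1, len(track)):
            j = keep[-1]
            dt_h = (t[i] - t[j]) / np.timedelta64(1, "h")
            if dt_h <= 0:
                continue
            dist = haversine_km((lon[j], lat[j]), (lon[i], lat[i]))
            if dist / dt_h <= speed_cap_kmh:
                keep.append(i)
        out.append(track.iloc[keep])
    if not out:
        return fixes.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def total_displacement(fixes: pd.DataFrame) -> float:
    """Sum of great-circle distances between consecutive fixes, in km.

    This is the cumulative distance moved (e.g. over a year or a season).
    Returns 0 with fewer than 2 fixes.
    """
    if len(fixes) < 2:
        return 0.0
    track = fixes.sort_values("timestamp")
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    return float(_haversine_vec(lon[:-1], lat[:-1], lon[1:], lat[1:]).sum())


def local_solar_time(timestamps: pd.Series, lon: pd.Series) -> pd.Series:
    """UTC timestamps shifted by longitude/15 hours (local solar time)."""
    offset = pd.to_timedelta(np.asarray(lon, dtype=float) / 15.0, unit="h")
    return pd.to_datetime(timestamps).dt.tz_localize(None) + offset


def daily_roosts(fixes: pd.DataFrame) -> pd.DataFrame:
    """One roost per individual per night: the median nocturnal position.

    The nocturnal window is 22:00-04:00 local solar time (longitude / 15 h
    offset from UTC); the night is assigned to the evening's calendar
    date.  Dates without nocturnal fixes are skipped.  Returns a frame
    with columns individual, date, lon, lat.
    """
    if len(fixes) == 0:
        return pd.DataFrame(columns=["individual", "date", "lon", "lat"])
    solar = local_solar_time(fixes["timestamp"], fixes["lon"])
    hour = solar.dt.hour + solar.dt.minute / 60.0
    nocturnal = (hour >= 22.0) | (hour < 4.0)
    night = fixes[nocturnal].copy()
    if len(night) == 0:
        return pd.DataFrame(columns=["individual", "date", "lon", "lat"])
    solar_n = solar[nocturnal]
    evening = solar_n.dt.date.where(solar_n.dt.hour >= 22, solar_n.dt.date - timedelta(days=1))
    night["date"] = evening
    roosts = (
        night.groupby(["individual", "date"], sort=True)[["lon", "lat"]]
        .median()
        .reset_index()
    )
    return roosts


@dataclass
class MigrationWindows:
    """Detected autumn (outbound) and spring (return) migration windows."""

    autumn: Optional[tuple[date, date]]
    spring: Optional[tuple[date, date]]


def _movement_runs(roosts: pd.DataFrame, geo: Geography) -> list[tuple[date, date, float]]:
    """Maximal runs of consecutive calendar days each moving > threshold.

    Returns (start_date, end_date, net_distance_change) per qualifying run,
    where the net change is measured from the series' first roost (positive
    = the run carries the bird away from home).  A missing roost date
    breaks a run: consecutive means calendar-date consecutive.
    """
    r = roosts.sort_values("date").reset_index(drop=True)
    if len(r) < 2:
        return []
    dates = r["date"].to_numpy()
    lon = r["lon"].to_numpy()
    lat = r["lat"].to_numpy()
    origin = (lon[0], lat[0])
    # movement day i (i >= 1): displacement from the previous calendar day
    consecutive = np.array(
        [(dates[i] - dates[i - 1]) == timedelta(days=1) for i in range(1, len(r))]
    )
    step = _haversine_vec(lon[:-1], lat[:-1], lon[1:], lat[1:])
    moving = consecutive & (step > geo.migration_daily_km)

    runs: list[tuple[date, date, float]] = []
    i = 0
    while i < len(moving):
        if not moving[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(moving) and moving[j + 1] and consecutive[j + 1]:
            j += 1
        length = j - i + 1
        if length >= geo.migration_run_days:
            d_start = haversine_km(origin, (lon[i], lat[i]))
            d_end = haversine_km(origin, (lon[j + 1], lat[j + 1]))
            runs.append((dates[i + 1], dates[j + 1], d_end - d_start))
        i = j + 1
    return runs


def detect_migration_windows(
    roosts: pd.DataFrame, geo: Geography | None = None
) -> Optional[MigrationWindows]:
    """Detect autumn and spring migration windows from a roost series.

    A migration bout is a run of >= 3 consecutive calendar days each with a
    roost-to-roost displacement > 60 km.  Outbound runs (net displacement
    away from the first roost of the series, i.e. the breeding grounds)
    form the autumn window — first day of the first such run to last day of
    the last one; return runs form the spring window analogously.  Returns
    None when no qualifying run exists (residents).
    """
    geo = geo or Geography()
    runs = _movement_runs(roosts, geo)
    if not runs:
        return None
    outbound = [r for r in runs if r[2] > 0]
    inbound = [r for r in runs if r[2] <= 0]
    autumn = (outbound[0][0], outbound[-1][1]) if outbound else None
    spring = (inbound[0][0], inbound[-1][1]) if inbound else None
    return MigrationWindows(autumn=autumn, spring=spring)


def classify_strategy(
    fixes: pd.DataFrame,
    nest: tuple[float, float],
    geo: Geography | None = None,
) -> str:
    """Four-way migratory strategy of one annual track.

    Migrant iff any roost lies south of the Gibraltar line; among
    migrants, sub-Saharan iff the wintering-period roost centroid lies
    south of the Sahara line, else Northwest African.  Among residents,
    local iff every roost is within 50 km of the nest, else regional.
    """
    if nest is None:
        raise InputError("nest location is required to classify a track")
    geo = geo or Geography()
    roosts = daily_roosts(fixes)
    if len(roosts) == 0:
        raise InputError("no roosts could be derived from the track")
    south = roosts[roosts["lat"] < geo.gibraltar_lat]
    if len(south) == 0:
        dist = _haversine_vec(
            np.full(len(roosts), nest[0]),
            np.full(len(roosts), nest[1]),
            roosts["lon"].to_numpy(),
            roosts["lat"].to_numpy(),
        )
        return "local" if float(dist.max()) < geo.local_radius_km else "regional"
    windows = detect_migration_windows(roosts, geo)
    if windows is not None and windows.autumn and windows.spring:
        start, end = windows.autumn[1], windows.spring[0]
        wintering = roosts[
            (roosts["date"] > start) & (roosts["date"] < end)
        ]
    else:
        wintering = south
    if len(wintering) == 0:
        wintering = south
    centroid_lat = float(wintering["lat"].mean())
    return "sub_saharan" if centroid_lat < geo.sahara_lat else "nw_africa"


#: Fixed season boundaries for residents (month, day), closed intervals.
RESIDENT_SEASON_DATES = {
    "autumn": ((8, 4), (9, 5)),
    "wintering": ((9, 6), (12, 12)),
    "spring": ((12, 13), (1, 22)),
    "breeding": ((1, 23), (8, 3)),
}


@dataclass
class SeasonPartition:
    """Partition of one annual cycle (4 Aug year – 3 Aug year+1).

    Each season maps to a list of closed date intervals; breeding may have
    two segments for migrants because the cycle anchor (4 Aug) can fall
    inside the pre-departure breeding residence.  The segments tile the
    cycle with no overlap.
    """

    individual: str
    year: int
    segments: dict[str, list[tuple[date, date]]] = field(default_factory=dict)

    @property
    def cycle(self) -> tuple[date, date]:
        return date(self.year, 8, 4), date(self.year + 1, 8, 3)

    def season_of(self, d: date) -> Optional[str]:
        for season, intervals in self.segments.items():
            for start, end in intervals:
                if start <= d <= end:
                    return season
        return None

    def validate(self) -> None:
        start, end = self.cycle
        n_days = (end - start).days + 1
        seen: set[date] = set()
        for intervals in self.segments.values():
            for s, e in intervals:
                d = s
                while d <= e:
                    if d in seen:
                        raise ConsistencyError(f"date {d} covered twice")
                    seen.add(d)
                    d += timedelta(days=1)
        if len(seen) != n_days or min(seen) != start or max(seen) != end:
            raise ConsistencyError("season segments do not tile the annual cycle")


def partition_seasons(
    strategy: str,
    windows: Optional[MigrationWindows],
    year: int,
    individual: str = "",
) -> SeasonPartition:
    """Season partition of one annual cycle.

    Residents use the fixed calendar dates; migrants use their detected
    migration windows: autumn = outbound window, wintering = between the
    windows, spring = return window, breeding = the remainder of the cycle
    (which may wrap around the 4 Aug anchor).
    """
    cycle_start, cycle_end = date(year, 8, 4), date(year + 1, 8, 3)
    if strategy in RESIDENT_STRATEGIES or windows is None:
        segs: dict[str, list[tuple[date, date]]] = {}
        for season, ((m1, d1), (m2, d2)) in RESIDENT_SEASON_DATES.items():
            y1 = year if (m1, d1) >= (8, 4) else year + 1
            start = date(y1, m1, d1)
            y2 = year if (m2, d2) >= (8, 4) else year + 1
            end = date(y2, m2, d2)
            segs[season] = [(start, end)]
        part = SeasonPartition(individual=individual, year=year, segments=segs)
        part.validate()
        return part

    if windows.autumn is None or windows.spring is None:
        raise ConsistencyError(
            f"migrant {strategy!r} needs both detected migration windows"
        )
    a0, a1 = windows.autumn
    s0, s1 = windows.spring
    if not (cycle_start <= a0 <= a1 < s0 <= s1 <= cycle_end):
        raise ConsistencyError(
            f"windows {windows} are out of order or outside cycle {year}"
        )
    segs = {
        "autumn": [(a0, a1)],
        "wintering": [(a1 + timedelta(days=1), s0 - timedelta(days=1))],
        "spring": [(s0, s1)],
        "breeding": [],
    }
    if s1 < cycle_end:
        segs["breeding"].append((s1 + timedelta(days=1), cycle_end))
    if a0 > cycle_start:
        segs["breeding"].insert(0, (cycle_start, a0 - timedelta(days=1)))
    part = SeasonPartition(individual=individual, year=year, segments=segs)
    part.validate()
    return part


@dataclass
class BreedingRecord:
    """Nest phenology for one individual-year.

    Laying date and fledgling count are field observations supplied as
    inputs; only the occupation date is derived from GPS.
    """

    individual: str
    year: int
    nest: tuple[float, float]
    occupation_date: Optional[date]
    laying_date: Optional[date] = None
    fledglings: Optional[int] = None

    def __post_init__(self) -> None:
        if (
            self.occupation_date is not None
            and self.laying_date is not None
            and self.occupation_date > self.laying_date
        ):
            raise ConsistencyError("occupation date after laying date")
        if self.fledglings is not None and (
            self.fledglings < 0 or self.fledglings != int(self.fledglings)
        ):
            raise ConsistencyError("fledglings must be a non-negative integer")


def nest_occupation_date(
    fixes: pd.DataFrame,
    nest: tuple[float, float],
    radius_m: float = 75.0,
) -> Optional[date]:
    """First day of the first run of 3 consecutive days with a nest visit.

    A visit is any fix within ``radius_m`` of the nest; days are local
    solar calendar days.  Returns None when no qualifying run exists.
    """
    if nest is None:
        raise InputError("nest location is required")
    if len(fixes) == 0:
        return None
    dist_km = _haversine_vec(
        np.full(len(fixes), nest[0]),
        np.full(len(fixes), nest[1]),
        fixes["lon"].to_numpy(),
        fixes["lat"].to_numpy(),
    )
    at_nest = dist_km <= radius_m / 1000.0
    if not at_nest.any():
        return None
    solar = local_solar_time(fixes["timestamp"], fixes["lon"])
    visit_days = sorted(set(solar[at_nest].dt.date))
    one = timedelta(days=1)
    days = set(visit_days)
    for d in visit_days:
        if d + one in days and d + 2 * one in days:
            return d
    return None


def infer_nest(roosts: pd.DataFrame, months: tuple[int, ...] = (3, 4, 5, 6)) -> tuple[float, float]:
    """Nest location as the median roost during the core breeding months.

    By the spring months every strategy class is back on the breeding
    grounds, so the median roost position is a robust nest proxy when no
    field-observed nest coordinate is available.
    """
    sel = roosts[[d.month in months for d in roosts["date"]]]
    if len(sel) == 0:
        sel = roosts
    if len(sel) == 0:
        raise InputError("cannot infer a nest from an empty roost series")
    return float(sel["lon"].median()), float(sel["lat"].median())


def seasonal_summary(
    fixes: pd.DataFrame,
    bursts: pd.DataFrame,
    partitions: Mapping[str, SeasonPartition],
    strategies: Mapping[str, str],
) -> pd.DataFrame:
    """Model-ready seasonal table: one row per individual x season.

    ``bursts`` must carry columns individual, timestamp, odba_g, behavior
    (and optionally tag_type).  Each row reports seasonal displacement,
    fix and burst counts, season duration, overall and per-behavior mean
    ODBA, behavior proportions (per-day averaged), strategy and tag type.
    Missing seasons are omitted.
    """
    rows = []
    fixes = fixes.copy()
    fixes["date"] = pd.to_datetime(fixes["timestamp"]).dt.date
    bursts = bursts.copy()
    bursts["date"] = pd.to_datetime(bursts["timestamp"]).dt.date
    for individual, part in partitions.items():
        ind_fixes = fixes[fixes["individual"] == individual]
        ind_bursts = bursts[bursts["individual"] == individual]
        tag_type = (
            ind_bursts["tag_type"].iloc[0]
            if "tag_type" in ind_bursts.columns and len(ind_bursts)
            else "default"
        )
        for season in SEASONS:
            intervals = part.segments.get(season, [])
            if not intervals:
                continue
            in_season_f = np.zeros(len(ind_fixes), dtype=bool)
            in_season_b = np.zeros(len(ind_bursts), dtype=bool)
            duration = 0
            for start, end in intervals:
                duration += (end - start).days + 1
                in_season_f |= (ind_fixes["date"] >= start) & (ind_fixes["date"] <= end)
                in_season_b |= (ind_bursts["date"] >= start) & (ind_bursts["date"] <= end)
            sf = ind_fixes[in_season_f]
            sb = ind_bursts[in_season_b]
            if len(sf) == 0 and len(sb) == 0:
                continue
            row = {
                "individual": individual,
                "year": part.year,
                "season": season,
                "strategy": strategies.get(individual),
                "tag_type": tag_type,
                "n_fixes": int(len(sf)),
                "n_bursts": int(len(sb)),
                "duration_days": duration,
                "displacement_km": total_displacement(sf),
                "mean_odba": float(sb["odba_g"].mean()) if len(sb) else np.nan,
            }
            if len(sb):
                budget = behavioral_budget(
                    zip(sb["timestamp"], sb["behavior"]), individual, season
                )
                for b in BEHAVIORS:
                    sel = sb[sb["behavior"] == b]
                    row[f"odba_{b}"] = (
                        float(sel["odba_g"].mean()) if len(sel) else np.nan
                    )
                    row[f"prop_{b}"] = budget.proportions[b]
            rows.append(row)
    return pd.DataFrame(rows)
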