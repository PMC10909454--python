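"""Synthetic field data with the statistical structure the pipeline assumes.

The generator stands in for the tracking dataset: annual GPS tracks for the
four migratory strategies, 9-s tri-axial acceleration bursts with
behavior-specific dynamics, per-individual phenotypes (wing length with a
negative logistic effect on migration probability), and encounter
histories drawn from the exact state/event matrices of the multievent
survival model.  Every simulated object is emitted together with a truth
record so downstream recovery can be tested.

Movement model
--------------
Only roost-scale geometry matters to the classification rules, so tracks
are built from daily roost positions: a breeding phase attracted to the
nest, travel legs of roughly 100-300 km/day during migration, and a
wintering phase attracted to a strategy-specific wintering centroid.
Within-day fixes (every 20 min) interpolate between consecutive roosts
during daytime (08:00-20:00 local solar) with small positional jitter.
Geography is two latitude lines (Gibraltar, Sahara) plus a nest point in
southern Portugal; there are no coastlines, thermals or habitat layers.

Burst model
-----------
A static gravity vector plus a behavior-specific dynamic process:
near-zero noise for resting, irregular mid-amplitude noise for foraging,
a slow smooth drift for soaring, and a strong periodic heave oscillation
(wingbeat, ~3.5 Hz) for flapping.  This is the minimal process separable
by the classification feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .accel import BEHAVIORS, AccelBurst, InputError
from .multievent import (
    EncounterHistory,
    MultieventParams,
    event_matrix,
    transition_matrix,
)
from .trajectory import STRATEGIES, Geography, is_migrant

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_track",
    "simulate_burst",
    "simulate_bursts_for_track",
    "simulate_encounter_histories",
    "simulate_phenotypes",
    "simulate_population",
]

KM_PER_DEG_LAT = 111.195


@dataclass
class SimConfig:
    """Study-design constants and generator noise scales.

    The defaults mirror the tagging program being emulated: GPS fixes and
    acceleration bursts every 20 min, 9-s bursts at 1 Hz, a population
    dominated by regional residents, and larger-winged birds less likely
    to migrate (negative logit slope per mm of wing length).
    """

    n_individuals: int = 40
    strategy_mix: dict[str, float] = field(
        default_factory=lambda: {
            # 67 single-strategy birds in the emulated population:
            # 9 local, 42 regional, 6 NW-Africa, 10 sub-Saharan
            "local": 9 / 67,
            "regional": 42 / 67,
            "nw_africa": 6 / 67,
            "sub_saharan": 10 / 67,
        }
    )
    gps_interval_min: float = 20.0
    burst_rate_hz: float = 1.0
    burst_duration_s: float = 9.0
    # dynamic noise scale per behavior, in g
    burst_noise_g: dict[str, float] = field(
        default_factory=lambda: {
            "foraging": 0.15,
            "resting": 0.01,
            "soaring": 0.02,
            "flapping": 0.05,
        }
    )
    flap_freq_hz: float = 3.5
    flap_freq_sd_hz: float = 0.15
    flap_amplitude_g: float = 0.4
    soar_drift_amplitude_g: float = 0.06
    wing_length_mean_mm: float = 580.0
    wing_length_sd_mm: float = 20.0
    migration_logit_slope_per_mm: float = -0.04  # negative: big birds stay
    migration_logit_intercept: float = -1.29  # ~21% migrants at mean wing
    nest_lon: float = -8.0
    nest_lat: float = 38.8
    geography: Geography = field(default_factory=Geography)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.strategy_mix.values())
        if abs(total - 1.0) > 1e-12:
            raise InputError(f"strategy_mix sums to {total}, expected 1")
        if set(self.strategy_mix) != set(STRATEGIES):
            raise InputError(f"strategy_mix keys must be {STRATEGIES}")
        if self.gps_interval_min <= 0:
            raise InputError("gps_interval must be positive")
        if self.burst_rate_hz <= 0 or self.burst_duration_s <= 0:
            raise InputError("burst rate and duration must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one simulated individual (or burst corpus)."""

    individual: str
    strategy: Optional[str] = None
    nest: Optional[tuple[float, float]] = None
    autumn_window: Optional[tuple[date, date]] = None
    spring_window: Optional[tuple[date, date]] = None
    behavior_per_burst: Optional[list[str]] = None
    states_per_occasion: Optional[list[str]] = None
    wing_length_mm: Optional[float] = None
    migrant: Optional[bool] = None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _offset_km(origin: tuple[float, float], dx_km: float, dy_km: float) -> tuple[float, float]:
    """Move a (lon, lat) point by east/north kilometers (local flat earth)."""
    lon, lat = origin
    return (
        lon + dx_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat))),
        lat + dy_km / KM_PER_DEG_LAT,
    )


def _distance_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    mean_lat = np.radians((a[1] + b[1]) / 2)
    dx = (b[0] - a[0]) * KM_PER_DEG_LAT * np.cos(mean_lat)
    dy = (b[1] - a[1]) * KM_PER_DEG_LAT
    return float(np.hypot(dx, dy))


def _travel_legs(distance_km: float, rng: np.random.Generator, target_leg_km: float) -> np.ndarray:
    """Split a journey into daily legs of comparable length.

    At least 3 legs, each within ~0.8-1.2x the mean leg, so every travel
    day comfortably exceeds the 60-km migration threshold.
    """
    n_legs = max(3, int(np.ceil(distance_km / target_leg_km)))
    weights = rng.uniform(0.8, 1.2, size=n_legs)
    return distance_km * weights / weights.sum()


def _interpolate_path(
    start: tuple[float, float],
    end: tuple[float, float],
    legs: np.ndarray,
) -> list[tuple[float, float]]:
    """Roost positions at the end of each travel day along a straight path."""
    fractions = np.cumsum(legs) / legs.sum()
    return [
        (start[0] + (end[0] - start[0]) * f, start[1] + (end[1] - start[1]) * f)
        for f in fractions
    ]


def _cycle_dates(year: int) -> list[date]:
    start, end = date(year, 8, 4), date(year + 1, 8, 3)
    return [start + timedelta(days=i) for i in range((end - start).days + 1)]


def _winter_center(strategy: str, nest: tuple[float, float], rng: np.random.Generator) -> tuple[float, float]:
    if strategy == "regional":
        while True:
            dx = rng.uniform(-250, 250)
            dy = rng.uniform(-100, 250)  # at most ~100 km south: stays in Iberia
            if 80.0 <= float(np.hypot(dx, dy)) <= 250.0:
                return _offset_km(nest, dx, dy)
    if strategy == "nw_africa":
        return (nest[0] + rng.uniform(-2.0, 2.0), rng.uniform(31.5, 34.5))
    if strategy == "sub_saharan":
        return (nest[0] + rng.uniform(-6.0, 4.0), rng.uniform(13.5, 16.5))
    raise InputError(f"no wintering center for strategy {strategy!r}")


def _roost_series(
    strategy: str,
    year: int,
    nest: tuple[float, float],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[float, float]], Optional[tuple[date, date]], Optional[tuple[date, date]], np.ndarray]:
    """Daily roosts over one annual cycle plus true migration windows.

    Returns (roosts, autumn_window, spring_window, is_travel_day).
    """
    dates = _cycle_dates(year)
    n_days = len(dates)
    day_of = {d: i for i, d in enumerate(dates)}

    def jittered(center: tuple[float, float], sd_km: float) -> tuple[float, float]:
        return _offset_km(center, rng.normal(0, sd_km), rng.normal(0, sd_km))

    roosts: list[tuple[float, float]] = [None] * n_days  # type: ignore[list-item]
    travel = np.zeros(n_days, dtype=bool)

    if strategy == "local":
        # roosts at the nest year-round (~20 m scatter); foraging movement
        # lives in the daytime fixes, not the roosts
        for i in range(n_days):
            roosts[i] = jittered(nest, 0.02)
        return roosts, None, None, travel

    center = _winter_center(strategy, nest, rng)

    if strategy == "regional":
        # sub-threshold legs: a regional bird never triggers the migration rule
        depart = date(year, 8, 20) + timedelta(days=int(rng.integers(0, 40)))
        ret = date(year + 1, 1, 5) + timedelta(days=int(rng.integers(0, 25)))
        dist = _distance_km(nest, center)
        n_legs = max(2, int(np.ceil(dist / 45.0)))
        legs = dist * np.ones(n_legs) / n_legs
        out_path = _interpolate_path(nest, center, legs)
        back_path = _interpolate_path(center, nest, legs)
        t_out, t_back = day_of[depart], day_of[ret]
        for i in range(n_days):
            if i < t_out:
                roosts[i] = jittered(nest, 0.02)
            elif i < t_out + len(out_path):
                roosts[i] = jittered(out_path[i - t_out], 1.0)
            elif i < t_back:
                roosts[i] = jittered(center, 2.0)
            elif i < t_back + len(back_path):
                roosts[i] = jittered(back_path[i - t_back], 1.0)
            else:
                roosts[i] = jittered(nest, 0.02)
        return roosts, None, None, travel

    # long-distance migrants
    target_leg = 150.0 if strategy == "nw_africa" else 200.0
    depart = date(year, 8, 10) + timedelta(days=int(rng.integers(0, 22)))
    ret = date(year, 12, 20) + timedelta(days=int(rng.integers(0, 37)))
    dist = _distance_km(nest, center)
    out_legs = _travel_legs(dist, rng, target_leg)
    back_legs = _travel_legs(dist, rng, target_leg)
    out_path = _interpolate_path(nest, center, out_legs)
    back_path = _interpolate_path(center, nest, back_legs)
    t_out, t_back = day_of[depart], day_of[ret]
    autumn = (dates[t_out], dates[t_out + len(out_path) - 1])
    spring = (dates[t_back], dates[t_back + len(back_path) - 1])
    for i in range(n_days):
        if i < t_out:
            roosts[i] = jittered(nest, 0.02)
        elif i < t_out + len(out_path):
            roosts[i] = out_path[i - t_out]
            travel[i] = True
        elif i < t_back:
            roosts[i] = jittered(center, 2.5)
        elif i < t_back + len(back_path):
            roosts[i] = back_path[i - t_back]
            travel[i] = True
        else:
            roosts[i] = jittered(nest, 0.02)
    return roosts, autumn, spring, travel


def simulate_track(
    strategy: str,
    year: int,
    cfg: SimConfig,
    seed,
    individual: str = "bird-0",
) -> tuple[pd.DataFrame, TruthRecord]:
    """One annual GPS track (fix table) for a given strategy, plus truth.

    The annual cycle runs 4 Aug ``year`` - 3 Aug ``year+1`` with a fix
    every ``cfg.gps_interval_min`` minutes.  Local tracks stay within
    50 km of the nest; regional tracks range beyond 50 km without crossing
    the Gibraltar line; migrants travel in daily legs above the 60-km
    threshold for at least 3 consecutive days per migration.
    """
    if strategy not in STRATEGIES:
        raise InputError(f"unknown strategy {strategy!r}")
    cfg.validate()
    rng = _rng(seed)
    nest = _offset_km(
        (cfg.nest_lon, cfg.nest_lat), rng.uniform(-30, 30), rng.uniform(-30, 30)
    )
    roosts, autumn, spring, _ = _roost_series(strategy, year, nest, cfg, rng)

    n_days = len(_cycle_dates(year))
    per_day = int(round(24 * 60 / cfg.gps_interval_min))
    n_fix = n_days * per_day
    start = datetime(year, 8, 4, tzinfo=timezone.utc)
    minutes = np.arange(n_fix) * cfg.gps_interval_min
    timestamps = pd.to_datetime(start) + pd.to_timedelta(minutes, unit="m")

    # local solar day/hour at the nest longitude; small longitude
    # differences along the route do not move fixes across the day/night
    # position boundaries used below
    offset_min = nest[0] / 15.0 * 60.0
    local_min = minutes + offset_min
    local_day = np.clip(np.floor(local_min / 1440.0).astype(int), 0, n_days - 1)
    local_hour = (local_min % 1440.0) / 60.0

    lons = np.array([r[0] for r in roosts])
    lats = np.array([r[1] for r in roosts])
    prev_day = np.maximum(local_day - 1, 0)
    frac = np.clip((local_hour - 8.0) / 12.0, 0.0, 1.0)
    lon = lons[prev_day] * (1 - frac) + lons[local_day] * frac
    lat = lats[prev_day] * (1 - frac) + lats[local_day] * frac

    # ~20 m scatter on the roost at night; ~2 km foraging scatter by day
    nocturnal = (local_hour >= 22.0) | (local_hour < 4.0)
    jitter_deg = np.where(nocturnal, 0.0002, 0.02)
    lon = lon + rng.normal(0, jitter_deg)
    lat = lat + rng.normal(0, jitter_deg)

    fixes = pd.DataFrame(
        {
            "individual": individual,
            "timestamp": timestamps,
            "lon": lon,
            "lat": lat,
        }
    )
    truth = TruthRecord(
        individual=individual,
        strategy=strategy,
        nest=nest,
        autumn_window=autumn,
        spring_window=spring,
        migrant=is_migrant(strategy),
    )
    return fixes, truth


def simulate_burst(
    behavior: str,
    cfg: SimConfig,
    seed,
    individual: str = "bird-0",
    timestamp: Optional[datetime] = None,
    rate_hz: Optional[float] = None,
) -> AccelBurst:
    """One tri-axial burst with behavior-specific dynamics.

    Resting is a static gravity vector plus near-zero noise; foraging has
    irregular mid-amplitude noise; soaring a smooth slow drift of the
    static orientation; flapping a strong periodic heave oscillation at
    the wingbeat frequency plus a weaker surge harmonic.
    """
    if behavior not in BEHAVIORS:
        raise InputError(f"unknown behavior {behavior!r}")
    cfg.validate()
    rng = _rng(seed)
    rate = float(rate_hz if rate_hz is not None else cfg.burst_rate_hz)
    if rate <= 0:
        raise InputError("sampling rate must be positive")
    n = max(1, int(round(rate * cfg.burst_duration_s)))
    t = np.arange(n) / rate
    noise = cfg.burst_noise_g[behavior]

    tilt = rng.normal(0, 0.05, size=2)
    static = np.array([tilt[0], tilt[1], 1.0])  # gravity mostly on heave
    surge = np.full(n, static[0])
    sway = np.full(n, static[1])
    heave = np.full(n, static[2])

    if behavior == "flapping":
        freq = rng.normal(cfg.flap_freq_hz, cfg.flap_freq_sd_hz)
        phase = rng.uniform(0, 2 * np.pi)
        amp = cfg.flap_amplitude_g * rng.uniform(0.8, 1.2)
        heave = heave + amp * np.sin(2 * np.pi * freq * t + phase)
        surge = surge + 0.3 * amp * np.sin(4 * np.pi * freq * t + phase)
    elif behavior == "soaring":
        # slow banking drift, well below the wingbeat band
        freq = rng.uniform(0.04, 0.12)
        amp = cfg.soar_drift_amplitude_g * rng.uniform(0.7, 1.3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        surge = surge + amp * np.sin(2 * np.pi * freq * t + phase[0])
        sway = sway + amp * np.sin(2 * np.pi * freq * t + phase[1])
        heave = heave + amp * np.sin(2 * np.pi * freq * t + phase[2])

    surge = surge + rng.normal(0, noise, size=n)
    sway = sway + rng.normal(0, noise * (0.7 if behavior == "foraging" else 1.0), size=n)
    heave = heave + rng.normal(0, noise, size=n)

    return AccelBurst(
        individual=individual,
        timestamp=timestamp or datetime(2000, 1, 1, tzinfo=timezone.utc),
        surge=surge,
        sway=sway,
        heave=heave,
        rate=rate,
    )


def _behavior_schedule(
    local_hour: float, travel_day: bool, rng: np.random.Generator
) -> str:
    """True behavior of a burst given time of day and travel status."""
    if local_hour >= 22.0 or local_hour < 6.0:
        return "resting"
    if travel_day:
        return "soaring" if rng.random() < 0.7 else "flapping"
    u = rng.random()
    if u < 0.40:
        return "foraging"
    if u < 0.78:
        return "resting"
    if u < 0.93:
        return "soaring"
    return "flapping"


def simulate_bursts_for_track(
    truth: TruthRecord,
    year: int,
    cfg: SimConfig,
    seed,
    burst_interval_min: float = 20.0,
    tag_type: str = "default",
) -> tuple[list[AccelBurst], list[str]]:
    """Burst corpus along one annual cycle with a realistic daily schedule.

    Nocturnal bursts are resting; daytime bursts on migration travel days
    are dominated by soaring with bouts of flapping; other daytime bursts
    mix foraging, resting, soaring and flapping.  Returns the bursts plus
    the true behavior labels, index-aligned.
    """
    rng = _rng(seed)
    dates = _cycle_dates(year)
    windows = [w for w in (truth.autumn_window, truth.spring_window) if w]
    travel_days = set()
    for w0, w1 in windows:
        d = w0
        while d <= w1:
            travel_days.add(d)
            d += timedelta(days=1)
    start = datetime(year, 8, 4, tzinfo=timezone.utc)
    n = int(round(len(dates) * 24 * 60 / burst_interval_min))
    bursts: list[AccelBurst] = []
    labels: list[str] = []
    nest_lon = truth.nest[0] if truth.nest else 0.0
    for i in range(n):
        ts = start + timedelta(minutes=i * burst_interval_min)
        local = ts + timedelta(hours=nest_lon / 15.0)
        behavior = _behavior_schedule(
            local.hour + local.minute / 60.0, local.date() in travel_days, rng
        )
        burst = simulate_burst(
            behavior, cfg, rng, individual=truth.individual, timestamp=ts
        )
        burst.tag_type = tag_type
        bursts.append(burst)
        labels.append(behavior)
    return bursts, labels


def simulate_encounter_histories(
    params: MultieventParams,
    n: int,
    occasions: int,
    strategy_mix: Optional[dict[str, float]] = None,
    seed=0,
) -> tuple[list[EncounterHistory], list[TruthRecord]]:
    """Encounter histories drawn from the multievent model's own matrices.

    Every individual is released at the first occasion in state Aa with a
    certain event 1; subsequent states follow the transition matrix and
    events the event matrix for the individual's strategy group.  Dead
    recoveries (event 3) can therefore only arise from state Ra.
    """
    params.validate()
    if occasions < 2:
        raise InputError("need >= 2 occasions")
    if n < 1:
        raise InputError("need >= 1 individual")
    rng = _rng(seed)
    mix = strategy_mix or SimConfig().strategy_mix
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9 or any(not 0 <= v <= 1 for v in mix.values()):
        raise InputError("strategy_mix must be probabilities summing to 1")
    groups = list(mix)
    group_draws = rng.choice(len(groups), size=n, p=[mix[g] for g in groups])

    histories, truths = [], []
    from .multievent import STATES

    for i in range(n):
        group = groups[group_draws[i]]
        T = transition_matrix(params, group)
        B = event_matrix(params, group)
        state = 0  # Aa at release
        events = np.zeros(occasions, dtype=int)
        events[0] = 1
        states = [STATES[0]]
        for t in range(1, occasions):
            state = int(rng.choice(4, p=T[state]))
            states.append(STATES[state])
            events[t] = int(rng.choice(4, p=B[state]))
        individual = f"bird-{i}"
        histories.append(
            EncounterHistory(individual=individual, events=events, group=group)
        )
        truths.append(
            TruthRecord(
                individual=individual, strategy=group if group in STRATEGIES else None,
                states_per_occasion=states,
            )
        )
    return histories, truths


def simulate_phenotypes(
    cfg: SimConfig, seed, n: Optional[int] = None
) -> pd.DataFrame:
    """Wing lengths and migration indicators with a size-dependent logit.

    Migration probability follows ``expit(intercept + slope * (wing -
    mean))`` with a negative slope, so larger birds are more likely to be
    resident.  Returns a frame with wing_length_mm, p_migrant, migrant.
    """
    cfg.validate()
    rng = _rng(seed)
    n = n if n is not None else cfg.n_individuals
    wing = rng.normal(cfg.wing_length_mean_mm, cfg.wing_length_sd_mm, size=n)
    logits = cfg.migration_logit_intercept + cfg.migration_logit_slope_per_mm * (
        wing - cfg.wing_length_mean_mm
    )
    p = 1.0 / (1.0 + np.exp(-logits))
    migrant = rng.random(n) < p
    return pd.DataFrame(
        {
            "individual": [f"bird-{i}" for i in range(n)],
            "wing_length_mm": wing,
            "p_migrant": p,
            "migrant": migrant,
        }
    )


def simulate_population(
    cfg: SimConfig,
    year: int = 2018,
    seed: Optional[int] = None,
    with_bursts: bool = False,
    burst_interval_min: float = 60.0,
) -> dict:
    """Full synthetic dataset: tracks, truths, phenotypes, optional bursts.

    Strategies are drawn from ``cfg.strategy_mix``; each individual gets
    an independent seeded stream, so the output is reproducible and
    insensitive to generation order.
    """
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    children = root.spawn(cfg.n_individuals + 1)
    head_rng = np.random.default_rng(children[0])
    strategies = head_rng.choice(
        STRATEGIES,
        size=cfg.n_individuals,
        p=[cfg.strategy_mix[s] for s in STRATEGIES],
    )
    all_fixes, truths, bursts, behavior_truth = [], [], [], []
    for i, strategy in enumerate(strategies):
        ind_rng = np.random.default_rng(children[i + 1])
        individual = f"bird-{i}"
        fixes, truth = simulate_track(
            str(strategy), year, cfg, ind_rng, individual=individual
        )
        all_fixes.append(fixes)
        truths.append(truth)
        if with_bursts:
            ind_bursts, labels = simulate_bursts_for_track(
                truth, year, cfg, ind_rng, burst_interval_min=burst_interval_min
            )
            bursts.extend(ind_bursts)
            behavior_truth.extend(labels)
    phenotypes = simulate_phenotypes(cfg, np.random.default_rng(children[0]))
    return {
        "fixes": pd.concat(all_fixes, ignore_index=True),
        "truths": truths,
        "phenotypes": phenotypes,
        "bursts": bursts,
        "behavior_truth": behavior_truth,
        "year": year,
    }
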