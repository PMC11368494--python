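"""Synthetic goose GPS tracks with planted ground truth.

The generator emits multi-phase spring tracks — winter residence, northward
migration alternating flights and stopovers (with occasional
latitude-reversing flights), pre-nesting settlement, and a per-individual
breeding scenario (defer, attempt-and-fail, attempt-and-succeed) — at a
fixed fix interval, with state-specific gamma step lengths, waypoint
navigation with von Mises heading noise, and isotropic GPS error added last.
Every planted quantity (onset time, stopover count, reverse flights, arrival
date, nest start and run length, outcome, strategy) is recorded in a truth
ledger that is exact by construction, so each pipeline stage can be scored
against it.

Positions advance by dead reckoning in a local planar frame re-projected to
lon/lat each step, which is accurate at step scales far below the Earth
radius. Motion is scheduled from an explicit itinerary rather than sampled
from an HMM, precisely so the truth ledger is deterministic; HMM parameter
recovery is instead exercised with the step-level sampler in
:mod:`migtrack.hmm`.

The default preset targets the field magnitudes of midcontinent white-fronted
goose spring migration (cumulative distance ≈ 5500 km, duration ≈ 90 days,
≈ 16 stopovers, migratory steps ≈ 32 km per 30-min fix); the ``compact``
preset keeps the same structure at roughly one-quarter scale for fast
simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GPSTrack
from .projection import destination_point, haversine_km, initial_bearing_rad

ROOST, FORAGE, LOCAL, MIGRATORY = 0, 1, 2, 3
STATE_NAMES = {ROOST: "roost", FORAGE: "forage", LOCAL: "local-flight",
               MIGRATORY: "migratory-flight"}


@dataclass(frozen=True)
class StateMotion:
    """Gamma step-length and von Mises heading-noise parameters of one state."""

    step_mean_km: float
    step_sd_km: float
    heading_kappa: float


@dataclass
class SimConfig:
    seed: int = 0
    n_individuals: int = 56
    year: int = 2019
    fix_interval_min: float = 30.0
    gps_noise_m: float = 8.0
    # phase scheduling
    winter_days: float = 12.0
    onset_month: int = 3
    onset_day: int = 1
    onset_jitter_days: float = 10.0
    n_stopovers_mean: float = 15.0
    stopover_days_mean: float = 4.5
    stopover_days_sd: float = 2.0
    min_leg_km: float = 80.0
    reverse_mean: float = 0.9
    reverse_max: int = 4
    reverse_leg_km: tuple[float, float] = (80.0, 150.0)
    wander_radius_km: float = 2.0
    # breeding scenario
    p_attempt: float = 0.554
    p_success_given_attempt: float = 0.71
    fail_days_range: tuple[int, int] = (8, 21)
    success_days_range: tuple[int, int] = (23, 30)
    prenest_days_west: tuple[int, int] = (13, 28)
    prenest_days_east: tuple[int, int] = (4, 20)
    nest_recess_m: float = 40.0
    #: probability a given incubation fix catches the bird off the nest
    nest_recess_prob: float = 0.08
    #: planted incubation never starts before this date (the daily-movement
    #: classification window opens 15 May)
    earliest_incubation: tuple[int, int] = (5, 16)
    molt_flight_km: float = 300.0
    # geography
    winter_origins: dict = field(default_factory=lambda: {
        "MAV": (-90.5, 34.5), "Chenier Plain": (-92.9, 29.9),
        "Rolling/High Plains": (-100.5, 33.9), "Other": (-97.5, 30.5)})
    winter_mix: dict = field(default_factory=lambda: {
        "MAV": 5 / 56, "Chenier Plain": 24 / 56,
        "Rolling/High Plains": 8 / 56, "Other": 19 / 56})
    destinations: dict = field(default_factory=lambda: {
        "west": (-151.0, 69.0), "east": (-96.0, 67.5)})
    p_west: float = 27 / 56
    origin_jitter_km: float = 30.0
    dest_jitter_km: float = 40.0
    # state motion (per 30-min step)
    states: dict = field(default_factory=lambda: {
        ROOST: StateMotion(0.012, 0.012, 0.0),
        FORAGE: StateMotion(0.12, 0.12, 0.0),
        LOCAL: StateMotion(1.4, 1.0, 0.5),
        MIGRATORY: StateMotion(32.3, 10.0, 50.0)})
    #: state mix during stopovers (roost, forage, local)
    stopover_mix: tuple[float, float, float] = (0.30, 0.60, 0.10)
    season_end_month: int = 8
    season_end_day: int = 1

    def __post_init__(self):
        for s in self.states.values():
            if s.step_mean_km <= 0 or s.step_sd_km <= 0:
                raise ValueError("state step scales must be positive")
        if abs(sum(self.winter_mix.values()) - 1) > 1e-9:
            raise ValueError("winter_mix probabilities must sum to 1")


def compact_config(**overrides) -> SimConfig:
    """Quarter-scale preset: same structure, short migration, late onset.

    Sized so incubation always starts after 15 May and the full track spans
    about 100 days at 30-min fixes.
    """
    cfg = SimConfig(
        winter_days=9.0, onset_month=5, onset_day=6, onset_jitter_days=2.0,
        n_stopovers_mean=4.0, stopover_days_mean=1.6, stopover_days_sd=0.5,
        reverse_mean=0.6, reverse_max=2,
        destinations={"west": (-118.0, 47.0), "east": (-94.0, 46.0)},
        prenest_days_west=(10, 24), prenest_days_east=(6, 18),
        molt_flight_km=200.0)
    return replace(cfg, **overrides)


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated individual."""

    individual_id: str
    winter_region: str
    dest_region: str
    onset_time: pd.Timestamp = None
    onset_index: int = 0
    arrival_time: pd.Timestamp = None
    arrival_ordinal: int = 0
    n_stopovers: int = 0
    n_reverse: int = 0
    scenario: str = "defer"
    incubation_start_ordinal: int | None = None
    incubation_days: int = 0
    outcome: str = "none"
    pre_nesting_days: int | None = None
    strategy: str | None = None
    nest_lon: float | None = None
    nest_lat: float | None = None
    planned_route_km: float = 0.0
    states: np.ndarray = field(default=None, repr=False)

    def to_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "states"}
        return d


class _Emitter:
    """Accumulates fixes on a fixed time grid while phases move the bird."""

    def __init__(self, start_time: pd.Timestamp, dt_min: float,
                 lon: float, lat: float):
        self.dt = pd.Timedelta(minutes=dt_min)
        self.times = [start_time]
        self.lon = [lon]
        self.lat = [lat]
        self.states: list[int] = []

    @property
    def pos(self) -> tuple[float, float]:
        return self.lon[-1], self.lat[-1]

    @property
    def now(self) -> pd.Timestamp:
        return self.times[-1]

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    def step_to(self, lon: float, lat: float, state: int):
        self.times.append(self.times[-1] + self.dt)
        self.lon.append(lon)
        self.lat.append(lat)
        self.states.append(state)

    def move(self, bearing_rad: float, dist_km: float, state: int):
        lon, lat = destination_point(self.lon[-1], self.lat[-1],
                                     bearing_rad, dist_km)
        self.step_to(float(lon), float(lat), state)


def _wander(em: _Emitter, rng: np.random.Generator, cfg: SimConfig,
            center: tuple[float, float], n_steps: int, mix) -> None:
    """Local movement around a center; mix = (p_roost, p_forage, p_local)."""
    states = rng.choice([ROOST, FORAGE, LOCAL], size=n_steps, p=mix)
    for s in states:
        m = cfg.states[int(s)]
        L = rng.gamma((m.step_mean_km / m.step_sd_km) ** 2,
                      m.step_sd_km ** 2 / m.step_mean_km)
        d_center = haversine_km(*em.pos, *center)
        if d_center > cfg.wander_radius_km:
            brg = float(initial_bearing_rad(*em.pos, *center)) + rng.vonmises(0.0, 2.0)
        else:
            brg = rng.uniform(-np.pi, np.pi)
        em.move(brg, float(L), int(s))


def _fly_to(em: _Emitter, rng: np.random.Generator, cfg: SimConfig,
            target: tuple[float, float]) -> float:
    """Migratory flight to the target waypoint; returns distance flown."""
    m = cfg.states[MIGRATORY]
    shape = (m.step_mean_km / m.step_sd_km) ** 2
    scale = m.step_sd_km ** 2 / m.step_mean_km
    flown = 0.0
    while True:
        remaining = float(haversine_km(*em.pos, *target))
        if remaining < 1.0:
            break
        L = float(min(rng.gamma(shape, scale), remaining))
        brg = float(initial_bearing_rad(*em.pos, *target))
        if remaining > 2 * L:
            brg += float(rng.vonmises(0.0, m.heading_kappa))
        em.move(brg, L, MIGRATORY)
        flown += L
    return flown


def _jitter_point(rng, lonlat, radius_km):
    brg = rng.uniform(-np.pi, np.pi)
    r = radius_km * np.sqrt(rng.uniform())
    lon, lat = destination_point(lonlat[0], lonlat[1], brg, r)
    return float(lon), float(lat)


def simulate_individual(cfg: SimConfig, index: int) -> tuple[GPSTrack, TruthRecord]:
    """One synthetic individual; deterministic given (cfg.seed, index)."""
    rng = np.random.default_rng([cfg.seed, index])
    ind_id = f"sim{index:03d}"

    region = rng.choice(list(cfg.winter_mix), p=list(cfg.winter_mix.values()))
    origin = _jitter_point(rng, cfg.winter_origins[region], cfg.origin_jitter_km)
    dest_region = "west" if rng.random() < cfg.p_west else "east"
    dest = _jitter_point(rng, cfg.destinations[dest_region], cfg.dest_jitter_km)
    truth = TruthRecord(ind_id, str(region), dest_region)

    # itinerary: legs between stopovers along the great circle, plus reverses
    n_stop = max(1, int(rng.poisson(cfg.n_stopovers_mean)))
    route_km = float(haversine_km(*origin, *dest))
    n_legs = n_stop + 1
    spare = max(route_km - n_legs * cfg.min_leg_km, 0.0)
    legs = cfg.min_leg_km + spare * rng.dirichlet(np.ones(n_legs))
    n_rev = min(int(rng.poisson(cfg.reverse_mean)), cfg.reverse_max, n_stop)
    rev_after = rng.choice(np.arange(1, n_stop + 1), size=n_rev, replace=False) \
        if n_rev else np.array([], dtype=int)

    # scenario
    if rng.random() < cfg.p_attempt:
        if rng.random() < cfg.p_success_given_attempt:
            scenario, inc_days = "success", int(rng.integers(*cfg.success_days_range))
        else:
            scenario, inc_days = "fail", int(rng.integers(*cfg.fail_days_range))
    else:
        scenario, inc_days = "defer", 0
    lo, hi = (cfg.prenest_days_west if dest_region == "west"
              else cfg.prenest_days_east)
    prenest_days = int(rng.integers(lo, hi + 1))

    # time grid anchored at midnight so day boundaries fall on fixes
    onset_date = (pd.Timestamp(year=cfg.year, month=cfg.onset_month,
                               day=cfg.onset_day, tz="UTC")
                  + pd.Timedelta(days=float(rng.uniform(0, cfg.onset_jitter_days))))
    start = (onset_date - pd.Timedelta(days=cfg.winter_days)).floor("D")
    end = pd.Timestamp(year=cfg.year, month=cfg.season_end_month,
                       day=cfg.season_end_day, tz="UTC") + pd.Timedelta(days=1)
    steps_per_day = int(round(1440.0 / cfg.fix_interval_min))

    em = _Emitter(start, cfg.fix_interval_min, *origin)

    # winter residence through a random time of the onset day
    winter_steps = int(cfg.winter_days * steps_per_day) + int(rng.integers(0, steps_per_day))
    _wander(em, rng, cfg, origin, winter_steps, cfg.stopover_mix)
    truth.onset_index = em.n_fixes - 1
    truth.onset_time = em.now

    # migration: flight legs and stopovers (reverses add a southward flight
    # plus a short pause, each its own segment)
    pos = origin
    total_flown = 0.0
    n_stop_truth = 0
    stop_shape = (cfg.stopover_days_mean / cfg.stopover_days_sd) ** 2
    stop_scale = cfg.stopover_days_sd ** 2 / cfg.stopover_days_mean
    for k in range(n_legs):
        brg = float(initial_bearing_rad(*pos, *dest))
        step_target = destination_point(pos[0], pos[1], brg, float(legs[k]))
        waypoint = (float(step_target[0]), float(step_target[1]))
        if k == n_legs - 1:
            waypoint = dest
        total_flown += _fly_to(em, rng, cfg, waypoint)
        pos = em.pos
        if k < n_legs - 1:
            d_stop = max(0.5, rng.gamma(stop_shape, stop_scale))
            _wander(em, rng, cfg, pos, int(d_stop * steps_per_day), cfg.stopover_mix)
            n_stop_truth += 1
            if (k + 1) in rev_after:
                rev_km = rng.uniform(*cfg.reverse_leg_km)
                south = destination_point(em.pos[0], em.pos[1],
                                          np.pi + rng.uniform(-0.3, 0.3), rev_km)
                total_flown += _fly_to(em, rng, cfg, (float(south[0]), float(south[1])))
                _wander(em, rng, cfg, em.pos,
                        int(rng.uniform(0.5, 1.0) * steps_per_day), cfg.stopover_mix)
                n_stop_truth += 1
            pos = em.pos
    truth.arrival_time = em.now
    truth.arrival_ordinal = int(em.now.dayofyear)
    truth.n_stopovers = n_stop_truth
    truth.n_reverse = int(n_rev)
    truth.scenario = scenario
    truth.planned_route_km = total_flown
    arrival_pos = em.pos

    # forage-only wandering from arrival keeps every pre/post-nesting day
    # well above the 2 km/day quiet threshold
    forage_mix = (0.0, 0.9, 0.1)

    if scenario == "defer":
        molt_date = (pd.Timestamp(year=cfg.year, month=6, day=24, tz="UTC")
                     + pd.Timedelta(days=float(rng.uniform(0, 6))))
        n1 = max(int((molt_date - em.now) / em.dt), 0)
        _wander(em, rng, cfg, arrival_pos, n1, forage_mix)
        molt_target = destination_point(em.pos[0], em.pos[1],
                                        rng.uniform(-0.5, 0.5), cfg.molt_flight_km)
        _fly_to(em, rng, cfg, (float(molt_target[0]), float(molt_target[1])))
        n2 = max(int((end - em.now) / em.dt) - 1, 0)
        _wander(em, rng, cfg, em.pos, n2, forage_mix)
    else:
        inc_start = (truth.arrival_time.floor("D")
                     + pd.Timedelta(days=prenest_days))
        floor_date = pd.Timestamp(year=cfg.year, month=cfg.earliest_incubation[0],
                                  day=cfg.earliest_incubation[1], tz="UTC")
        if inc_start < floor_date:
            inc_start = floor_date
            prenest_days = int((inc_start - truth.arrival_time.floor("D")).days)
        n_pre = int((inc_start - em.now) / em.dt)
        _wander(em, rng, cfg, arrival_pos, n_pre, forage_mix)
        nest = em.pos
        for _ in range(inc_days * steps_per_day):
            # incubating birds sit: only occasional recesses leave the nest
            if rng.random() < cfg.nest_recess_prob:
                j = _jitter_point(rng, nest, cfg.nest_recess_m / 1000.0)
            else:
                j = nest
            em.step_to(j[0], j[1], ROOST)
        truth.incubation_start_ordinal = int(inc_start.dayofyear)
        truth.incubation_days = inc_days
        truth.outcome = scenario
        truth.pre_nesting_days = prenest_days
        truth.strategy = ("capital-leaning" if prenest_days < 10
                          else "income-leaning")
        truth.nest_lon, truth.nest_lat = nest
        n_post = max(int((end - em.now) / em.dt) - 1, 0)
        _wander(em, rng, cfg, nest, n_post, forage_mix)

    # trim to the season and add GPS noise
    times = pd.DatetimeIndex(em.times)
    keep = times < end
    lon = np.array(em.lon)[keep]
    lat = np.array(em.lat)[keep]
    times = times[keep]
    states = np.array(em.states)[: len(times) - 1]
    if cfg.gps_noise_m > 0:
        sigma_deg_lat = cfg.gps_noise_m / 111195.0
        lat_noise = rng.normal(0.0, sigma_deg_lat, len(lat))
        lon_noise = rng.normal(0.0, sigma_deg_lat, len(lon)) / np.cos(np.radians(lat))
        lon = lon + lon_noise
        lat = lat + lat_noise
    track = GPSTrack(ind_id, times, lon, lat,
                     nominal_interval_min=cfg.fix_interval_min)
    # device-reported speed: step length / interval, in km/h
    speed = np.zeros(len(track))
    d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    speed[:-1] = d / (cfg.fix_interval_min / 60.0)
    speed[-1] = speed[-2] if len(speed) > 1 else 0.0
    track.speed = speed
    truth.states = states
    return track, truth


def simulate_population(cfg: SimConfig) -> tuple[list[GPSTrack], list[TruthRecord]]:
    """Independent individuals on RNG substreams (seed, index)."""
    tracks, truths = [], []
    for i in range(cfg.n_individuals):
        tr, th = simulate_individual(cfg, i)
        tracks.append(tr)
        truths.append(th)
    return tracks, truths


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.to_row() for t in truths])
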