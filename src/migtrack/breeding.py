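"""Breeding attempt, outcome, and strategy classification from movement.

An incubating goose barely moves: total daily travel ≤ 2 km for at least 6
consecutive days, with the fixes clustered at a single site, marks a nesting
attempt; a quiet run of at least 23 days — the minimum published incubation
period for the species in the Canadian Arctic — marks apparent success.
Failures during egg laying (before incubation) are undetectable from
movement alone and are not claimed. In place of the visual nest-plot
inspection a human would do, site fidelity is checked explicitly: at least
90% of the run's fixes must fall within 250 m of the run's median
coordinate (~30× the 8 m device error).

The capital–income continuum is operationalized by pre-nesting duration:
under 10 days on the breeding grounds before incubation is too short to
build a clutch from local feeding alone, so such birds lean on stored
(capital) reserves; 10 days or more marks an income-leaning strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GPSTrack
from .projection import haversine_km

ATTEMPT = "attempt"
DEFER = "defer"
SUCCESS = "success"
FAIL = "fail"
NONE = "none"
CAPITAL = "capital-leaning"
INCOME = "income-leaning"


@dataclass(frozen=True)
class BreedingConfig:
    window_start_month: int = 5
    window_start_day: int = 15
    window_end_month: int = 7
    window_end_day: int = 30
    daily_max_km: float = 2.0
    min_attempt_days: int = 6
    success_days: int = 23
    cluster_radius_km: float = 0.25
    cluster_min_fraction: float = 0.90
    capital_prenest_days: int = 10
    max_missing_run_days: int = 1
    #: hour offset applied before taking calendar days (local-solar sensitivity)
    day_offset_hours: float = 0.0

    def __post_init__(self):
        if self.min_attempt_days >= self.success_days:
            raise ValueError("min_attempt_days must be < success_days")
        for name in ("daily_max_km", "cluster_radius_km", "capital_prenest_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DailyMovement:
    """One calendar day of movement; ``missing`` days have no fixes at all."""

    date: pd.Timestamp
    total_distance_km: float
    max_displacement_km: float
    fix_count: int
    missing: bool = False


@dataclass
class BreedingRecord:
    individual_id: str
    attempt: bool
    incubation_start_ordinal: int | None
    incubation_run_days: int
    outcome: str                       # success / fail / none
    arrival_ordinal: int | None = None
    pre_nesting_days: int | None = None
    strategy: str | None = None
    endpoint_ordinal: int | None = None
    nest_lon: float | None = None
    nest_lat: float | None = None


def daily_movement(track: GPSTrack, cfg: BreedingConfig = BreedingConfig(),
                   year: int | None = None) -> list[DailyMovement]:
    """Per-day totals over the breeding window (default 15 May – 30 July).

    A step is charged to the day of its starting fix. Days inside the window
    with no fixes are flagged missing rather than reported as zero movement.
    """
    if len(track) == 0:
        return []
    ts = track.timestamps + pd.Timedelta(hours=cfg.day_offset_hours)
    if year is None:
        year = int(ts[len(ts) // 2].year)
    tz = ts.tz
    w0 = pd.Timestamp(year=year, month=cfg.window_start_month,
                      day=cfg.window_start_day, tz=tz)
    w1 = pd.Timestamp(year=year, month=cfg.window_end_month,
                      day=cfg.window_end_day, tz=tz) + pd.Timedelta(days=1)
    sel = (ts >= w0) & (ts < w1)
    if not sel.any():
        return []
    idx = np.flatnonzero(sel)
    lon, lat = track.lon[idx], track.lat[idx]
    days = ts[idx].floor("D")
    step_km = np.zeros(len(idx))
    if len(idx) > 1:
        step_km[:-1] = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])

    frame = pd.DataFrame({"day": days, "lon": lon, "lat": lat, "step": step_km})
    out: list[DailyMovement] = []
    prev_last = None  # (lon, lat) of previous day's final fix
    for day in pd.date_range(days[0].normalize(), days[-1].normalize(), tz=tz):
        grp = frame[frame["day"] == day]
        if grp.empty:
            out.append(DailyMovement(day, 0.0, 0.0, 0, missing=True))
            continue
        # a step is charged to the day of its starting fix (midnight-crossing
        # steps included); the final fix of the window has step 0
        total = float(grp["step"].sum())
        max_disp = 0.0
        if prev_last is not None:
            max_disp = float(haversine_km(prev_last[0], prev_last[1],
                                          grp["lon"].to_numpy(),
                                          grp["lat"].to_numpy()).max())
        out.append(DailyMovement(day, total, max_disp, len(grp)))
        prev_last = (float(grp["lon"].iloc[-1]), float(grp["lat"].iloc[-1]))
    return out


def _candidate_runs(daily: list[DailyMovement], cfg: BreedingConfig):
    """Maximal runs of quiet days, tolerating short flanked missing gaps.

    Yields (start_idx, end_idx) inclusive over ``daily``; endpoints are quiet
    (non-missing) days.
    """
    quiet = [(not d.missing) and d.total_distance_km <= cfg.daily_max_km
             for d in daily]
    missing = [d.missing for d in daily]
    n = len(daily)
    i = 0
    while i < n:
        if not quiet[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            if quiet[j + 1]:
                j += 1
                continue
            # tolerate a short run of missing days if flanked by quiet days
            g = j + 1
            while g < n and missing[g] and g - (j + 1) < cfg.max_missing_run_days:
                g += 1
            if g < n and g > j + 1 and quiet[g]:
                j = g
                continue
            break
        yield i, j
        i = j + 1


def _site_fidelity(track: GPSTrack, day0: pd.Timestamp, day1: pd.Timestamp,
                   cfg: BreedingConfig):
    """Check clustering of fixes between day0 and day1 (inclusive days).

    Returns (ok, median_lon, median_lat, fraction_within).
    """
    ts = track.timestamps + pd.Timedelta(hours=cfg.day_offset_hours)
    sel = (ts >= day0) & (ts < day1 + pd.Timedelta(days=1))
    if not sel.any():
        return False, np.nan, np.nan, 0.0
    lon = track.lon[sel]
    lat = track.lat[sel]
    mlon, mlat = float(np.median(lon)), float(np.median(lat))
    d = haversine_km(mlon, mlat, lon, lat)
    frac = float(np.mean(d <= cfg.cluster_radius_km))
    return frac >= cfg.cluster_min_fraction, mlon, mlat, frac


def detect_attempt(daily: list[DailyMovement], track: GPSTrack,
                   cfg: BreedingConfig = BreedingConfig(),
                   first_run: bool = False):
    """Longest quiet, site-faithful run; attempt if it spans >= 6 days.

    Returns (attempt, incubation_start_date, run_days, nest_lonlat). Run
    length is the calendar span from the first to the last qualifying day
    inclusive, so a single tolerated missing day inside the run neither
    extends nor breaks it. ``first_run`` selects the first qualifying run
    instead of the longest (sensitivity variant).
    """
    best = None
    for i, j in _candidate_runs(daily, cfg):
        ok, mlon, mlat, _ = _site_fidelity(track, daily[i].date, daily[j].date, cfg)
        if not ok:
            continue
        span = (daily[j].date - daily[i].date).days + 1
        if best is None or span > best[0]:
            best = (span, daily[i].date, (mlon, mlat))
            if first_run and span >= cfg.min_attempt_days:
                break
    if best is None:
        return False, None, 0, None
    span, start, nest = best
    if span < cfg.min_attempt_days:
        return False, None, span, None
    return True, start, span, nest


def classify_outcome(run_days: int, cfg: BreedingConfig = BreedingConfig()) -> str:
    """Success iff the quiet run lasted at least the minimum incubation period."""
    if run_days < cfg.min_attempt_days:
        raise ValueError("classify_outcome called without a nesting attempt")
    return SUCCESS if run_days >= cfg.success_days else FAIL


def phenology(individual_id: str, arrival_ordinal: int,
              incubation_start_ordinal: int | None, run_days: int = 0,
              cohort_median_start: int | None = None,
              cfg: BreedingConfig = BreedingConfig(),
              nest=None) -> BreedingRecord:
    """Assemble the breeding record: outcome, pre-nesting duration, strategy.

    Attempters get pre_nesting_days = incubation start − arrival and a
    capital-leaning label when that is under ``capital_prenest_days``.
    Non-attempters get the cohort median incubation start (lower median over
    the year's attempters) as their trajectory endpoint.
    """
    if incubation_start_ordinal is not None:
        if incubation_start_ordinal < arrival_ordinal:
            raise ValueError(f"{individual_id}: incubation precedes arrival")
        pre = int(incubation_start_ordinal - arrival_ordinal)
        return BreedingRecord(
            individual_id=individual_id, attempt=True,
            incubation_start_ordinal=int(incubation_start_ordinal),
            incubation_run_days=int(run_days),
            outcome=classify_outcome(run_days, cfg),
            arrival_ordinal=int(arrival_ordinal), pre_nesting_days=pre,
            strategy=CAPITAL if pre < cfg.capital_prenest_days else INCOME,
            endpoint_ordinal=int(incubation_start_ordinal),
            nest_lon=None if nest is None else nest[0],
            nest_lat=None if nest is None else nest[1])
    return BreedingRecord(
        individual_id=individual_id, attempt=False,
        incubation_start_ordinal=None, incubation_run_days=0, outcome=NONE,
        arrival_ordinal=int(arrival_ordinal), pre_nesting_days=None,
        strategy=None, endpoint_ordinal=cohort_median_start)


def lower_median(values) -> int:
    """Median taking the lower middle element for even counts."""
    v = sorted(values)
    if not v:
        raise ValueError("no values")
    return int(v[(len(v) - 1) // 2])


def classify_breeding(track: GPSTrack, arrival_ordinal: int,
                      cfg: BreedingConfig = BreedingConfig(),
                      year: int | None = None) -> BreedingRecord:
    """Full per-individual classification from a QC'd track."""
    daily = daily_movement(track, cfg, year=year)
    attempt, start, run_days, nest = detect_attempt(daily, track, cfg)
    if attempt:
        return phenology(track.individual_id, arrival_ordinal,
                         int(start.dayofyear), run_days, cfg=cfg, nest=nest)
    return phenology(track.individual_id, arrival_ordinal, None, cfg=cfg)


def fill_cohort_endpoints(records: list[BreedingRecord]) -> None:
    """Give non-attempters the cohort's (lower-)median incubation start."""
    starts = [r.incubation_start_ordinal for r in records if r.attempt]
    if not starts:
        return
    med = lower_median(starts)
    for r in records:
        if not r.attempt:
            r.endpoint_ordinal = med


def summarize_cohort(records: list[BreedingRecord]) -> dict[str, float]:
    """Attempt and success percentages over a cohort of breeding records."""
    n = len(records)
    attempts = [r for r in records if r.attempt]
    succ = [r for r in attempts if r.outcome == SUCCESS]
    return {
        "n": n,
        "n_attempt": len(attempts),
        "n_success": len(succ),
        "attempt_rate_pct": 100.0 * len(attempts) / n if n else float("nan"),
        "success_rate_pct": (100.0 * len(succ) / len(attempts)
                             if attempts else float("nan")),
    }
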