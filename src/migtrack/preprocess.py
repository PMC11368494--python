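"""Quality control and migration-onset detection.

The pipeline's QC mirrors standard waterfowl telemetry practice: drop fixes
with horizontal dilution of precision above 5, thin 15-min duty cycles to a
common 30-min interval, find the first northward movement bout displacing at
least 50 km from the wintering area (net squared displacement), and keep the
window from 7 days before that onset through 1 August.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import EmptyTrackError, GPSTrack
from .projection import haversine_km

logger = logging.getLogger(__name__)

#: Sentinel returned when no qualifying migration onset exists.
NO_ONSET = None


@dataclass(frozen=True)
class QCConfig:
    max_hdop: float = 5.0
    target_interval_min: float = 30.0
    resample_tolerance_min: float = 5.0
    onset_displacement_km: float = 50.0
    pre_onset_buffer_days: float = 7.0
    season_end_month: int = 8
    season_end_day: int = 1
    #: slack allowed for small NSD regressions inside a movement bout, km
    bout_regression_slack_km: float = 2.0
    #: minimum per-step displacement gain for a step to count as bout progress, km
    bout_min_progress_km: float = 0.25
    #: consecutive non-progress (tolerated) steps allowed inside a bout
    bout_max_tolerated_steps: int = 2
    #: displacement a bout must reach before non-progress steps are tolerated, km
    bout_tolerance_floor_km: float = 5.0

    def __post_init__(self):
        if self.resample_tolerance_min >= self.target_interval_min / 2:
            raise ValueError("resample tolerance must be < target_interval/2")
        for name in ("max_hdop", "target_interval_min", "resample_tolerance_min",
                     "onset_displacement_km", "pre_onset_buffer_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def filter_hdop(track: GPSTrack, max_hdop: float = 5.0) -> GPSTrack:
    """Drop fixes with measured HDOP strictly above ``max_hdop``.

    Fixes with no HDOP report are retained (the filter acts on measured
    values only). Raises :class:`EmptyTrackError` if nothing survives.
    """
    with np.errstate(invalid="ignore"):
        keep = ~(track.hdop > max_hdop)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("track %s: removed %d fixes with HDOP > %g",
                    track.individual_id, n_removed, max_hdop)
    if not keep.any():
        raise EmptyTrackError(f"track {track.individual_id}: all fixes removed by HDOP filter")
    return track.subset(keep)


def resample_interval(track: GPSTrack, target_interval_min: float = 30.0,
                      tolerance_min: float = 5.0) -> GPSTrack:
    """Thin a track to one fix per ``target_interval_min`` slot.

    Slots are anchored at the first fix; for each slot the nearest in-tolerance
    fix is kept, subject to retained fixes being at least
    (target − tolerance) apart. Gaps remain gaps — nothing is interpolated.
    """
    n = len(track)
    if n == 0:
        return track
    t = track.timestamps.asi8 / 60e9  # minutes
    t0 = t[0]
    tol = tolerance_min
    step = target_interval_min
    keep = []
    last_kept_t = -np.inf
    slot = 0
    j = 0
    max_slot = int(np.ceil((t[-1] - t0) / step)) + 1
    while slot <= max_slot:
        target = t0 + slot * step
        # nearest fix to this slot target
        while j + 1 < n and abs(t[j + 1] - target) <= abs(t[j] - target):
            j += 1
        if (abs(t[j] - target) <= tol and t[j] - last_kept_t >= step - tol
                and (not keep or j != keep[-1])):
            keep.append(j)
            last_kept_t = t[j]
        slot += 1
    out = track.subset(np.array(keep, dtype=int))
    out.nominal_interval_min = target_interval_min
    return out


def net_squared_displacement(track: GPSTrack, reference_index: int = 0) -> np.ndarray:
    """Squared great-circle displacement (km²) of every fix from the reference fix."""
    if not 0 <= reference_index < len(track):
        raise IndexError("reference index out of range")
    d = haversine_km(track.lon[reference_index], track.lat[reference_index],
                     track.lon, track.lat)
    return d ** 2


def _bout_end(dist_from_start: np.ndarray, cfg: QCConfig) -> int:
    """Last index of the maximal away-from-start movement run (0 = no bout).

    A step continues the bout if it gains at least ``bout_min_progress_km``
    of displacement from the bout start, or — for at most
    ``bout_max_tolerated_steps`` in a row — stays within
    ``bout_regression_slack_km`` of the running displacement maximum. The
    per-step progress floor keeps device jitter from chaining into a bout;
    the slack lets a genuine flight survive brief circling or wind setbacks.
    """
    run_max = 0.0
    end = 0
    tolerated = 0
    for j in range(1, len(dist_from_start)):
        gain = dist_from_start[j] - dist_from_start[j - 1]
        if gain >= cfg.bout_min_progress_km:
            tolerated = 0
        elif (dist_from_start[j] >= run_max - cfg.bout_regression_slack_km
              and run_max >= cfg.bout_tolerance_floor_km
              and tolerated < cfg.bout_max_tolerated_steps and end > 0):
            tolerated += 1
        else:
            break
        run_max = max(run_max, dist_from_start[j])
        end = j
    return end


def detect_migration_onset(track: GPSTrack, cfg: QCConfig = QCConfig()):
    """First northward movement bout displacing ≥ ``onset_displacement_km``.

    A bout is the maximal run of consecutive steps moving away from the
    pre-bout position (displacement monotone up to a small slack, each step
    making real progress). Returns ``(onset_timestamp, onset_fix_index)``, or
    ``NO_ONSET`` if no qualifying bout exists — a sentinel rather than an
    exception, so callers can drop incomplete migrations.
    """
    n = len(track)
    if n < 2:
        return NO_ONSET
    for s in range(n - 1):
        # grow the candidate bout lazily; stationary starts die in O(1) steps
        chunk = min(n - s, 64)
        dist = haversine_km(track.lon[s], track.lat[s],
                            track.lon[s:s + chunk], track.lat[s:s + chunk])
        while True:
            end_rel = _bout_end(dist, cfg)
            if end_rel < len(dist) - 1 or s + len(dist) >= n:
                break
            chunk = min(n - s, len(dist) * 2)
            dist = haversine_km(track.lon[s], track.lat[s],
                                track.lon[s:s + chunk], track.lat[s:s + chunk])
        end = s + end_rel
        if (end > s and dist[end_rel] >= cfg.onset_displacement_km
                and track.lat[end] > track.lat[s]):
            return track.timestamps[s], s
    return NO_ONSET


def window_track(track: GPSTrack, onset_timestamp, cfg: QCConfig = QCConfig()) -> GPSTrack:
    """Retain fixes from (onset − buffer days) through the season end date.

    The season end day (default 1 August of the onset year) is inclusive
    through 23:59:59.
    """
    onset = pd.Timestamp(onset_timestamp)
    start = onset - pd.Timedelta(days=cfg.pre_onset_buffer_days)
    end = pd.Timestamp(year=onset.year, month=cfg.season_end_month,
                       day=cfg.season_end_day, tz=onset.tz) + pd.Timedelta(days=1)
    keep = (track.timestamps >= start) & (track.timestamps < end)
    if not keep.any():
        raise EmptyTrackError(f"track {track.individual_id}: analysis window is empty")
    return track.subset(keep)


def prepare_track(track: GPSTrack, cfg: QCConfig = QCConfig()):
    """filter → resample → onset → window. Returns (track, onset) or (None, NO_ONSET)."""
    qc = resample_interval(filter_hdop(track, cfg.max_hdop),
                           cfg.target_interval_min, cfg.resample_tolerance_min)
    onset = detect_migration_onset(qc, cfg)
    if onset is NO_ONSET:
        return None, NO_ONSET
    return window_track(qc, onset[0], cfg), onset
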