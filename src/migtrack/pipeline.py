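"""End-to-end track-to-outcome analysis driver.

Order of operations mirrors the analysis design: quality control and onset
detection first; a pooled hidden Markov model fit over all individuals (with
optional per-individual refits seeded from the pooled parameters); Viterbi
segmentation into flights and stopovers; breeding classification from daily
movement; trajectory endpoints (incubation start for attempters, the year
cohort's median incubation start for non-attempters) truncate each track
before migration characteristics are summarized, so a deferring bird's molt
movements never masquerade as its final migratory flight; dynamic Brownian
bridge utilization distributions are built per individual over the migration
window, day-weighted, composited, and reduced to isopleths for the
proportion-of-time-in-high-use metric and the regional area accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breeding as br
from . import dbbmm, hmm
from .io_formats import GPSTrack, RegionSet
from .preprocess import NO_ONSET, QCConfig, prepare_track

logger = logging.getLogger(__name__)


@dataclass
class IndividualResult:
    track: GPSTrack                    # windowed, QC'd
    onset_index: int
    onset_time: pd.Timestamp
    segmented: hmm.SegmentedTrack
    summary: hmm.MigrationSummary = None
    record: br.BreedingRecord = None
    model: hmm.HMMModel = None
    # endpoint-truncated views used for migration characteristics
    track_for_summary: GPSTrack = None
    segmented_for_summary: hmm.SegmentedTrack = None


@dataclass
class PipelineResult:
    individuals: list[IndividualResult]
    pooled_model: hmm.HMMModel
    composite: dbbmm.UDGrid = None
    isopleth_set: dbbmm.IsoplethSet = None
    region_table: pd.DataFrame = None
    dropped: list[str] = field(default_factory=list)

    @property
    def summaries(self) -> list[hmm.MigrationSummary]:
        return [r.summary for r in self.individuals if r.summary is not None]

    @property
    def records(self) -> list[br.BreedingRecord]:
        return [r.record for r in self.individuals if r.record is not None]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.individuals:
            if r.summary is None:
                continue
            s, b = r.summary, r.record
            rows.append({
                "individual_id": s.individual_id,
                "total_distance_km": s.total_distance_km,
                "duration_days": s.duration_days,
                "n_stopovers": s.n_stopovers,
                "n_reverse": s.n_reverse,
                "arrival_ordinal": s.arrival_ordinal,
                "prop_high_use": s.prop_high_use,
                "winter_region": s.winter_region,
                "attempt": b.attempt if b else None,
                "outcome": b.outcome if b else None,
                "incubation_start_ordinal": b.incubation_start_ordinal if b else None,
                "pre_nesting_days": b.pre_nesting_days if b else None,
                "strategy": b.strategy if b else None,
            })
        return pd.DataFrame(rows)


def _truncate(track: GPSTrack, end_time: pd.Timestamp) -> GPSTrack:
    keep = track.timestamps <= end_time
    return track.subset(keep)


def _ordinal_to_time(ordinal: int, year: int, tz) -> pd.Timestamp:
    return (pd.Timestamp(year=year, month=1, day=1, tz=tz)
            + pd.Timedelta(days=int(ordinal) - 1))


def run_pipeline(tracks: list[GPSTrack],
                 qc: QCConfig = QCConfig(),
                 breed_cfg: br.BreedingConfig = br.BreedingConfig(),
                 n_states: int = 4,
                 seed: int = 0,
                 use_covariate: bool = False,
                 n_restarts: int = 5,
                 refit_individuals: bool = False,
                 pooled_steps_cap: int = 6000,
                 regions: RegionSet | None = None,
                 winter_regions: RegionSet | None = None,
                 compute_uds: bool = True,
                 cell_size_km: float = dbbmm.DEFAULT_CELL_KM,
                 lat_cutoff_deg: float = 60.0) -> PipelineResult:
    """Run the full analysis. Deterministic given ``seed``.

    ``pooled_steps_cap`` bounds the pooled HMM fit by subsampling whole
    tracks' step series round-robin; decoding always uses every step.
    """
    prepared = []
    dropped = []
    for tr in tracks:
        win, onset = prepare_track(tr, qc)
        if onset is NO_ONSET:
            dropped.append(tr.individual_id)
            logger.info("dropping %s: no migration onset", tr.individual_id)
            continue
        onset_time = onset[0]
        onset_index = int(np.searchsorted(win.timestamps.asi8, onset_time.value))
        prepared.append((win, onset_index, onset_time))
    if not prepared:
        raise ValueError("no tracks with a detected migration onset")

    all_steps = [hmm.build_steps(win) for win, _, _ in prepared]
    pooled = _pool_steps(all_steps, pooled_steps_cap)
    pooled_model = hmm.fit_hmm(pooled, n_states, use_covariate=use_covariate,
                               seed=seed, n_restarts=n_restarts)

    results: list[IndividualResult] = []
    for (win, onset_index, onset_time), steps in zip(prepared, all_steps):
        model = pooled_model
        if refit_individuals:
            try:
                model = hmm.fit_hmm(steps, n_states, use_covariate=use_covariate,
                                    seed=seed, n_restarts=1,
                                    start_from=pooled_model)
            except hmm.ConvergenceError:
                logger.warning("%s: individual refit failed; using pooled model",
                               win.individual_id)
        seg = hmm.segment_track(steps, model)
        results.append(IndividualResult(win, onset_index, onset_time, seg,
                                        model=model))

    # breeding attempt detection first: the trajectory endpoint (incubation
    # start, or the cohort median for non-attempters) truncates each track
    # before arrival and the other migration characteristics are read off,
    # so molt or post-nesting movements never count as migratory flights
    year = int(prepared[0][0].timestamps[0].year)
    attempts = []
    for r in results:
        daily = br.daily_movement(r.track, breed_cfg, year=year)
        attempts.append(br.detect_attempt(daily, r.track, breed_cfg))
    starts = [int(a[1].dayofyear) for a in attempts if a[0]]
    median_start = br.lower_median(starts) if starts else None

    for r, (attempt, start, run_days, nest) in zip(results, attempts):
        endpoint = int(start.dayofyear) if attempt else median_start
        seg = r.segmented
        track = r.track
        if endpoint is not None:
            end_t = _ordinal_to_time(endpoint, year,
                                     track.timestamps.tz) + pd.Timedelta(days=1)
            if end_t < track.timestamps[-1]:
                track = _truncate(track, end_t)
                if len(track) >= 3:
                    steps = hmm.build_steps(track)
                    seg = hmm.segment_track(steps, r.model or pooled_model)
        r.track_for_summary = track
        r.segmented_for_summary = seg
        flights = seg.flights
        arrival_ord = (int(track.timestamps[flights[-1].end + 1].dayofyear)
                       if flights else int(track.timestamps[-1].dayofyear))
        r.record = br.phenology(
            r.track.individual_id, arrival_ord,
            int(start.dayofyear) if attempt else None,
            run_days=run_days, cohort_median_start=median_start,
            cfg=breed_cfg, nest=nest)

    composite = iso = table = None
    if compute_uds:
        migration_tracks = []
        for r in results:
            sub = _migration_subtrack(r)
            if sub is not None and len(sub) >= 3:
                migration_tracks.append(sub)
        if migration_tracks:
            grid = dbbmm.GridSpec.for_tracks(migration_tracks,
                                             cell_size_km=cell_size_km)
            uds = []
            for sub in migration_tracks:
                var = dbbmm.estimate_dynamic_variance(sub)
                ud = dbbmm.compute_ud(sub, var, grid)
                uds.append(dbbmm.weight_by_days(ud, sub))
            composite = dbbmm.composite_ud(uds)
            iso = dbbmm.isopleths(composite)
            if regions is not None:
                table = dbbmm.region_areas(iso, regions, lat_cutoff_deg)

    for r in results:
        seg = r.segmented_for_summary
        track = r.track_for_summary
        if not seg.flights:
            logger.info("%s: no flights after truncation; skipping summary",
                        track.individual_id)
            continue
        onset_idx = int(np.searchsorted(track.timestamps.asi8, r.onset_time.value))
        r.summary = hmm.summarize_migration(
            seg, track, onset_idx, high_use_mask=iso,
            winter_regions=winter_regions)
    return PipelineResult(results, pooled_model, composite, iso, table, dropped)


def _pool_steps(all_steps: list[hmm.StepSeries], cap: int) -> hmm.StepSeries:
    """Concatenate whole step series until the cap is reached.

    Whole tracks are kept so every behavioral phase (winter, flights,
    stopovers, nesting) is represented in the pooled fit; at least one track
    is always included.
    """
    chosen = []
    total = 0
    for s in all_steps:
        chosen.append(s)
        total += len(s)
        if total >= cap:
            break
    return hmm.StepSeries(
        np.concatenate([s.lengths for s in chosen]),
        np.concatenate([_nan_first(s.angles) for s in chosen]),
        np.concatenate([s.intervals_min for s in chosen]),
        np.concatenate([s.covariate for s in chosen]),
        np.concatenate([s.dlat for s in chosen]),
        None, "pooled")


def _nan_first(angles: np.ndarray) -> np.ndarray:
    out = angles.copy()
    if len(out):
        out[0] = np.nan  # track boundary: turning angle undefined
    return out


def _migration_subtrack(r: IndividualResult) -> GPSTrack | None:
    """Fixes from onset through the end of the final migratory flight."""
    seg = getattr(r, "segmented_for_summary", r.segmented)
    track = getattr(r, "track_for_summary", r.track)
    flights = seg.flights
    if not flights:
        return None
    onset_idx = int(np.searchsorted(track.timestamps.asi8, r.onset_time.value))
    end_fix = flights[-1].end + 1
    if end_fix <= onset_idx + 2:
        return None
    return track.subset(np.arange(onset_idx, end_fix + 1))


def build_predictor_frame(result: PipelineResult) -> pd.DataFrame:
    """Per-individual predictor/outcome frame for the statistical models."""
    df = result.summary_frame()
    return df.dropna(subset=["total_distance_km", "duration_days"])
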