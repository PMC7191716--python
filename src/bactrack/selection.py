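"""Two-stage track selection with a per-criterion exclusion ledger.

Raw tracks from the linker are noisy: IDs born from spurious detections,
tracks padded with gap points, overlap events that inflate the bounding
rectangle, IDs that jump between neighbours.  Rather than model these
failure modes, the pipeline selects stringently against them:

* **Coarse stage** — whole tracks are dropped when their mean rectangle area
  (gap points counting as zero area) falls outside
  ``[coarse_area_lower_frac, coarse_area_upper_mult] x avg_bacterial_area_px2``,
  or when the track is shorter than ``min_track_time_s``.
* **Point scrubbing** — zero-area gap placeholders are deleted, as are
  points whose area exceeds ``point_area_outlier_mult`` times the track's
  mean area (bacteria overlapping for a frame).
* **Splitting** — a run of more than ``max_consecutive_gaps`` missing frames,
  or a per-step distance above the Tukey outer fence (Q3 + 3 IQR) of the
  track's step distances, cuts the track; every piece re-enters the pipeline
  from the coarse stage.  Because immotile-heavy data makes the fence
  meaningless, distance-outlier splitting disables itself for the whole
  table when the outlier fraction exceeds
  ``distance_outlier_auto_disable_frac``.
* **Fine stage** — per-segment checks, first failure wins: minimum duration,
  maximum consecutive gap run, maximum gap fraction, mean area within a
  percentile band of all candidate tracks' mean areas, and mean position
  clear of the frame edges.

If several pieces of one original ID pass, only the longest is kept, and an
optional maximum duration truncates (or truncates-and-drops) the result.
Every finally rejected ID increments exactly one exclusion counter, so
``tracks_in == tracks_accepted + sum(exclusions)`` always holds; a rejected
ID that was split is attributed to the cause of its first split, otherwise
to the criterion that rejected its longest candidate piece.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TrackerConfig
from .tracking import RAW_COLUMNS

EXCLUSION_KEYS = (
    "coarse_size",
    "min_time_initial",
    "min_time_fine",
    "consecutive_gaps",
    "distance_outlier_split",
    "gap_fraction",
    "size_percentile",
    "edge_margin",
    "max_duration_drop",
)

_EPS = 1e-9


@dataclass
class Track:
    """Time-ordered points of one selected ID; the unit of statistics."""

    track_id: int
    table: pd.DataFrame  # columns: time_s, x, y, width, height, angle_deg

    def __post_init__(self):
        t = self.table["time_s"].to_numpy()
        if len(t) and not (np.diff(t) > 0).all():
            raise ValueError(f"track {self.track_id}: time not strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.table)

    @property
    def duration_s(self) -> float:
        t = self.table["time_s"]
        return float(t.iloc[-1] - t.iloc[0]) if len(t) else 0.0

    @property
    def n_gap_points(self) -> int:
        return int(self._areas().eq(0).sum())

    def _areas(self) -> pd.Series:
        return self.table["width"] * self.table["height"]

    @property
    def mean_area_px2(self) -> float:
        areas = self._areas()
        nz = areas[areas > 0]
        return float(nz.mean()) if len(nz) else 0.0


@dataclass
class FilterReport:
    """Per-criterion exclusion ledger of one selection run."""

    tracks_in: int = 0
    tracks_accepted: int = 0
    split_events: int = 0
    distance_outlier_auto_disabled: bool = False
    exclusions: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in EXCLUSION_KEYS})

    def conservation_holds(self) -> bool:
        return self.tracks_in == self.tracks_accepted + sum(self.exclusions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("tracks_in", self.tracks_in),
                ("tracks_accepted", self.tracks_accepted),
                ("split_events", self.split_events),
                ("distance_outlier_auto_disabled",
                 int(self.distance_outlier_auto_disabled))]
        rows += list(self.exclusions.items())
        return pd.DataFrame(rows, columns=["criterion", "count"])

    def summary(self) -> str:
        parts = [f"{self.tracks_accepted}/{self.tracks_in} tracks accepted",
                 f"{self.split_events} splits"]
        if self.distance_outlier_auto_disabled:
            parts.append("distance-outlier splitting auto-disabled")
        parts += [f"{k}={v}" for k, v in self.exclusions.items() if v]
        return "; ".join(parts)


# ---------------------------------------------------------------- internals

def _frames(df: pd.DataFrame, fps: float) -> np.ndarray:
    return np.rint(df["time_s"].to_numpy() * fps).astype(np.int64)


def _duration(df: pd.DataFrame) -> float:
    t = df["time_s"].to_numpy()
    return float(t[-1] - t[0]) if len(t) > 1 else 0.0


def _coarse_check(df: pd.DataFrame, config: TrackerConfig) -> str | None:
    areas = (df["width"] * df["height"]).to_numpy()
    mean_area = float(areas.mean()) if len(areas) else 0.0
    lower = config.coarse_area_lower_frac * config.avg_bacterial_area_px2
    upper = config.coarse_area_upper_mult * config.avg_bacterial_area_px2
    if mean_area < lower or mean_area > upper:
        return "coarse_size"
    if config.min_track_time_s > 0 and _duration(df) < config.min_track_time_s - _EPS:
        return "min_time_initial"
    return None


def _scrub(df: pd.DataFrame, config: TrackerConfig) -> pd.DataFrame:
    areas = df["width"] * df["height"]
    keep = areas > 0
    df = df[keep]
    if config.point_area_outlier_mult > 1 and len(df):
        areas = (df["width"] * df["height"]).to_numpy()
        mean_area = areas.mean()  # over non-gap points, before removal
        df = df[areas <= config.point_area_outlier_mult * mean_area + _EPS]
    return df.reset_index(drop=True)


def _step_distances(df: pd.DataFrame) -> np.ndarray:
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    return np.hypot(np.diff(x), np.diff(y))


def _outer_fence(dists: np.ndarray) -> float:
    q1, q3 = np.percentile(dists, [25, 75])  # linear interpolation
    return float(q3 + 3.0 * (q3 - q1))


def _find_cuts(df: pd.DataFrame, config: TrackerConfig,
               outliers_on: bool) -> list[tuple[int, str]]:
    """Cut positions as ``(i, cause)``: cut between rows i and i+1."""
    cuts: dict[int, str] = {}
    frames = _frames(df, config.fps)
    if config.max_consecutive_gaps > 0:
        gap_runs = np.diff(frames) - 1
        for i in np.nonzero(gap_runs > config.max_consecutive_gaps)[0]:
            cuts[int(i)] = "consecutive_gaps"
    if outliers_on and len(df) >= 3:
        dists = _step_distances(df)
        fence = _outer_fence(dists)
        for i in np.nonzero(dists > fence + _EPS)[0]:
            cuts.setdefault(int(i), "distance_outlier_split")
    return sorted(cuts.items())


def _split_at(df: pd.DataFrame, cut_idx: list[int]) -> list[pd.DataFrame]:
    bounds = [0] + [i + 1 for i in cut_idx] + [len(df)]
    return [df.iloc[a:b].reset_index(drop=True)
            for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def _fine_check(df: pd.DataFrame, size_dist: np.ndarray,
                config: TrackerConfig) -> str | None:
    if config.min_track_time_s > 0 and _duration(df) < config.min_track_time_s - _EPS:
        return "min_time_fine"
    frames = _frames(df, config.fps)
    if config.max_consecutive_gaps > 0 and len(frames) > 1:
        if (np.diff(frames) - 1).max() > config.max_consecutive_gaps:
            return "consecutive_gaps"
    if 0 < config.max_gap_fraction < 1 and len(frames) > 1:
        expected = int(frames[-1] - frames[0] + 1)
        missing = expected - len(frames)
        if missing / expected > config.max_gap_fraction + _EPS:
            return "gap_fraction"
    if config.size_percentile > 0 and size_dist.size:
        p = config.size_percentile
        mean_area = float((df["width"] * df["height"]).mean())
        hi = float(np.percentile(size_dist, 100 - p))
        if mean_area > hi + _EPS:
            return "size_percentile"
        if config.size_percentile_two_sided:
            lo = float(np.percentile(size_dist, p))
            if mean_area < lo - _EPS:
                return "size_percentile"
    if config.edge_margin_frac > 0:
        mx = config.edge_margin_frac * config.frame_width
        my = config.edge_margin_frac * config.frame_height
        mean_x = float(df["x"].mean())
        mean_y = float(df["y"].mean())
        if (mean_x < mx or mean_x > config.frame_width - mx
                or mean_y < my or mean_y > config.frame_height - my):
            return "edge_margin"
    return None


@dataclass
class _Ctx:
    size_dist: np.ndarray
    outliers_on: bool
    split_events: int = 0
    first_split_cause: str | None = None


def _candidate_key(item) -> tuple:
    # longest duration; tie -> more points; tie -> earlier start
    _, dur, npts, t0 = item
    return (dur, npts, -t0)


def _process(df: pd.DataFrame, config: TrackerConfig, ctx: _Ctx
             ) -> tuple[list[pd.DataFrame], list[tuple]]:
    """Recursive pipeline for one segment.

    Returns ``(accepted segment tables, rejected candidates)`` where each
    rejected candidate is ``(criterion, duration, n_points, t_start)``.
    """
    t0 = float(df["time_s"].iloc[0]) if len(df) else 0.0
    crit = _coarse_check(df, config)
    if crit:
        return [], [(crit, _duration(df), len(df), t0)]
    sdf = _scrub(df, config)
    if len(sdf) < 2:
        return [], [("min_time_fine", _duration(sdf), len(sdf), t0)]
    cuts = _find_cuts(sdf, config, ctx.outliers_on)
    if cuts:
        ctx.split_events += len(cuts)
        if ctx.first_split_cause is None:
            ctx.first_split_cause = cuts[0][1]
        accepted, rejected = [], []
        for seg in _split_at(sdf, [i for i, _ in cuts]):
            a, r = _process(seg, config, ctx)
            accepted += a
            rejected += r
        return accepted, rejected
    crit = _fine_check(sdf, ctx.size_dist, config)
    t0 = float(sdf["time_s"].iloc[0])
    if crit:
        return [], [(crit, _duration(sdf), len(sdf), t0)]
    return [sdf], []


def _truncate(df: pd.DataFrame, config: TrackerConfig) -> pd.DataFrame | None:
    """Apply the maximum-duration limit; ``None`` means the track is dropped."""
    if config.max_track_time_s <= 0:
        return df
    if _duration(df) <= config.max_track_time_s + _EPS:
        return df  # never subject to shortening
    t = df["time_s"].to_numpy()
    limit = t[0] + config.max_track_time_s
    kept = df[df["time_s"] <= limit + _EPS].reset_index(drop=True)
    if config.drop_short_after_truncation:
        if _duration(kept) < config.max_track_time_s - _EPS:
            return None
    return kept


def _table_prepass(groups, config: TrackerConfig
                   ) -> tuple[np.ndarray, bool, int, int]:
    """Candidate mean-area distribution and distance-outlier statistics."""
    sizes = []
    total_steps = 0
    outlier_steps = 0
    for _, df in groups:
        if _coarse_check(df, config) is not None:
            continue
        sdf = _scrub(df, config)
        if len(sdf):
            sizes.append(float((sdf["width"] * sdf["height"]).mean()))
        if config.distance_outlier_enabled and len(sdf) >= 3:
            dists = _step_distances(sdf)
            fence = _outer_fence(dists)
            total_steps += dists.size
            outlier_steps += int((dists > fence + _EPS).sum())
    auto_disabled = False
    if config.distance_outlier_enabled and total_steps > 0:
        frac = outlier_steps / total_steps
        auto_disabled = frac > config.distance_outlier_auto_disable_frac
    return np.asarray(sizes), auto_disabled, total_steps, outlier_steps


def _check_sorted(table: pd.DataFrame) -> None:
    tid = table["track_id"].to_numpy()
    if len(tid) > 1 and (np.diff(tid) < 0).any():
        raise ValueError("raw track table must be sorted by track_id then time_s")


# --------------------------------------------------------------- public API

def select_tracks(table: pd.DataFrame,
                  config: TrackerConfig) -> tuple[list[Track], FilterReport]:
    """Run the full selection ledger over a raw track table."""
    _check_sorted(table)
    report = FilterReport()
    groups = list(table.groupby("track_id", sort=True))
    report.tracks_in = len(groups)
    size_dist, auto_disabled, _, _ = _table_prepass(groups, config)
    report.distance_outlier_auto_disabled = auto_disabled
    outliers_on = config.distance_outlier_enabled and not auto_disabled

    accepted_tracks: list[Track] = []
    for tid, df in groups:
        df = df.drop(columns="track_id").reset_index(drop=True)
        ctx = _Ctx(size_dist=size_dist, outliers_on=outliers_on)
        accepted, rejected = _process(df, config, ctx)
        report.split_events += ctx.split_events
        if accepted:
            items = [(seg, _duration(seg), len(seg), float(seg["time_s"].iloc[0]))
                     for seg in accepted]
            best = max(items, key=lambda it: (it[1], it[2], -it[3]))[0]
            final = _truncate(best, config)
            if final is None:
                report.exclusions["max_duration_drop"] += 1
            else:
                accepted_tracks.append(Track(int(tid), final))
                report.tracks_accepted += 1
        else:
            if ctx.first_split_cause is not None:
                crit = ctx.first_split_cause
            else:
                crit = max(rejected, key=_candidate_key)[0]
            report.exclusions[crit] += 1
    return accepted_tracks, report


def coarse_select(table: pd.DataFrame,
                  config: TrackerConfig) -> tuple[list[Track], FilterReport]:
    """Stage-one-only selection: whole-track size and minimum-time exclusion."""
    _check_sorted(table)
    report = FilterReport()
    survivors: list[Track] = []
    for tid, df in table.groupby("track_id", sort=True):
        report.tracks_in += 1
        crit = _coarse_check(df, config)
        if crit:
            report.exclusions[crit] += 1
        else:
            survivors.append(Track(
                int(tid), df.drop(columns="track_id").reset_index(drop=True)))
            report.tracks_accepted += 1
    return survivors, report


def scrub_points(track: Track, config: TrackerConfig) -> Track:
    """Remove gap placeholders and single-point area outliers."""
    return Track(track.track_id, _scrub(track.table, config))


def split_track(track: Track, config: TrackerConfig) -> list[Track]:
    """Cut a scrubbed track at oversized gap runs and distance outliers."""
    cuts = _find_cuts(track.table, config, config.distance_outlier_enabled)
    return [Track(track.track_id, seg)
            for seg in _split_at(track.table, [i for i, _ in cuts])]


def fine_select(segment: Track, size_dist: np.ndarray,
                config: TrackerConfig) -> str | None:
    """Fine per-segment checks; returns the failed criterion or ``None``."""
    return _fine_check(segment.table, np.asarray(size_dist), config)


def enforce_max_duration(track: Track, config: TrackerConfig) -> Track | None:
    """Truncate to ``max_track_time_s``; ``None`` if truncated-and-dropped."""
    out = _truncate(track.table, config)
    return None if out is None else Track(track.track_id, out)


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Selected tracks as one table in the raw CSV schema."""
    if not tracks:
        return pd.DataFrame(columns=RAW_COLUMNS)
    frames = []
    for tr in tracks:
        df = tr.table.copy()
        df.insert(0, "track_id", tr.track_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[RAW_COLUMNS]


def write_selected_csv(tracks: list[Track], path) -> Path:
    path = Path(path)
    tracks_to_table(tracks).to_csv(path, index=False, lineterminator="\n")
    return path


def write_report_csv(report: FilterReport, path) -> Path:
    path = Path(path)
    report.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path
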