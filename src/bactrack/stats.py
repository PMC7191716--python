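"""Per-track motility statistics.

Seven parameters per accepted track, in micrometres and seconds:

1. total travelled distance — sum of consecutive Euclidean steps;
2. mean speed — total distance / duration;
3. duration — last minus first timestamp;
4. maximum displacement — largest pairwise distance between positions;
5. percent motile — share of inter-point steps whose instantaneous speed
   reaches ``motile_speed_threshold_um_s``;
6. turn points per second — interior points whose heading change between the
   incoming and outgoing displacement exceeds ``turn_angle_threshold_deg``
   (steps shorter than ``turn_min_step_px`` or spanning a gap are not
   considered, and a run of consecutive over-threshold points counts as one
   turn event);
7. arc-chord ratio — path length / first-to-last straight-line distance
   (NaN for a closed path).

Positions are used as stored (the linker's filtered coordinates); no extra
smoothing is applied before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .config import TrackerConfig
from .selection import Track

STAT_COLUMNS = [
    "total_distance_um",
    "mean_speed_um_s",
    "duration_s",
    "max_displacement_um",
    "percent_motile",
    "turn_points_per_s",
    "arc_chord_ratio",
]

STAT_LABELS = {
    "total_distance_um": "total distance (µm)",
    "mean_speed_um_s": "speed (µm/s)",
    "duration_s": "duration (s)",
    "max_displacement_um": "max displacement (µm)",
    "percent_motile": "motile (% of time)",
    "turn_points_per_s": "turn points (1/s)",
    "arc_chord_ratio": "arc-chord ratio",
}


@dataclass
class TrackStats:
    track_id: int
    total_distance_um: float
    mean_speed_um_s: float
    duration_s: float
    max_displacement_um: float
    percent_motile: float
    turn_points_per_s: float
    arc_chord_ratio: float


def _positions(track: Track) -> tuple[np.ndarray, np.ndarray]:
    df = track.table
    areas = (df["width"] * df["height"]).to_numpy()
    keep = areas > 0
    if keep.all():
        sub = df
    else:  # tolerate unscrubbed tracks: ignore gap placeholders
        sub = df[keep]
    xy = sub[["x", "y"]].to_numpy(dtype=float)
    t = sub["time_s"].to_numpy(dtype=float)
    return xy, t


def percent_motile(track: Track, config: TrackerConfig) -> float:
    """Percentage of inter-point steps at or above the motile speed threshold."""
    xy, t = _positions(track)
    if len(xy) < 2:
        raise ValueError("percent_motile needs at least 2 points")
    steps_px = np.hypot(*np.diff(xy, axis=0).T)
    dt = np.diff(t)
    speeds = steps_px / config.px_per_um / dt
    return float((speeds >= config.motile_speed_threshold_um_s).mean() * 100.0)


def turn_points_per_second(track: Track, config: TrackerConfig) -> float:
    """Turn events per second of track duration.

    A turn point is an interior point whose adjacent displacement vectors
    are both at least ``turn_min_step_px`` long, span adjacent frames
    (heading across a gap is unreliable), and enclose an angle above
    ``turn_angle_threshold_deg``.
    """
    xy, t = _positions(track)
    if len(xy) < 3:
        raise ValueError("turn_points_per_second needs at least 3 points")
    frames = np.rint(t * config.fps).astype(np.int64)
    steps = np.diff(xy, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    adjacent = np.diff(frames) == 1
    v1, v2 = steps[:-1], steps[1:]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    dtheta = np.degrees(np.abs(np.arctan2(cross, dot)))
    usable = (adjacent[:-1] & adjacent[1:]
              & (lengths[:-1] >= config.turn_min_step_px)
              & (lengths[1:] >= config.turn_min_step_px))
    flagged = usable & (dtheta > config.turn_angle_threshold_deg)
    count = int(np.count_nonzero(flagged))
    duration = t[-1] - t[0]
    return float(count / duration) if duration > 0 else 0.0


def compute_track_stats(track: Track, config: TrackerConfig) -> TrackStats:
    """All seven motility parameters for one track."""
    xy, t = _positions(track)
    if len(xy) < 2:
        raise ValueError("compute_track_stats needs at least 2 points")
    ppu = config.px_per_um
    steps_px = np.hypot(*np.diff(xy, axis=0).T)
    total_um = float(steps_px.sum() / ppu)
    duration = float(t[-1] - t[0])
    speed = total_um / duration if duration > 0 else float("nan")
    max_disp = float(pdist(xy).max() / ppu)
    chord = float(np.hypot(*(xy[-1] - xy[0])) / ppu)
    arc_chord = total_um / chord if chord > 0 else float("nan")
    turns = (turn_points_per_second(track, config) if len(xy) >= 3
             else float("nan"))
    return TrackStats(
        track_id=track.track_id,
        total_distance_um=total_um,
        mean_speed_um_s=speed,
        duration_s=duration,
        max_displacement_um=max_disp,
        percent_motile=percent_motile(track, config),
        turn_points_per_s=turns,
        arc_chord_ratio=arc_chord,
    )


def compute_stats_table(tracks: list[Track], config: TrackerConfig) -> pd.DataFrame:
    """One row per track with the seven motility parameters."""
    rows = []
    for tr in tracks:
        if tr.n_points < 2:
            continue
        s = compute_track_stats(tr, config)
        rows.append([s.track_id] + [getattr(s, c) for c in STAT_COLUMNS])
    return pd.DataFrame(rows, columns=["track_id"] + STAT_COLUMNS)


def write_stats_csv(stats: pd.DataFrame, path) -> Path:
    path = Path(path)
    stats.to_csv(path, index=False, lineterminator="\n")
    return path


def collate_stats(csv_paths, xlsx_path) -> Path:
    """Optional convenience: bundle several stats CSVs into one workbook."""
    xlsx_path = Path(xlsx_path)
    with pd.ExcelWriter(xlsx_path) as writer:
        for p in csv_paths:
            p = Path(p)
            pd.read_csv(p).to_excel(writer, sheet_name=p.stem[:31], index=False)
    return xlsx_path
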