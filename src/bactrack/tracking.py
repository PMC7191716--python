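"""Least-distance track linking with a constant-velocity predictive filter.

Each tracked ID carries a finite-impulse-response state filter over its most
recent raw positions: a least-squares linear (constant-velocity) fit in
time, optionally with one Gaussian re-weighting pass that down-weights
measurements by their residual to the fitted trend.  The fit is exact on
linear motion, so noiseless straight swimming is reproduced measurement for
measurement, while isolated mis-detections are suppressed.  The fit also
yields the velocity estimate used to predict each ID's position in the next
frame.

Frame-to-frame association greedily joins the (prediction, detection) pair
with the smallest Euclidean distance until a gating radius — the largest
per-frame displacement a plausible swimmer can make — is exceeded.  IDs
without a match coast on their prediction and are written as gap points
(width = height = 0); IDs unmatched for longer than ``track_expiry_s``
seconds are retired, dropping any trailing gap points.  Detections without a
match open fresh, never-reused IDs.

The raw result is one row per (ID, frame) with the *filtered* position,
sorted by ID then time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TrackerConfig
from .detection import Detection

RAW_COLUMNS = ["track_id", "time_s", "x", "y", "width", "height", "angle_deg"]


@dataclass
class TrackPoint:
    """Per-frame filtered state of one tracked ID (one raw CSV row)."""

    track_id: int
    time_s: float
    x: float
    y: float
    width: float
    height: float
    angle_deg: float

    @property
    def gap(self) -> bool:
        return self.width == 0.0 and self.height == 0.0


@dataclass
class CVFilterState:
    """Constant-velocity FIR filter over a window of raw measurements."""

    window: int
    reweight: bool = True
    times: list[float] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    position: tuple[float, float] = (0.0, 0.0)
    velocity: tuple[float, float] = (0.0, 0.0)  # px / frame
    prediction: tuple[float, float] = (0.0, 0.0)

    def _fit(self, t_eval: float) -> tuple[float, float, float, float]:
        t = np.asarray(self.times)
        x = np.asarray(self.xs)
        y = np.asarray(self.ys)
        if len(t) == 1:
            return x[0], y[0], 0.0, 0.0
        tc = t - t[-1]
        w = np.ones_like(t)
        for _ in range(2 if self.reweight else 1):
            # closed-form weighted linear regression in time
            sw = w.sum()
            tm = (w * tc).sum() / sw
            var = (w * (tc - tm) ** 2).sum()
            if var <= 1e-18:  # degenerate: identical timestamps
                bx, by, vx, vy = x[-1], y[-1], 0.0, 0.0
                break
            xm = (w * x).sum() / sw
            ym = (w * y).sum() / sw
            vx = (w * (tc - tm) * (x - xm)).sum() / var
            vy = (w * (tc - tm) * (y - ym)).sum() / var
            bx = xm - vx * tm
            by = ym - vy * tm
            if not self.reweight:
                break
            rx = x - (bx + vx * (t - t[-1]))
            ry = y - (by + vy * (t - t[-1]))
            r2 = rx ** 2 + ry ** 2
            sigma2 = float(r2.mean())
            if sigma2 <= 1e-18:  # exact fit; weights stay uniform
                break
            w = np.exp(-r2 / (2.0 * sigma2))
        dt = t_eval - t[-1]
        return bx + vx * dt, by + vy * dt, vx, vy

    def step(self, frame_index: float,
             measurement: tuple[float, float] | None) -> tuple[float, float]:
        """Advance one frame; returns the filtered position for this frame."""
        if measurement is not None:
            self.times.append(frame_index)
            self.xs.append(measurement[0])
            self.ys.append(measurement[1])
            if len(self.times) > self.window:
                del self.times[0], self.xs[0], self.ys[0]
            px, py, vx, vy = self._fit(frame_index)
            self.position = (px, py)
            self.velocity = (vx, vy)
            self.prediction = (px + vx, py + vy)
        else:
            self.position = self.prediction
            self.prediction = (self.prediction[0] + self.velocity[0],
                               self.prediction[1] + self.velocity[1])
        return self.position


def cv_filter_step(state: CVFilterState, frame_index: float,
                   measurement: tuple[float, float] | None
                   ) -> tuple[tuple[float, float], tuple[float, float], CVFilterState]:
    """Functional wrapper: returns (filtered position, next-frame prediction, state)."""
    pos = state.step(frame_index, measurement)
    return pos, state.prediction, state


def match_detections(predictions: list[tuple[int, float, float]],
                     detections: list[Detection],
                     config: TrackerConfig
                     ) -> tuple[dict[int, int], list[int], list[int]]:
    """Greedy globally-least-distance assignment with a gating radius.

    Repeatedly binds the closest (prediction, detection) pair and removes
    both, until either side runs out or the smallest remaining distance
    exceeds the gate.  Ties break deterministically by (ID, detection index).
    Returns ``(assignment {id -> detection index}, unmatched ids, unmatched
    detection indices)``.
    """
    gate = config.max_linking_speed_um_s * config.px_per_um / config.fps
    if not predictions or not detections:
        return {}, sorted(p[0] for p in predictions), list(range(len(detections)))
    # rows sorted by id so that np.argmin's first-occurrence rule implements
    # the deterministic (id, detection order) tie-break
    preds = sorted(predictions, key=lambda p: p[0])
    ids = [p[0] for p in preds]
    pred_xy = np.array([[p[1], p[2]] for p in preds])
    det_xy = np.array([[d.centre_x, d.centre_y] for d in detections])
    dist = np.linalg.norm(pred_xy[:, None, :] - det_xy[None, :, :], axis=2)
    assignment: dict[int, int] = {}
    work = dist.copy()
    n_pairs = min(len(ids), len(detections))
    for _ in range(n_pairs):
        flat = int(np.argmin(work))
        i, j = divmod(flat, work.shape[1])
        if not np.isfinite(work[i, j]) or work[i, j] > gate:
            break
        assignment[ids[i]] = j
        work[i, :] = np.inf
        work[:, j] = np.inf
    unmatched_ids = sorted(tid for tid in ids if tid not in assignment)
    matched_dets = set(assignment.values())
    unmatched_dets = [j for j in range(len(detections)) if j not in matched_dets]
    return assignment, unmatched_ids, unmatched_dets


@dataclass
class _TrackRecord:
    filter: CVFilterState
    points: list[TrackPoint] = field(default_factory=list)
    frames_since_last_detection: int = 0
    last_angle: float = 0.0


class Tracker:
    """Stateful frame-by-frame multi-object tracker."""

    def __init__(self, config: TrackerConfig):
        self.config = config
        self.active: dict[int, _TrackRecord] = {}
        self.finished: list[list[TrackPoint]] = []
        self._next_id = 0
        self._last_frame: int | None = None
        # retire an ID once its gap exceeds the expiry horizon
        self._max_gap_frames = int(np.floor(config.track_expiry_s * config.fps + 1e-9))

    def step(self, detections: list[Detection], frame_index: int) -> None:
        if self._last_frame is not None and frame_index <= self._last_frame:
            raise ValueError(
                f"frames must be presented in order (got {frame_index} after "
                f"{self._last_frame})"
            )
        self._last_frame = frame_index
        time_s = frame_index / self.config.fps
        predictions = [
            (tid, rec.filter.prediction[0], rec.filter.prediction[1])
            if rec.points else (tid, *rec.filter.position)
            for tid, rec in self.active.items()
        ]
        assignment, unmatched_ids, unmatched_dets = match_detections(
            predictions, detections, self.config)

        for tid, j in assignment.items():
            det = detections[j]
            rec = self.active[tid]
            pos = rec.filter.step(frame_index, (det.centre_x, det.centre_y))
            rec.frames_since_last_detection = 0
            rec.last_angle = det.angle_deg
            rec.points.append(TrackPoint(tid, time_s, pos[0], pos[1],
                                         det.width, det.height, det.angle_deg))

        for tid in unmatched_ids:
            rec = self.active[tid]
            pos = rec.filter.step(frame_index, None)
            rec.frames_since_last_detection += 1
            rec.points.append(TrackPoint(tid, time_s, pos[0], pos[1],
                                         0.0, 0.0, rec.last_angle))
            if rec.frames_since_last_detection > self._max_gap_frames:
                self._retire(tid)

        for j in unmatched_dets:
            det = detections[j]
            tid = self._next_id
            self._next_id += 1
            filt = CVFilterState(window=self.config.filter_window,
                                 reweight=self.config.filter_reweight)
            pos = filt.step(frame_index, (det.centre_x, det.centre_y))
            self.active[tid] = _TrackRecord(filter=filt, last_angle=det.angle_deg)
            self.active[tid].points.append(
                TrackPoint(tid, time_s, pos[0], pos[1],
                           det.width, det.height, det.angle_deg))

    def _retire(self, tid: int) -> None:
        rec = self.active.pop(tid)
        points = rec.points
        while points and points[-1].gap:  # trailing coasting is extrapolation
            points.pop()
        if points:
            self.finished.append(points)

    def flush(self, out_path=None) -> pd.DataFrame:
        """Finalise all tracks; return (and optionally write) the raw table."""
        for tid in sorted(self.active):
            self._retire(tid)
        rows = [
            (p.track_id, p.time_s, p.x, p.y, p.width, p.height, p.angle_deg)
            for points in self.finished for p in points
        ]
        table = pd.DataFrame(rows, columns=RAW_COLUMNS)
        table.sort_values(["track_id", "time_s"], inplace=True, kind="mergesort")
        table.reset_index(drop=True, inplace=True)
        if out_path is not None:
            write_raw_csv(table, out_path)
        return table


def write_raw_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    try:
        table.to_csv(path, index=False, columns=RAW_COLUMNS, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write track table to {path}: {exc}") from exc
    return path


def read_raw_csv(path) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is byte-identical
    return pd.read_csv(path, float_precision="round_trip")


def track_detections(frames_detections, config: TrackerConfig,
                     out_path=None) -> pd.DataFrame:
    """Run the tracker over per-frame detection lists (frame order = list order)."""
    tracker = Tracker(config)
    for frame_index, dets in enumerate(frames_detections):
        tracker.step(dets, frame_index)
    return tracker.flush(out_path)
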