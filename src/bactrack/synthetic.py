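"""Synthetic run-and-tumble scenes with known ground truth.

The generator produces what a 10x-objective, 30 fps recording of a dilute
suspension of swimming bacteria looks like to this pipeline: dark (or
bright) ellipsoidal bodies of a few tens of px^2 over a noisy uniform
background.  Motion is the classic run-and-tumble model — straight runs at
constant speed, interrupted by a Poisson process of instantaneous
reorientations — plus an optional immotile fraction that only jitters in
place.  Every scene carries its exact per-frame ground truth, so detection,
linking, selection and statistics can all be scored against known answers.

Trajectories reflect off the frame border (or, with ``min_separation_px``
set, off a per-cell territory boundary, which guarantees a minimum pairwise
distance between objects — the regime in which identity-preserving linking
can be required to be perfect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TrackerConfig
from .video_io import AviWriter

GROUND_TRUTH_COLUMNS = ["frame", "true_id", "x", "y", "angle_deg", "motile"]


@dataclass
class MotionParams:
    """Parameters of a simulated scene.

    Defaults describe a moderately dense field of healthy swimmers: 50 cells
    at 20 um/s tumbling at 0.5 Hz for 30 s.  ``tumble_angle_dispersion_deg``
    is the standard deviation of the (wrapped normal) reorientation draw; the
    broad 150 deg default approximates the near-uniform tumble angles of a
    peritrichously flagellated swimmer.
    """

    n_bacteria: int = 50
    speed_um_s: float = 20.0
    tumble_rate_hz: float = 0.5
    tumble_angle_dispersion_deg: float = 150.0
    frac_immotile: float = 0.0
    body_length_px: float = 7.0
    body_width_px: float = 3.0
    duration_s: float = 30.0
    seed: int = 0
    jitter_px: float = 0.1
    min_separation_px: float | None = None

    def validate(self) -> None:
        errors = []
        if not (isinstance(self.n_bacteria, (int, np.integer)) and self.n_bacteria >= 0):
            errors.append("n_bacteria must be a non-negative integer")
        if self.speed_um_s < 0:
            errors.append("speed_um_s must be >= 0")
        if self.tumble_rate_hz < 0:
            errors.append("tumble_rate_hz must be >= 0")
        if not 0 <= self.frac_immotile <= 1:
            errors.append("frac_immotile must be in [0, 1]")
        if not self.body_length_px > 0 or not self.body_width_px > 0:
            errors.append("body dimensions must be > 0")
        if not self.duration_s > 0:
            errors.append("duration_s must be > 0")
        if self.jitter_px < 0:
            errors.append("jitter_px must be >= 0")
        if self.min_separation_px is not None and not self.min_separation_px > 0:
            errors.append("min_separation_px must be > 0 when set")
        if errors:
            raise ValueError("invalid MotionParams: " + "; ".join(errors))


def _territories(params: MotionParams, config: TrackerConfig) -> np.ndarray:
    """Per-bacterium reflecting boxes ``(x0, y0, x1, y1)``.

    With ``min_separation_px`` set, the frame is split into a grid of cells
    and each bacterium is confined to a shrunken core of its own cell, so any
    two objects stay at least ``min_separation_px`` apart at all times.
    """
    w, h = float(config.frame_width), float(config.frame_height)
    n = params.n_bacteria
    margin = params.body_length_px
    if params.min_separation_px is None:
        box = np.array([margin, margin, w - margin, h - margin])
        return np.tile(box, (n, 1))
    n_cols = max(1, int(math.ceil(math.sqrt(n * w / h))))
    n_rows = int(math.ceil(n / n_cols))
    cell_w, cell_h = w / n_cols, h / n_rows
    pad = params.min_separation_px / 2.0 + margin
    if 2 * pad >= min(cell_w, cell_h):
        raise ValueError(
            f"min_separation_px={params.min_separation_px} too large for "
            f"{n} bacteria in a {w:.0f}x{h:.0f} frame"
        )
    boxes = np.empty((n, 4))
    for i in range(n):
        r, c = divmod(i, n_cols)
        boxes[i] = (c * cell_w + pad, r * cell_h + pad,
                    (c + 1) * cell_w - pad, (r + 1) * cell_h - pad)
    return boxes


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray,
             heading: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Specular reflection of out-of-box positions; preserves step length."""
    vx = np.cos(np.radians(heading))
    vy = np.sin(np.radians(heading))
    for axis, vel in ((0, vx), (1, vy)):
        low, high = lo[:, axis], hi[:, axis]
        p = pos[:, axis]
        under, over = p < low, p > high
        p[under] = 2 * low[under] - p[under]
        p[over] = 2 * high[over] - p[over]
        vel[under | over] *= -1
        # second pass in case a long step crosses the whole (narrow) box
        np.clip(p, low, high, out=p)
    heading[:] = np.degrees(np.arctan2(vy, vx))
    return pos, heading


def simulate_tracks(params: MotionParams, config: TrackerConfig) -> pd.DataFrame:
    """Simulate ground-truth trajectories.

    Returns a DataFrame with columns ``frame, true_id, x, y, angle_deg,
    motile`` (one row per object per frame), deterministic for a fixed seed.
    """
    params.validate()
    n_frames = int(round(params.duration_s * config.fps))
    if n_frames < 2:
        raise ValueError("duration_s x fps must cover at least 2 frames")
    n = params.n_bacteria
    rng = np.random.default_rng(params.seed)
    step_px = params.speed_um_s * config.px_per_um / config.fps
    p_tumble = 1.0 - math.exp(-params.tumble_rate_hz / config.fps)

    boxes = _territories(params, config)
    lo, hi = boxes[:, :2], boxes[:, 2:]
    pos = lo + rng.random((n, 2)) * (hi - lo)
    anchor = pos.copy()
    heading = rng.uniform(0.0, 360.0, size=n)
    n_immotile = int(round(params.frac_immotile * n))
    immotile = np.zeros(n, dtype=bool)
    if n_immotile:
        immotile[rng.permutation(n)[:n_immotile]] = True
    motile = ~immotile

    frames = np.empty((n_frames, n, 2))
    angles = np.empty((n_frames, n))
    frames[0] = pos
    angles[0] = heading % 180.0
    for k in range(1, n_frames):
        tumbling = motile & (rng.random(n) < p_tumble)
        if tumbling.any():
            heading[tumbling] += rng.normal(
                0.0, params.tumble_angle_dispersion_deg, size=int(tumbling.sum())
            )
        step = np.zeros((n, 2))
        step[motile, 0] = step_px * np.cos(np.radians(heading[motile]))
        step[motile, 1] = step_px * np.sin(np.radians(heading[motile]))
        pos = pos + step
        if immotile.any():
            pos[immotile] = anchor[immotile] + rng.normal(
                0.0, params.jitter_px, size=(int(immotile.sum()), 2)
            )
        pos, heading = _reflect(pos, lo, hi, heading)
        frames[k] = pos
        angles[k] = heading % 180.0

    frame_idx = np.repeat(np.arange(n_frames), n)
    ids = np.tile(np.arange(n), n_frames)
    table = pd.DataFrame({
        "frame": frame_idx,
        "true_id": ids,
        "x": frames[:, :, 0].ravel(),
        "y": frames[:, :, 1].ravel(),
        "angle_deg": angles.ravel(),
        "motile": np.tile(motile, n_frames),
    })
    return table


def render_frame(truth_rows: pd.DataFrame, params: MotionParams,
                 config: TrackerConfig) -> np.ndarray:
    """Rasterise one frame's objects as filled rotated ellipses (no noise)."""
    w, h = config.frame_width, config.frame_height
    if config.bacteria_brighter_than_background:
        bg, fg = 55, 195
    else:
        bg, fg = 200, 60
    frame = np.full((h, w), bg, dtype=np.uint8)
    a = params.body_length_px / 2.0
    b = params.body_width_px / 2.0
    for x, y, ang in zip(truth_rows["x"], truth_rows["y"], truth_rows["angle_deg"]):
        x0 = max(0, int(math.floor(x - a - 1)))
        x1 = min(w - 1, int(math.ceil(x + a + 1)))
        y0 = max(0, int(math.floor(y - a - 1)))
        y1 = min(h - 1, int(math.ceil(y + a + 1)))
        if x1 < x0 or y1 < y0:
            continue
        xs = np.arange(x0, x1 + 1) - x
        ys = np.arange(y0, y1 + 1) - y
        dx, dy = np.meshgrid(xs, ys)
        theta = math.radians(ang)
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        frame[y0:y1 + 1, x0:x1 + 1][inside] = fg
    return frame


def render_video(truth: pd.DataFrame, params: MotionParams, config: TrackerConfig,
                 noise_sd: float, out_path, codec: str = "MJPG") -> tuple[Path, Path]:
    """Render a ground-truth table as a noisy greyscale AVI.

    Additive Gaussian pixel noise with standard deviation ``noise_sd`` is
    applied after rasterisation (seeded from ``params.seed``).  The ground
    truth is written as CSV next to the video (``<stem>_truth.csv``).
    Returns ``(video_path, truth_csv_path)``.
    """
    out_path = Path(out_path)
    truth_path = out_path.with_name(out_path.stem + "_truth.csv")
    noise_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA11CE]))
    n_frames = int(truth["frame"].max()) + 1 if len(truth) else int(
        round(params.duration_s * config.fps))
    by_frame = dict(tuple(truth.groupby("frame"))) if len(truth) else {}
    shape = (config.frame_height, config.frame_width)
    try:
        writer = AviWriter(out_path, config.fps, shape, codec=codec)
    except OSError as exc:  # pragma: no cover - path errors surface at close
        raise OSError(f"cannot open {out_path} for writing: {exc}") from exc
    with writer:
        for k in range(n_frames):
            rows = by_frame.get(k)
            if rows is None:
                frame = np.full(shape, 200 if not config.bacteria_brighter_than_background
                                else 55, dtype=np.uint8)
            else:
                frame = render_frame(rows, params, config)
            if noise_sd > 0:
                noisy = frame.astype(np.float64) + noise_rng.normal(0, noise_sd, shape)
                frame = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
            writer.add(frame)
    write_ground_truth(truth, truth_path)
    return out_path, truth_path


def write_ground_truth(truth: pd.DataFrame, path) -> Path:
    """Write the ground-truth table (comma separated, '.' decimal)."""
    path = Path(path)
    out = truth.copy()
    out["motile"] = out["motile"].astype(int)
    out.to_csv(path, index=False, columns=GROUND_TRUTH_COLUMNS)
    return path


def read_ground_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, float_precision="round_trip")
    truth["motile"] = truth["motile"].astype(bool)
    return truth


def make_scene(params: MotionParams, config: TrackerConfig, noise_sd: float,
               out_path, codec: str = "MJPG") -> tuple[Path, Path, pd.DataFrame]:
    """Convenience: simulate + render in one call."""
    truth = simulate_tracks(params, config)
    video, truth_csv = render_video(truth, params, config, noise_sd, out_path,
                                    codec=codec)
    return video, truth_csv, truth
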