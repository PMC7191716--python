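"""Persistent artefacts: annotated overlay video and the plot families."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib import colors  # noqa: E402
from PIL import Image, ImageDraw  # noqa: E402

from .config import TrackerConfig  # noqa: E402
from .selection import Track  # noqa: E402
from .stats import STAT_COLUMNS, STAT_LABELS  # noqa: E402
from .video_io import AviWriter  # noqa: E402

TRAIL_SECONDS = 2.0  # length of the recent-positions trail in the overlay
DISTANCE_COLORMAP = "viridis"  # track colour ~ min-max normalised distance


@dataclass
class RunArtifacts:
    """Paths of everything one pipeline run wrote (absent flags stay None)."""

    video: Path
    raw_csv: Path | None = None
    selected_csv: Path | None = None
    stats_csv: Path | None = None
    report_csv: Path | None = None
    overlay_video: Path | None = None
    plots: list[Path] = field(default_factory=list)
    log_file: Path | None = None


def _rect_corners(x, y, w, h, angle_deg):
    theta = np.radians(angle_deg)
    dx = np.array([np.cos(theta), np.sin(theta)]) * w / 2.0
    dy = np.array([-np.sin(theta), np.cos(theta)]) * h / 2.0
    c = np.array([x, y])
    return [tuple(c - dx - dy), tuple(c + dx - dy), tuple(c + dx + dy),
            tuple(c - dx + dy)]


def write_overlay_video(frames, table: pd.DataFrame, out_path,
                        config: TrackerConfig, codec: str = "MJPG") -> Path:
    """Annotate frames with live rectangles, ID labels and recent trails.

    ``frames`` is an iterable of uint8 frames (grey or RGB) from the same
    run as ``table`` (a raw or selected track table).  Output frame count
    equals input frame count.
    """
    out_path = Path(out_path)
    by_frame: dict[int, pd.DataFrame] = {}
    if len(table):
        idx = np.rint(table["time_s"].to_numpy() * config.fps).astype(np.int64)
        for k, sub in table.groupby(idx):
            by_frame[int(k)] = sub
    trail_frames = int(round(TRAIL_SECONDS * config.fps))
    history: dict[int, list[tuple[float, float]]] = {}
    writer = None
    try:
        for k, frame in enumerate(frames):
            frame = np.asarray(frame)
            if frame.ndim == 2:
                img = Image.fromarray(frame, "L").convert("RGB")
            else:
                img = Image.fromarray(frame, "RGB")
            if writer is None:
                writer = AviWriter(out_path, config.fps,
                                   (img.height, img.width, 3), codec=codec)
            draw = ImageDraw.Draw(img)
            rows = by_frame.get(k)
            if rows is not None:
                for row in rows.itertuples(index=False):
                    tid = int(row.track_id)
                    history.setdefault(tid, []).append((row.x, row.y))
                    history[tid] = history[tid][-trail_frames:]
                    if len(history[tid]) > 1:
                        draw.line(history[tid], fill=(60, 120, 255), width=1)
                    if row.width > 0 or row.height > 0:
                        draw.polygon(
                            _rect_corners(row.x, row.y, row.width, row.height,
                                          row.angle_deg),
                            outline=(255, 80, 40))
                    draw.text((row.x + 3, row.y + 3), str(tid),
                              fill=(255, 200, 0))
            writer.add(np.asarray(img))
    finally:
        if writer is not None:
            writer.close()
    if writer is None:
        raise ValueError("no frames to annotate")
    return out_path


def track_distance_colors(tracks: list[Track], config: TrackerConfig,
                          cmap: str = DISTANCE_COLORMAP) -> dict[int, tuple]:
    """Map each track to ``(distance_um, rgba)`` by min-max normalised distance."""
    dists = {}
    for tr in tracks:
        xy = tr.table[["x", "y"]].to_numpy()
        steps = np.hypot(*np.diff(xy, axis=0).T) if len(xy) > 1 else np.array([0.0])
        dists[tr.track_id] = float(steps.sum() / config.px_per_um)
    if not dists:
        return {}
    vals = np.array(list(dists.values()))
    norm = colors.Normalize(vmin=vals.min(), vmax=max(vals.max(), vals.min() + 1e-12))
    mapper = matplotlib.colormaps[cmap]
    return {tid: (d, mapper(norm(d))) for tid, d in dists.items()}


def plot_tracks(tracks: list[Track], mode: str, out_path,
                config: TrackerConfig) -> Path:
    """Coordinate plot (native positions, start markers) or rose plot
    (every track translated to start at the origin); colour encodes total
    travelled distance."""
    if mode not in ("coordinate", "rose"):
        raise ValueError(f"mode must be 'coordinate' or 'rose', got {mode!r}")
    out_path = Path(out_path)
    colour_map = track_distance_colors(tracks, config)
    fig, ax = plt.subplots(figsize=(6, 6))
    for tr in tracks:
        xy = tr.table[["x", "y"]].to_numpy() / config.px_per_um
        if mode == "rose":
            xy = xy - xy[0]
        _, rgba = colour_map[tr.track_id]
        ax.plot(xy[:, 0], xy[:, 1], color=rgba, linewidth=0.8)
        if mode == "coordinate":
            ax.plot(xy[0, 0], xy[0, 1], marker="o", markersize=3, color=rgba)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal", adjustable="datalim")
    ax.invert_yaxis()  # image convention: y grows downward
    ax.set_title("tracks" if mode == "coordinate" else "rose plot (start at origin)")
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_violin(stats: pd.DataFrame, out_path,
                parameters: list[str] | None = None) -> Path:
    """Violin plot per motility parameter over all tracks."""
    if stats is None or len(stats) == 0:
        raise ValueError("no statistics rows to plot")
    parameters = parameters or STAT_COLUMNS
    unknown = set(parameters) - set(STAT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    out_path = Path(out_path)
    n = len(parameters)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 4), squeeze=False)
    for ax, param in zip(axes[0], parameters):
        vals = stats[param].dropna().to_numpy()
        if len(vals) > 1 and np.ptp(vals) > 0:
            ax.violinplot(vals, showmedians=True)
        elif len(vals):  # degenerate distribution still renders
            ax.plot([1] * len(vals), vals, "o", color="tab:blue")
        ax.set_xticks([])
        ax.set_ylabel(STAT_LABELS[param])
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
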