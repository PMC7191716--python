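"""Per-frame bacterium detection by grey value.

The default pipeline for one frame is: grey conversion, a small Gaussian
blur, an adaptive Gaussian threshold that turns potential bacteria white
(candidates), a second adaptive threshold with a stricter offset (markers),
and a gate that keeps only those connected candidate regions containing at
least one marker pixel.  Each surviving region becomes a `Detection` whose
rectangle is either the minimum-area rotated rectangle (rod-shaped cells) or
the axis-aligned bounding box (coccoid cells); the rectangle centre (the
"tracking target") is the coordinate used for linking.

Two simpler alternatives are available: ``adaptive_simple`` (the candidate
threshold without marker gating) and ``global_rolling`` (one global
threshold per frame from the frame's mean grey value and standard deviation,
smoothed by a moving average over a few seconds to damp flicker).

Coordinate convention: origin at the centre of the top-left pixel, x to the
right, y downward; frame indices 0-based; ``time = frame_index / fps``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely import MultiPoint

from .config import TrackerConfig
from .video_io import to_grey


@dataclass
class Detection:
    """One bacterium candidate in one frame."""

    frame_index: int
    centre_x: float
    centre_y: float
    width: float
    height: float
    angle_deg: float  # rotation of the width axis, [0, 180); 0 in coccoid mode

    @property
    def area_px2(self) -> float:
        return self.width * self.height


def _gaussian_kernel_1d(ksize: int) -> np.ndarray:
    # the conventional ksize -> sigma mapping for small smoothing kernels
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2
    k = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def _gaussian_smooth(img: np.ndarray, ksize: int) -> np.ndarray:
    k = _gaussian_kernel_1d(ksize).astype(np.float32)
    out = ndimage.correlate1d(img.astype(np.float32), k, axis=0, mode="mirror")
    return ndimage.correlate1d(out, k, axis=1, mode="mirror", output=out)


def preprocess_frame(frame: np.ndarray, config: TrackerConfig) -> np.ndarray:
    """Grey conversion followed by a ``blur_kernel`` Gaussian blur (uint8)."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.dtype != np.uint8:
        raise ValueError(f"expected 8-bit frame, got dtype {frame.dtype}")
    grey = to_grey(frame)
    blurred = _gaussian_smooth(grey, config.blur_kernel)
    return np.clip(np.rint(blurred), 0, 255).astype(np.uint8)


def _adaptive_mask(grey: np.ndarray, ksize: int, offset: float,
                   brighter: bool, local_mean: np.ndarray | None = None
                   ) -> np.ndarray:
    """Adaptive Gaussian threshold; bacteria-coloured pixels become True."""
    if local_mean is None:
        local_mean = _gaussian_smooth(grey, ksize)
    g = grey.astype(np.float32)
    if brighter:
        return g > local_mean + np.float32(offset)
    return g < local_mean - np.float32(offset)


def marker_gated_threshold(grey: np.ndarray, config: TrackerConfig) -> np.ndarray:
    """Dual-threshold detection mask.

    Candidate regions come from the adaptive threshold at ``adaptive_offset``;
    a stricter threshold at ``marker_offset`` produces markers.  Only
    candidate regions containing at least one marker pixel survive.
    """
    if grey.ndim != 2:
        raise ValueError("marker_gated_threshold expects a single-channel image")
    brighter = config.bacteria_brighter_than_background
    local_mean = _gaussian_smooth(grey, config.adaptive_kernel)
    candidates = _adaptive_mask(grey, config.adaptive_kernel,
                                config.adaptive_offset, brighter, local_mean)
    markers = _adaptive_mask(grey, config.adaptive_kernel,
                             config.marker_offset, brighter, local_mean)
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(candidates)
    marked = np.zeros(n + 1, dtype=bool)
    marked[np.unique(labels[markers & candidates])] = True
    marked[0] = False
    return marked[labels]


def adaptive_simple_threshold(grey: np.ndarray, config: TrackerConfig) -> np.ndarray:
    """Candidate mask only — the marker gate is skipped."""
    if grey.ndim != 2:
        raise ValueError("adaptive_simple_threshold expects a single-channel image")
    return _adaptive_mask(grey, config.adaptive_kernel, config.adaptive_offset,
                          config.bacteria_brighter_than_background)


@dataclass
class RollingThresholdState:
    """Per-frame (mean, SD) grey statistics over the rolling window."""

    maxlen: int
    buffer: deque = field(default_factory=deque)
    last_threshold: float | None = None

    @classmethod
    def for_config(cls, config: TrackerConfig) -> "RollingThresholdState":
        return cls(maxlen=int(np.ceil(config.rolling_window_s * config.fps)))

    def push(self, mean: float, sd: float) -> None:
        self.buffer.append((mean, sd))
        while len(self.buffer) > self.maxlen:
            self.buffer.popleft()


def global_rolling_threshold(grey: np.ndarray, state: RollingThresholdState,
                             config: TrackerConfig) -> np.ndarray:
    """One global threshold from frame statistics, smoothed over the window.

    The per-frame threshold contribution is ``mean + s * global_offset * SD``
    where ``s`` is +1 for bright bacteria and -1 for dark ones; the applied
    threshold is the mean of these contributions over the last
    ``rolling_window_s`` seconds (including the current frame).
    """
    if grey.ndim != 2:
        raise ValueError("global_rolling_threshold expects a single-channel image")
    sign = 1.0 if config.bacteria_brighter_than_background else -1.0
    state.push(float(grey.mean()), float(grey.std()))
    t = float(np.mean([m + sign * config.global_offset * s for m, s in state.buffer]))
    state.last_threshold = t
    if config.bacteria_brighter_than_background:
        return grey.astype(np.float64) > t
    return grey.astype(np.float64) < t


def _min_area_rect(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float, float, float]:
    """Minimum-area rotated rectangle over the pixel *corner* points.

    Returns ``(cx, cy, width, height, angle_deg)`` with width >= height and
    the angle of the width axis in [0, 180).  Using pixel corners (each pixel
    spans +-0.5 around its centre) makes an axis-aligned n x m pixel block
    measure exactly n x m.
    """
    corners = np.empty((rows.size * 4, 2))
    for i, (dr, dc) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        corners[i::4, 0] = cols + dc
        corners[i::4, 1] = rows + dr
    rect = MultiPoint(corners).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    if l1 >= l2:
        width, height, axis = l1, l2, e1
    else:
        width, height, axis = l2, l1, e2
    angle = np.degrees(np.arctan2(axis[1], axis[0])) % 180.0
    cx, cy = xy.mean(axis=0)
    return float(cx), float(cy), float(width), float(height), float(angle)


def extract_detections(mask: np.ndarray, frame_index: int,
                       config: TrackerConfig) -> list[Detection]:
    """One Detection per 8-connected white region of ``mask``.

    Rod-shaped mode fits the minimum-area rotated rectangle; coccoid mode
    uses the axis-aligned bounding box with angle 0.  The returned list is
    sorted by (centre_y, centre_x).
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool),
                              structure=np.ones((3, 3), dtype=int))
    detections: list[Detection] = []
    if n == 0:
        return detections
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        region = labels[sl] == lab
        rows, cols = np.nonzero(region)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        if config.rod_shaped and rows.size > 1:
            cx, cy, w, h, ang = _min_area_rect(rows, cols)
        else:
            r0, r1 = rows.min(), rows.max()
            c0, c1 = cols.min(), cols.max()
            w = float(c1 - c0 + 1)
            h = float(r1 - r0 + 1)
            cx, cy = (c0 + c1) / 2.0, (r0 + r1) / 2.0
            ang = 0.0
        detections.append(Detection(frame_index, float(cx), float(cy), w, h, ang))
    detections.sort(key=lambda d: (d.centre_y, d.centre_x))
    return detections


def detect_frame(frame: np.ndarray, frame_index: int,
                 state: RollingThresholdState | None,
                 config: TrackerConfig) -> list[Detection]:
    """Full single-frame detection, dispatching on ``config.detection_mode``."""
    grey = preprocess_frame(frame, config)
    mode = config.detection_mode
    if mode == "marker_gated":
        mask = marker_gated_threshold(grey, config)
    elif mode == "adaptive_simple":
        mask = adaptive_simple_threshold(grey, config)
    elif mode == "global_rolling":
        if state is None:
            raise ValueError("global_rolling mode needs a RollingThresholdState")
        mask = global_rolling_threshold(grey, state, config)
    else:  # pragma: no cover - config validation rejects this earlier
        raise ValueError(f"unknown detection_mode {mode!r}")
    return extract_detections(mask, frame_index, config)
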