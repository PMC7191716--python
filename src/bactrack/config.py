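"""Settings file ("tracking.ini") handling.

Every stage of the pipeline — detection, linking, track selection, statistics,
output — is parameterised through a single INI file.  The dialect is
deliberately permissive: keys are case-insensitive, ``#`` and ``;`` start
comments, booleans are written ``true``/``false``.  Unknown keys warn instead
of failing so that a settings file can travel between versions.

The numeric conventions used throughout the package:

* ``px_per_um`` converts micrometres to pixels (px = um * px_per_um).
* Times are seconds, frame indices are 0-based, ``time_s = frame / fps``.
* A selection criterion with value 0 (or an empty string) is disabled.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

DETECTION_MODES = ("marker_gated", "adaptive_simple", "global_rolling")

#: Default expected bounding-rectangle area (px^2) seeded by cell shape.
#: A rod of ~7x3 px (10x objective, small bacillus) has a rectangle area near
#: 20 px^2; a coccus of ~4 px diameter sits near 12 px^2.
DEFAULT_AVG_AREA_ROD = 20.0
DEFAULT_AVG_AREA_COCCOID = 12.0


class ConfigError(ValueError):
    """Raised when a settings file is missing, malformed, or inconsistent."""


@dataclass
class TrackerConfig:
    """All user-settable parameters of the tracking pipeline."""

    # --- basic (required in a settings file) ---
    px_per_um: float = 3.0
    fps: float = 30.0
    frame_width: int = 1024
    frame_height: int = 1024
    bacteria_brighter_than_background: bool = False
    rod_shaped: bool = True
    avg_bacterial_area_px2: float = DEFAULT_AVG_AREA_ROD
    video_paths: list[str] = field(default_factory=list)

    # --- detection ---
    detection_mode: str = "marker_gated"
    blur_kernel: int = 3
    adaptive_kernel: int = 11
    adaptive_offset: float = 5.0
    marker_offset: float = 10.0  # stricter than adaptive_offset
    global_offset: float = 2.0  # in frame-SD units, global_rolling mode
    rolling_window_s: float = 5.0

    # --- tracking ---
    track_expiry_s: float = 1.0
    # Gating radius for assignment, expressed as a top apparent speed.  Set
    # this to ~2x the fastest expected swimming speed: the constant-velocity
    # prediction overshoots by a few per-frame displacements when a cell
    # reorients sharply, and the gate has to absorb that error.
    max_linking_speed_um_s: float = 120.0
    filter_window: int = 5  # FIR window length (measurements)
    filter_reweight: bool = True  # Gaussian residual re-weighting pass

    # --- selection ---
    coarse_area_lower_frac: float = 0.20
    coarse_area_upper_mult: float = 5.0
    min_track_time_s: float = 2.0
    max_track_time_s: float = 0.0
    drop_short_after_truncation: bool = False
    max_consecutive_gaps: int = 5
    max_gap_fraction: float = 0.2
    point_area_outlier_mult: float = 1.5
    distance_outlier_enabled: bool = True
    distance_outlier_auto_disable_frac: float = 0.2
    size_percentile: float = 5.0
    size_percentile_two_sided: bool = True
    edge_margin_frac: float = 0.05

    # --- statistics ---
    motile_speed_threshold_um_s: float = 5.0
    turn_angle_threshold_deg: float = 30.0
    turn_min_step_px: float = 0.5

    # --- output ---
    display_video: bool = False
    save_overlay_video: bool = False
    save_raw_csv: bool = True
    save_selected_csv: bool = True
    save_stats_csv: bool = True
    save_coordinate_plot: bool = False
    save_rose_plot: bool = False
    save_violin_plot: bool = False

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every violated invariant."""
        errors = []
        if not self.px_per_um > 0:
            errors.append("px_per_um must be > 0")
        if not self.fps > 0:
            errors.append("fps must be > 0")
        for name in ("frame_width", "frame_height"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                errors.append(f"{name} must be a positive integer")
        for name in ("blur_kernel", "adaptive_kernel"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 3 and v % 2 == 1):
                errors.append(f"{name} must be an odd integer >= 3")
        if self.detection_mode not in DETECTION_MODES:
            errors.append(
                f"detection_mode must be one of {DETECTION_MODES}, "
                f"got {self.detection_mode!r}"
            )
        if self.marker_offset < self.adaptive_offset:
            errors.append("marker_offset must be >= adaptive_offset (stricter)")
        if not self.rolling_window_s > 0:
            errors.append("rolling_window_s must be > 0")
        if not self.avg_bacterial_area_px2 > 0:
            errors.append("avg_bacterial_area_px2 must be > 0")
        if not 0 < self.coarse_area_lower_frac < 1:
            errors.append("coarse_area_lower_frac must be in (0, 1)")
        if not self.coarse_area_upper_mult > 1:
            errors.append("coarse_area_upper_mult must be > 1")
        lower = self.coarse_area_lower_frac * self.avg_bacterial_area_px2
        upper = self.coarse_area_upper_mult * self.avg_bacterial_area_px2
        if not lower < upper:
            errors.append("coarse lower area bound must be < upper bound")
        if self.min_track_time_s < 0:
            errors.append("min_track_time_s must be >= 0")
        if self.max_track_time_s < 0:
            errors.append("max_track_time_s must be >= 0")
        if not self.track_expiry_s > 0:
            errors.append("track_expiry_s must be > 0")
        if self.max_consecutive_gaps < 0:
            errors.append("max_consecutive_gaps must be >= 0")
        if not 0 <= self.max_gap_fraction <= 1:
            errors.append("max_gap_fraction must be in [0, 1]")
        if self.point_area_outlier_mult != 0 and not self.point_area_outlier_mult > 1:
            errors.append("point_area_outlier_mult must be > 1 (or 0 to disable)")
        if not 0 < self.distance_outlier_auto_disable_frac <= 1:
            errors.append("distance_outlier_auto_disable_frac must be in (0, 1]")
        if self.size_percentile != 0 and not 0 < self.size_percentile <= 50:
            errors.append("size_percentile must be in (0, 50] (or 0 to disable)")
        if not 0 <= self.edge_margin_frac < 0.5:
            errors.append("edge_margin_frac must be in [0, 0.5)")
        if not self.motile_speed_threshold_um_s > 0:
            errors.append("motile_speed_threshold_um_s must be > 0")
        if not 0 < self.turn_angle_threshold_deg < 180:
            errors.append("turn_angle_threshold_deg must be in (0, 180)")
        if self.turn_min_step_px < 0:
            errors.append("turn_min_step_px must be >= 0")
        if not (isinstance(self.filter_window, int) and self.filter_window >= 1):
            errors.append("filter_window must be a positive integer")
        if not self.max_linking_speed_um_s > 0:
            errors.append("max_linking_speed_um_s must be > 0")
        if errors:
            raise ConfigError("invalid configuration: " + "; ".join(errors))


# field name -> INI section, in presentation order (basic values first)
_SECTIONS: dict[str, list[str]] = {
    "basic": [
        "px_per_um",
        "fps",
        "frame_width",
        "frame_height",
        "bacteria_brighter_than_background",
        "rod_shaped",
        "avg_bacterial_area_px2",
        "video_paths",
    ],
    "detection": [
        "detection_mode",
        "blur_kernel",
        "adaptive_kernel",
        "adaptive_offset",
        "marker_offset",
        "global_offset",
        "rolling_window_s",
    ],
    "tracking": [
        "track_expiry_s",
        "max_linking_speed_um_s",
        "filter_window",
        "filter_reweight",
    ],
    "selection": [
        "coarse_area_lower_frac",
        "coarse_area_upper_mult",
        "min_track_time_s",
        "max_track_time_s",
        "drop_short_after_truncation",
        "max_consecutive_gaps",
        "max_gap_fraction",
        "point_area_outlier_mult",
        "distance_outlier_enabled",
        "distance_outlier_auto_disable_frac",
        "size_percentile",
        "size_percentile_two_sided",
        "edge_margin_frac",
    ],
    "statistics": [
        "motile_speed_threshold_um_s",
        "turn_angle_threshold_deg",
        "turn_min_step_px",
    ],
    "output": [
        "display_video",
        "save_overlay_video",
        "save_raw_csv",
        "save_selected_csv",
        "save_stats_csv",
        "save_coordinate_plot",
        "save_rose_plot",
        "save_violin_plot",
    ],
}

_SECTION_COMMENTS = {
    "basic": (
        "Basic values -- set these first.\n"
        "px_per_um: pixels per micrometre of the recording.\n"
        "Polarity: bacteria_brighter_than_background = false for dark cells\n"
        "on a bright background (phase contrast / bright field)."
    ),
    "detection": (
        "Grey-value detection. marker_gated uses two adaptive thresholds\n"
        "(candidates + stricter markers); adaptive_simple skips the marker\n"
        "gate; global_rolling thresholds on the frame mean + global_offset\n"
        "standard deviations, averaged over rolling_window_s seconds."
    ),
    "tracking": (
        "Least-distance linking against constant-velocity predictions.\n"
        "Lost IDs are dropped after track_expiry_s seconds without a match."
    ),
    "selection": (
        "Track selection ledger. A value of 0 disables the criterion.\n"
        "Coarse area limits are fractions/multiples of avg_bacterial_area_px2."
    ),
    "statistics": "Per-track motility statistics.",
    "output": "Which artefacts to write.",
}

_REQUIRED_BASIC = (
    "px_per_um",
    "fps",
    "frame_width",
    "frame_height",
    "bacteria_brighter_than_background",
    "rod_shaped",
)

_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(TrackerConfig)}


def _format_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, list):
        return ", ".join(str(v) for v in value)
    return repr(value) if isinstance(value, float) else str(value)


def generate_default_config(path, overwrite: bool = False) -> Path:
    """Write a fully commented default "tracking.ini" to *path*.

    Fails if *path* already exists unless ``overwrite`` is set; the existing
    file is left untouched in that case.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"settings file already exists: {path}")
    cfg = TrackerConfig()
    lines = []
    for section, names in _SECTIONS.items():
        for comment_line in _SECTION_COMMENTS[section].splitlines():
            lines.append(f"# {comment_line}")
        lines.append(f"[{section}]")
        for name in names:
            lines.append(f"{name} = {_format_value(getattr(cfg, name))}")
        lines.append("")
    try:
        path.write_text("\n".join(lines))
    except OSError as exc:
        raise OSError(f"cannot write settings file to {path}: {exc}") from exc
    return path


def _parse_value(name: str, raw: str):
    ftype = _FIELD_TYPES[name]
    raw = raw.strip()
    try:
        if ftype == "bool":
            low = raw.lower()
            if low in ("true", "yes", "on", "1"):
                return True
            if low in ("false", "no", "off", "0"):
                return False
            raise ValueError(f"not a boolean: {raw!r}")
        if ftype == "int":
            return int(raw)
        if ftype == "float":
            return float(raw)
        if name == "video_paths":
            parts = [p.strip() for chunk in raw.splitlines() for p in chunk.split(",")]
            return [p for p in parts if p]
        return raw  # str
    except ValueError as exc:
        raise ConfigError(f"field {name!r}: {exc}") from exc


def load_config(path) -> TrackerConfig:
    """Load and validate a settings file.

    Unknown keys are logged as warnings and ignored; a missing required basic
    field, a type mismatch, or a violated invariant raises
    :class:`ConfigError` naming the field.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"settings file not found: {path}")
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    try:
        parser.read_string(path.read_text())
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc

    known = {name for names in _SECTIONS.values() for name in names}
    values = {}
    for section in parser.sections():
        for key, raw in parser.items(section):
            if key not in known:
                logger.warning("unknown key %r in [%s] of %s ignored", key, section, path)
                continue
            values[key] = _parse_value(key, raw)

    missing = [name for name in _REQUIRED_BASIC if name not in values]
    if missing:
        raise ConfigError(f"missing required basic field(s): {', '.join(missing)}")
    if "avg_bacterial_area_px2" not in values:
        values["avg_bacterial_area_px2"] = (
            DEFAULT_AVG_AREA_ROD if values["rod_shaped"] else DEFAULT_AVG_AREA_COCCOID
        )
    cfg = TrackerConfig(**values)
    cfg.validate()
    return cfg


def write_config(cfg: TrackerConfig, path, overwrite: bool = True) -> Path:
    """Write *cfg* in the same INI dialect ``load_config`` reads."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"settings file already exists: {path}")
    lines = []
    for section, names in _SECTIONS.items():
        lines.append(f"[{section}]")
        for name in names:
            lines.append(f"{name} = {_format_value(getattr(cfg, name))}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path
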