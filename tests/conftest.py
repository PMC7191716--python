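import numpy as np
import pandas as pd
import pytest

from bactrack import TrackerConfig


@pytest.fixture
def small_config() -> TrackerConfig:
    """A 256x256 scene configuration used by most rendering tests."""
    return TrackerConfig(frame_width=256, frame_height=256)


def make_track_df(track_id, frames, xy, areas, fps=30.0, angle=0.0):
    """Build raw-table rows for one track.

    ``frames`` are integer frame indices, ``xy`` an (n, 2) array, ``areas``
    the rectangle areas (0 marks a gap point; stored as width=height=0,
    otherwise as a square rectangle of the given area).
    """
    frames = np.asarray(frames)
    xy = np.asarray(xy, dtype=float)
    areas = np.asarray(areas, dtype=float)
    side = np.sqrt(areas)
    return pd.DataFrame({
        "track_id": track_id,
        "time_s": frames / fps,
        "x": xy[:, 0],
        "y": xy[:, 1],
        "width": side,
        "height": side,
        "angle_deg": angle,
    })


def stack_tracks(*dfs) -> pd.DataFrame:
    table = pd.concat(dfs, ignore_index=True)
    return table.sort_values(["track_id", "time_s"], kind="mergesort",
                             ignore_index=True)
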