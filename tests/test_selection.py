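import dataclasses

import numpy as np
import pandas as pd
import pytest

from bactrack import (Track, TrackerConfig, coarse_select,
                      enforce_max_duration, fine_select, scrub_points,
                      select_tracks, split_track)
from conftest import make_track_df, stack_tracks

FPS = 30.0


def base_config(**kw) -> TrackerConfig:
    """Selection config with every criterion initially disabled."""
    defaults = dict(
        frame_width=1000, frame_height=1000, fps=FPS,
        avg_bacterial_area_px2=100.0, min_track_time_s=0.0,
        max_track_time_s=0.0, max_consecutive_gaps=0, max_gap_fraction=0.0,
        point_area_outlier_mult=0.0, distance_outlier_enabled=False,
        size_percentile=0.0, edge_margin_frac=0.0,
    )
    defaults.update(kw)
    return TrackerConfig(**defaults)


def moving_track(tid, n, area=100.0, start=(500.0, 500.0), step=1.0,
                 frames=None):
    frames = np.arange(n) if frames is None else np.asarray(frames)
    xy = np.stack([start[0] + step * np.arange(len(frames)),
                   np.full(len(frames), start[1])], axis=1)
    return make_track_df(tid, frames, xy, np.full(len(frames), area), fps=FPS)


def still_track(tid, frames, area=100.0, pos=(500.0, 500.0)):
    frames = np.asarray(frames)
    xy = np.tile(pos, (len(frames), 1))
    return make_track_df(tid, frames, xy, np.full(len(frames), area), fps=FPS)


# ------------------------------------------------------------ coarse stage

def test_coarse_drops_small_large_and_gap_dominated_tracks():
    """Mean rectangle area outside [20%, 5x] of the expected cell area drops
    the whole track; gap zeros drag the mean toward zero."""
    cfg = base_config()
    small = still_track(0, range(60), area=10.0)
    large = still_track(1, range(60), area=600.0)
    ok = still_track(2, range(60), area=100.0)
    # 3 real detections then 1 s of zero-area gap points: mean ~ 9 < 20
    gappy = still_track(3, range(33), area=100.0)
    gappy.loc[3:, ["width", "height"]] = 0.0
    table = stack_tracks(small, large, ok, gappy)
    tracks, report = coarse_select(table, cfg)
    assert [t.track_id for t in tracks] == [2]
    assert report.exclusions["coarse_size"] == 3
    assert report.conservation_holds()


def test_coarse_min_time():
    cfg = base_config(min_track_time_s=2.0)
    short = still_track(0, range(30))  # ~1 s
    long = still_track(1, range(90))  # ~3 s
    tracks, report = coarse_select(stack_tracks(short, long), cfg)
    assert [t.track_id for t in tracks] == [1]
    assert report.exclusions["min_time_initial"] == 1


def test_unsorted_table_is_a_contract_error():
    cfg = base_config()
    a, b = still_track(1, range(5)), still_track(0, range(5))
    table = pd.concat([a, b], ignore_index=True)  # ids out of order
    with pytest.raises(ValueError):
        coarse_select(table, cfg)


# ---------------------------------------------------------------- scrubbing

def test_scrub_removes_gap_points_and_area_outliers():
    cfg = base_config(point_area_outlier_mult=1.5)
    df = still_track(0, range(10))
    df.loc[[2, 5], ["width", "height"]] = 0.0  # gaps
    df.loc[7, ["width", "height"]] = [20.0, 10.0]  # overlap event: area 200
    track = Track(0, df.drop(columns="track_id"))
    scrubbed = scrub_points(track, cfg)
    assert scrubbed.n_points == 7
    assert (scrubbed.table["width"] * scrubbed.table["height"] <= 150 + 1e-9).all()
    # removal creates gaps by timestamp, times keep their original values
    frames = np.rint(scrubbed.table["time_s"] * FPS).astype(int).tolist()
    assert frames == [0, 1, 3, 4, 6, 8, 9]


def test_scrub_is_identity_without_gaps_or_outliers():
    cfg = base_config()
    df = still_track(0, range(10)).drop(columns="track_id")
    track = Track(0, df)
    pd.testing.assert_frame_equal(scrub_points(track, cfg).table, df)


# ----------------------------------------------------------------- splitting

def test_outer_fence_split_on_known_distances():
    """Distances {1,1,1,1,1,1,10}: Q1 = Q3 = 1, IQR = 0, outer fence 1, so
    the 10 px step is cut."""
    cfg = base_config(distance_outlier_enabled=True)
    xs = np.concatenate([[0.0], np.cumsum([1, 1, 1, 1, 1, 1, 10])]) + 400
    df = make_track_df(0, np.arange(8), np.stack([xs, np.full(8, 500.0)], 1),
                       np.full(8, 100.0), fps=FPS)
    segments = split_track(Track(0, df.drop(columns="track_id")), cfg)
    assert [s.n_points for s in segments] == [7, 1]


def test_small_gap_run_does_not_split():
    cfg = base_config(max_consecutive_gaps=5)
    frames = [0, 1, 2, 5, 6, 7]  # run of 2 missing frames
    track = Track(0, still_track(0, frames).drop(columns="track_id"))
    assert len(split_track(track, cfg)) == 1


def test_large_gap_run_splits():
    cfg = base_config(max_consecutive_gaps=5)
    frames = list(range(10)) + list(range(20, 30))  # 10 missing frames
    track = Track(0, still_track(0, frames).drop(columns="track_id"))
    segments = split_track(track, cfg)
    assert [s.n_points for s in segments] == [10, 10]


def test_distance_outliers_auto_disable_on_immotile_data():
    """When more than the configured fraction of all steps are fence
    outliers (immotile-heavy data), outlier splitting turns itself off."""
    cfg = base_config(distance_outlier_enabled=True,
                      distance_outlier_auto_disable_frac=0.1)
    dfs = []
    for tid in range(5):
        # steps: five 0s then a 1, repeated -> Q3 = 0, fence 0, so ~17% of
        # steps are "outliers", above the 10% self-disable limit
        steps = np.tile([0.0, 0.0, 0.0, 0.0, 0.0, 1.0], 4)
        xs = 400 + np.concatenate([[0.0], np.cumsum(steps)])
        xy = np.stack([xs, np.full(25, 500.0)], 1)
        dfs.append(make_track_df(tid, np.arange(25), xy, np.full(25, 100.0),
                                 fps=FPS))
    tracks, report = select_tracks(stack_tracks(*dfs), cfg)
    assert report.distance_outlier_auto_disabled
    assert report.split_events == 0
    assert len(tracks) == 5


# ---------------------------------------------------------------- fine stage

def test_fine_minimum_time():
    cfg = base_config(min_track_time_s=5.0)
    seg = Track(0, still_track(0, range(60)).drop(columns="track_id"))  # ~2 s
    assert fine_select(seg, np.array([]), cfg) == "min_time_fine"


def test_fine_gap_fraction():
    cfg = base_config(max_gap_fraction=0.2)
    keep = [f for f in range(100) if f % 10 < 7]  # 30% of frames missing
    seg = Track(0, still_track(0, keep).drop(columns="track_id"))
    assert fine_select(seg, np.array([]), cfg) == "gap_fraction"
    cfg2 = base_config(max_gap_fraction=0.5)
    assert fine_select(seg, np.array([]), cfg2) is None


def test_fine_size_percentile_two_sided():
    cfg = base_config(size_percentile=10.0)
    dist = np.array([100.0] * 9 + [300.0])
    big = Track(0, still_track(0, range(60), area=300.0).drop(columns="track_id"))
    normal = Track(1, still_track(1, range(60), area=100.0).drop(columns="track_id"))
    assert fine_select(big, dist, cfg) == "size_percentile"
    assert fine_select(normal, dist, cfg) is None


def test_fine_edge_margin():
    cfg = base_config(edge_margin_frac=0.05)  # 50 px margin on 1000 px frame
    near = Track(0, still_track(0, range(60), pos=(20.0, 500.0))
                 .drop(columns="track_id"))
    assert fine_select(near, np.array([]), cfg) == "edge_margin"


# ------------------------------------------------------------- max duration

def test_max_duration_truncates_exactly():
    cfg = base_config(max_track_time_s=10.0)
    track = Track(0, still_track(0, range(361)).drop(columns="track_id"))  # 12 s
    out = enforce_max_duration(track, cfg)
    assert out.duration_s == pytest.approx(10.0)
    assert np.rint(out.table["time_s"].iloc[-1] * FPS) == 300


def test_max_duration_truncates_to_point_below_gap():
    cfg = base_config(max_track_time_s=10.0)
    frames = [f for f in range(361) if not 298 <= f <= 303]
    track = Track(0, still_track(0, frames).drop(columns="track_id"))
    out = enforce_max_duration(track, cfg)
    assert np.rint(out.table["time_s"].iloc[-1] * FPS) == 297


def test_max_duration_drop_short_only_after_shortening():
    cfg = base_config(max_track_time_s=10.0, drop_short_after_truncation=True)
    frames = [f for f in range(361) if not 298 <= f <= 303]
    assert enforce_max_duration(
        Track(0, still_track(0, frames).drop(columns="track_id")), cfg) is None
    # a track already below the limit was never shortened and is kept
    short = Track(1, still_track(1, range(150)).drop(columns="track_id"))
    assert enforce_max_duration(short, cfg) is not None


def test_max_duration_unset_is_identity():
    cfg = base_config()
    track = Track(0, still_track(0, range(100)).drop(columns="track_id"))
    out = enforce_max_duration(track, cfg)
    pd.testing.assert_frame_equal(out.table, track.table)


# ------------------------------------------------------------ orchestration

def ledger_fixture_config() -> TrackerConfig:
    return base_config(
        min_track_time_s=2.0, max_consecutive_gaps=5, max_gap_fraction=0.2,
        point_area_outlier_mult=1.5, distance_outlier_enabled=True,
        distance_outlier_auto_disable_frac=0.2, size_percentile=10.0,
        edge_margin_frac=0.05, max_track_time_s=10.0,
        drop_short_after_truncation=True,
    )


def ledger_fixture_tracks():
    """Ten tracks, each engineered to fail one specific ledger criterion."""
    tracks = []
    # 1: mean area below 20% of expected
    tracks.append(still_track(0, range(150), area=10.0))
    # 2: a few detections then 1 s of gaps -> mean area ~ 0 (coarse size)
    t = still_track(1, range(150), area=100.0)
    t.loc[3:, ["width", "height"]] = 0.0
    tracks.append(t)
    # 3: shorter than the initial minimum time
    tracks.append(still_track(2, range(30)))
    # 4: long enough in span, but the trailing half is gap points, so the
    # scrubbed duration falls below the minimum (fine-stage min time)
    t = still_track(3, range(150))
    t.loc[45:, ["width", "height"]] = 0.0
    tracks.append(t)
    # 5: an oversized gap run splits the track; both halves are too short
    frames = list(range(45)) + list(range(55, 100))
    tracks.append(still_track(4, frames))
    # 6: one huge step splits the track at the fence; both halves too short
    xs = 400 + np.concatenate([np.arange(45), 200 + np.arange(45)])
    xy = np.stack([xs, np.full(90, 500.0)], 1)
    tracks.append(make_track_df(5, np.concatenate([np.arange(45),
                                                   np.arange(45, 90)]),
                                xy, np.full(90, 100.0), fps=FPS))
    # 7: 30% of frames missing in short runs (gap fraction)
    keep = [f for f in range(150) if f % 10 < 7]
    tracks.append(still_track(6, keep))
    # 8: mean area far above the percentile band of all candidates
    tracks.append(still_track(7, range(150), area=300.0))
    # 9: hugging the left frame edge
    tracks.append(still_track(8, range(150), pos=(20.0, 500.0)))
    # 10: 12 s track with a gap at +10 s; truncation shortens it below the
    # limit and drop_short_after_truncation rejects it
    frames = [f for f in range(361) if not 299 <= f <= 303]
    tracks.append(still_track(9, frames))
    return tracks


def test_ledger_counts_every_criterion_once():
    """Each engineered violation lands on its own ledger counter; the
    all-gap track is, like the undersized one, a coarse size exclusion."""
    cfg = ledger_fixture_config()
    table = stack_tracks(*ledger_fixture_tracks())
    tracks, report = select_tracks(table, cfg)
    assert tracks == []
    assert report.tracks_in == 10
    assert report.exclusions == {
        "coarse_size": 2,
        "min_time_initial": 1,
        "min_time_fine": 1,
        "consecutive_gaps": 1,
        "distance_outlier_split": 1,
        "gap_fraction": 1,
        "size_percentile": 1,
        "edge_margin": 1,
        "max_duration_drop": 1,
    }
    assert report.conservation_holds()


def test_clean_table_accepts_everything():
    cfg = ledger_fixture_config()
    dfs = [moving_track(tid, 200, start=(300.0 + 40 * tid, 500.0), step=0.5)
           for tid in range(6)]
    tracks, report = select_tracks(stack_tracks(*dfs), cfg)
    assert len(tracks) == 6
    assert all(v == 0 for v in report.exclusions.values())
    assert report.split_events == 0
    assert report.conservation_holds()


def test_longest_passing_part_is_selected():
    """A split producing 8 s and 4 s passing halves keeps only the 8 s one."""
    cfg = base_config(distance_outlier_enabled=True, min_track_time_s=1.0)
    n1, n2 = 241, 121  # 8 s and 4 s at 30 fps
    xs = 200 + np.concatenate([0.5 * np.arange(n1),
                               400 + 0.5 * np.arange(n2)])
    xy = np.stack([xs, np.full(n1 + n2, 500.0)], 1)
    df = make_track_df(0, np.arange(n1 + n2), xy,
                       np.full(n1 + n2, 100.0), fps=FPS)
    tracks, report = select_tracks(df, cfg)
    assert len(tracks) == 1
    assert tracks[0].duration_s == pytest.approx(8.0)
    assert report.split_events == 1
    assert report.conservation_holds()


def test_accepted_tracks_satisfy_every_enabled_criterion():
    """Re-checking every accepted track against the enabled criteria finds
    no violation, and at most one segment per original id survives."""
    cfg = ledger_fixture_config()
    rng = np.random.default_rng(17)
    dfs = []
    for tid in range(25):
        n = rng.integers(30, 400)
        start = rng.uniform(100, 900, 2)
        step = rng.uniform(0, 2)
        df = moving_track(tid, int(n), start=tuple(start), step=float(step))
        drop = rng.random(len(df)) < 0.1
        df = df[~drop]
        dfs.append(df)
    table = stack_tracks(*dfs)
    tracks, report = select_tracks(table, cfg)
    assert report.conservation_holds()
    ids = [t.track_id for t in tracks]
    assert len(ids) == len(set(ids))  # at most one segment per origin id
    sizes = np.array([t.mean_area_px2 for t in tracks])
    for t in tracks:
        assert t.duration_s >= cfg.min_track_time_s - 1e-9
        assert t.duration_s <= cfg.max_track_time_s + 1e-9
        frames = np.rint(t.table["time_s"].to_numpy() * FPS).astype(int)
        if len(frames) > 1:
            assert (np.diff(frames) - 1).max() <= cfg.max_consecutive_gaps
            expected = frames[-1] - frames[0] + 1
            assert (expected - len(frames)) / expected <= cfg.max_gap_fraction + 1e-9
        assert (t.table["width"] * t.table["height"] > 0).all()
        m = cfg.edge_margin_frac * cfg.frame_width
        assert m <= t.table["x"].mean() <= cfg.frame_width - m
        assert m <= t.table["y"].mean() <= cfg.frame_height - m


def test_disabling_a_criterion_never_decreases_acceptance():
    cfg = ledger_fixture_config()
    table = stack_tracks(*ledger_fixture_tracks())
    baseline = len(select_tracks(table, cfg)[0])
    for disabled in [
        dict(min_track_time_s=0.0),
        dict(max_gap_fraction=0.0),
        dict(size_percentile=0.0),
        dict(edge_margin_frac=0.0),
        dict(max_track_time_s=0.0),
        dict(max_consecutive_gaps=0),
        dict(distance_outlier_enabled=False),
    ]:
        relaxed = dataclasses.replace(cfg, **disabled)
        assert len(select_tracks(table, relaxed)[0]) >= baseline
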