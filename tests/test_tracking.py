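import numpy as np
import pytest

from fatrack import AnalysisConfig, build_lineages, match_forward, resolve_merges
from fatrack.segmentation import AdhesionBlob
from fatrack.simulate import simulate_moving
from fatrack.pipeline import run_pipeline
from fatrack import score_against_truth
from fatrack.tracking import (
    BIRTH_NEW,
    BIRTH_SPLIT,
    DEATH_CENSORED,
    DEATH_DISAPPEAR,
    DEATH_MERGED,
)

SHAPE = (40, 40)


def blob(bid, pixels, frame=0, intensity=0.5):
    rows = np.array([p[0] for p in pixels], dtype=np.int32)
    cols = np.array([p[1] for p in pixels], dtype=np.int32)
    return AdhesionBlob(
        blob_id=bid, frame_index=frame, rows=rows, cols=cols, image_shape=SHAPE,
        area_px=len(pixels), area_um2=len(pixels) * 0.215**2,
        centroid=(float(cols.mean()), float(rows.mean())),
        mean_intensity=intensity, axial_ratio=1.0,
    )


def square(bid, r0, c0, size, frame=0, intensity=0.5):
    pixels = [(r, c) for r in range(r0, r0 + size) for c in range(c0, c0 + size)]
    return blob(bid, pixels, frame, intensity)


class TestMatchForward:
    def test_identical_frames_identity_mapping(self):
        t = [square(1, 5, 5, 3), square(2, 20, 20, 4)]
        t1 = [square(1, 5, 5, 3, frame=1), square(2, 20, 20, 4, frame=1)]
        m = match_forward(t, t1)
        assert m.assignment == [0, 1]
        assert m.split_births == set()

    def test_greatest_overlap_wins_and_loser_flagged_split(self):
        # one 10-px blob splits 60/40 into two blobs
        t = [blob(1, [(5, c) for c in range(10)])]
        t1 = [
            blob(1, [(5, c) for c in range(6)], frame=1),       # 60% overlap
            blob(2, [(5, c) for c in range(6, 10)], frame=1),   # 40% overlap
        ]
        m = match_forward(t, t1)
        assert m.assignment == [0]
        assert m.overlap_px == [6]
        assert m.split_births == {1}

    def test_isolated_blob_beyond_cap_is_death_candidate(self):
        t = [square(1, 5, 5, 2)]
        t1 = [square(1, 30, 30, 2, frame=1)]
        m = match_forward(t, t1, max_distance_px=3.0)
        assert m.assignment == [None]

    def test_nearest_centroid_fallback_within_cap(self):
        t = [square(1, 5, 5, 2)]
        t1 = [square(1, 7, 5, 2, frame=1)]  # shifted 2 px: rows 7-8 vs 5-6, no overlap
        m = match_forward(t, t1, max_distance_px=3.0)
        assert m.assignment == [0]
        assert m.overlap_px == [0]


class TestResolveMerges:
    def test_larger_continues_when_sizes_differ_ten_percent(self):
        t = [square(1, 5, 5, 10), square(2, 16, 5, 7)]  # 100 px vs 49 px
        target = square(1, 5, 5, 12, frame=1)           # overlaps both
        m = match_forward(t, [target])
        fates = resolve_merges(m, t, [target]).fates
        assert fates[0] == ("continue", 0)
        assert fates[1] == ("death", DEATH_MERGED, 0)

    def test_close_sizes_resolved_by_centroid_distance(self):
        # 100 px vs 95 px (<10% apart): the one nearer the target continues
        a = blob(1, [(r, c) for r in range(10) for c in range(10)])
        b = blob(2, [(r, c) for r in range(10) for c in range(12, 22)][:95])
        target = blob(1, [(r, c) for r in range(10) for c in range(22)], frame=1)
        m = match_forward([a, b], [target])
        fates = resolve_merges(m, [a, b], [target]).fates
        tx, ty = target.centroid
        da = np.hypot(a.centroid[0] - tx, a.centroid[1] - ty)
        db = np.hypot(b.centroid[0] - tx, b.centroid[1] - ty)
        winner = 0 if da < db else 1
        assert fates[winner][0] == "continue"
        assert fates[1 - winner] == ("death", DEATH_MERGED, 0)

    def test_single_claimant_continues(self):
        t = [square(1, 5, 5, 3)]
        t1 = [square(1, 5, 5, 3, frame=1)]
        m = match_forward(t, t1)
        assert resolve_merges(m, t, t1).fates[0] == ("continue", 0)

    def test_non_overlapping_claimant_in_merge_dies_not_merged(self):
        a = square(1, 5, 5, 5)                       # overlaps target
        b = square(2, 12, 5, 2)                      # no overlap, nearby
        target = square(1, 5, 5, 6, frame=1)
        m = match_forward([a, b], [target], max_distance_px=10.0)
        fates = resolve_merges(m, [a, b], [target]).fates
        assert fates[0] == ("continue", 0)
        assert fates[1] == ("death", DEATH_DISAPPEAR, None)


class TestBuildLineages:
    def test_single_frame_all_censored(self):
        blobs = [[square(i, 5 * i, 5, 2) for i in range(1, 4)]]
        lineages = build_lineages(blobs, AnalysisConfig())
        assert len(lineages) == 3
        assert all(l.death_type == DEATH_CENSORED for l in lineages)
        assert all(l.birth_type == BIRTH_NEW for l in lineages)

    def test_partition_identity(self, small_stationary):
        _, result, _ = small_stationary
        n_blobs = sum(len(fb) for fb in result.frame_blobs)
        assert sum(l.length for l in result.lineages) == n_blobs

    def test_split_birth_labeled(self):
        f0 = [blob(1, [(5, c) for c in range(10)])]
        f1 = [
            blob(1, [(5, c) for c in range(6)], frame=1),
            blob(2, [(5, c) for c in range(6, 10)], frame=1),
        ]
        lineages = build_lineages([f0, f1], AnalysisConfig())
        types = sorted(l.birth_type for l in lineages)
        assert types == [BIRTH_NEW, BIRTH_SPLIT]

    def test_intensity_series_follows_blobs(self):
        frames = [
            [square(1, 5, 5, 3, frame=0, intensity=0.2)],
            [square(1, 5, 5, 3, frame=1, intensity=0.3)],
            [square(1, 5, 5, 3, frame=2, intensity=0.4)],
        ]
        (lin,) = build_lineages(frames, AnalysisConfig())
        np.testing.assert_allclose(lin.intensity_series, [0.2, 0.3, 0.4])
        assert lin.birth_frame == 0 and lin.death_frame == 2
        assert lin.length == 3

    def test_death_when_blob_vanishes(self):
        frames = [
            [square(1, 5, 5, 3, frame=0)],
            [square(1, 5, 5, 3, frame=1)],
            [],
        ]
        (lin,) = build_lineages(frames, AnalysisConfig())
        assert lin.death_type == DEATH_DISAPPEAR
        assert lin.death_frame == 1

    def test_stationary_truth_one_lineage_per_adhesion(self, small_stationary):
        movie, result, scores = small_stationary
        # bright, well-separated discs: every planted adhesion recovered by
        # exactly one lineage covering its full life
        assert scores["full_life"].all()
        assert scores["lineage_id"].is_unique

    def test_birth_death_counting_identity(self, small_stationary):
        _, result, _ = small_stationary
        for t in range(1, len(result.frame_blobs)):
            births = sum(1 for l in result.lineages if l.birth_frame == t)
            deaths = sum(
                1 for l in result.lineages
                if l.death_frame == t - 1 and l.death_type != DEATH_CENSORED
            )
            # net identity: blobs(t) = blobs(t-1) - deaths + births
            assert len(result.frame_blobs[t]) == len(result.frame_blobs[t - 1]) - deaths + births


class TestMovingSimulationTracking:
    def test_accuracy_monotone_in_speed_and_radius(self):
        cfg = AnalysisConfig(seed=5)
        movie = simulate_moving(
            radii=(1.0, 3.0, 5.0), speeds_px_per_frame=(0.0, 1.0, 2.0),
            n_frames=12, seed=5, config=cfg,
        )
        result = run_pipeline(movie.frames, config=cfg)
        scores = score_against_truth(movie, result.lineages)
        pivot = scores.pivot_table(
            index="radius_px", columns="speed_px_per_frame", values="tracking_accuracy"
        )
        arr = pivot.to_numpy()
        assert (np.diff(arr, axis=1) <= 1e-9).all()   # non-increasing in speed
        assert (np.diff(arr, axis=0) >= -1e-9).all()  # non-decreasing in radius

    def test_large_slow_adhesion_single_lineage(self):
        cfg = AnalysisConfig(seed=6)
        movie = simulate_moving(
            radii=(3.0,), speeds_px_per_frame=(1.0,), n_frames=12, seed=6, config=cfg,
        )
        result = run_pipeline(movie.frames, config=cfg)
        scores = score_against_truth(movie, result.lineages)
        assert scores["tracking_accuracy"].iloc[0] == 1.0
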