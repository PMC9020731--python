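import numpy as np
import pandas as pd
import pytest

from wormbox.boxio import Box, CalibrationConfig, DetectionRecord, FrameRecord
from wormbox.kinematics import (
    Track,
    assemble_track,
    box_growth,
    centroid,
    compare_tracks,
    displacement_series,
    downsample,
    smooth,
)
from wormbox.synthetic_data import DetectorNoise, ScenarioConfig, \
    simulate_detections, simulate_trajectory


def make_track(points, dt=1.0, size=2.0):
    """Track from centroid points; timestamps 0, dt, 2dt, ..."""
    samples = []
    for i, (x, y) in enumerate(points):
        samples.append((i * dt, Box(x - size / 2, y - size / 2, x + size / 2, y + size / 2), 1.0))
    return Track.from_samples(samples)


class TestCentroid:
    def test_midpoints(self):
        assert centroid(Box(0, 0, 10, 10)) == (5, 5)
        assert centroid(Box(2, 4, 6, 12)) == (4, 8)

    def test_translation_equivariance(self):
        b = Box(3, 7, 11, 13)
        cx, cy = centroid(b)
        tx, ty = centroid(b.translated(4.5, -2.5))
        assert (tx - 4.5, ty + 2.5) == (cx, cy)


class TestAssembleTrack:
    def _frames(self, dets_per_frame):
        frames = []
        for i, dets in enumerate(dets_per_frame):
            frames.append(FrameRecord(f"f{i}", timestamp=float(i), detections=dets))
        return frames

    def test_one_detection_per_frame(self):
        frames = self._frames([
            [DetectionRecord(Box(i, i, i + 2, i + 2), "worm", 0.9)] for i in range(5)
        ])
        tr = assemble_track(frames, "worm", 0.5)
        assert len(tr) == 5

    def test_highest_confidence_policy(self):
        frames = self._frames([[
            DetectionRecord(Box(0, 0, 2, 2), "worm", 0.9),
            DetectionRecord(Box(50, 50, 52, 52), "worm", 0.6),
        ]])
        tr = assemble_track(frames, "worm", 0.5, "highest_confidence")
        assert tuple(tr.centroids[0]) == (1, 1)

    def test_gap_on_empty_frame(self):
        frames = self._frames([
            [DetectionRecord(Box(0, 0, 2, 2), "worm", 0.9)],
            [],
            [DetectionRecord(Box(4, 4, 6, 6), "worm", 0.9)],
        ])
        tr = assemble_track(frames, "worm", 0.5)
        assert list(tr.timestamps) == [0.0, 2.0]

    def test_nearest_to_previous_rejects_false_positives(self):
        """With sporadic far-away false positives, the proximity policy
        recovers the true centroid at >= 99% of frames (10 seeds)."""
        cfg = ScenarioConfig(duration_min=300)
        noise = DetectorNoise(centroid_jitter_sd_px=0.5, box_jitter_frac=0.0,
                              miss_prob=0.0, false_positive_rate=0.05,
                              false_conf_beta=(8.0, 2.0))  # confident FPs
        for seed in range(10):
            truth, _ = simulate_trajectory(cfg, seed)
            frames = simulate_detections(truth, cfg, seed, noise=noise)
            tr = assemble_track(frames, "worm", 0.5, "nearest_to_previous")
            merged = pd.merge(
                pd.DataFrame({"t": tr.timestamps, "x": tr.centroids[:, 0], "y": tr.centroids[:, 1]}),
                pd.DataFrame({"t": truth.timestamps, "xt": truth.centroids[:, 0],
                              "yt": truth.centroids[:, 1]}),
                on="t")
            err = np.hypot(merged.x - merged.xt, merged.y - merged.yt)
            assert (err < 10.0).mean() >= 0.99


class TestDisplacement:
    def test_stationary_track_is_zero(self, calibration):
        tr = make_track([(5, 5)] * 10)
        s = displacement_series(tr, 1.0, calibration)
        assert (s.displacement_mm == 0).all()

    def test_three_four_five_triangle(self, calibration):
        tr = make_track([(0, 0), (3, 4)])
        s = displacement_series(tr, 1.0, calibration)
        assert s.displacement_mm.iloc[0] == pytest.approx(0.5)  # 5 px * 0.1 mm
        assert s.velocity_mm_per_min.iloc[0] == pytest.approx(0.5)

    def test_gap_yields_absent_not_zero(self, calibration):
        tr = make_track([(0, 0), (1, 0), (2, 0), (3, 0)])
        tr = Track(tr.data[tr.data.timestamp_min != 1.0].reset_index(drop=True))
        s = displacement_series(tr, 1.0, calibration)
        assert set(s.timestamp_min) == {2.0}  # only the 2->3 pair survives

    def test_non_grid_interval_rejected(self, calibration):
        tr = make_track([(0, 0), (1, 0)])
        with pytest.raises(ValueError):
            displacement_series(tr, 1.5, calibration)

    def test_constant_speed_recovered(self, calibration):
        v_px = 7.0  # px/min -> 0.7 mm/min
        tr = make_track([(v_px * i, 0) for i in range(100)])
        s = displacement_series(tr, 1.0, calibration)
        assert s.velocity_mm_per_min.mean() == pytest.approx(0.7, rel=1e-12)


class TestSmooth:
    def test_window_one_is_identity(self, rng):
        s = pd.Series(rng.random(20), index=np.arange(20.0))
        assert (smooth(s, 1) == s).all()

    def test_constant_series_unchanged(self):
        s = pd.Series([2.5] * 8, index=np.arange(8.0))
        assert (smooth(s, 3) == 2.5).all()

    def test_hand_average_with_edge_truncation(self):
        s = pd.Series([0, 0, 3, 0, 0], index=np.arange(5.0), dtype=float)
        out = smooth(s, 3)
        assert out.tolist() == [0, 1, 1, 1, 0]

    def test_window_does_not_cross_gap(self):
        # two runs: t = 0,1,2 and t = 10,11,12
        s = pd.Series([0, 0, 0, 9, 9, 9], index=[0.0, 1, 2, 10, 11, 12])
        out = smooth(s, 3)
        assert out.tolist() == [0, 0, 0, 9, 9, 9]


class TestDownsample:
    def test_native_interval_is_identity(self, calibration):
        tr = make_track([(i, 0) for i in range(10)])
        out = downsample(tr, 1.0, calibration)
        assert list(out.timestamps) == list(tr.timestamps)

    def test_index_arithmetic(self):
        cal = CalibrationConfig(mm_per_pixel=0.1, frame_interval=1 / 180)  # 3 fps
        tr = make_track([(i, 0) for i in range(540)], dt=1 / 180)
        out = downsample(tr, 1.0, cal)
        assert len(out) == 3  # every 180th sample
        assert np.allclose(np.diff(out.timestamps), 1.0)

    def test_composition(self, calibration):
        tr = make_track([(i, 0) for i in range(24)])
        once = downsample(tr, 2.0, calibration)
        twice = downsample(downsample(tr, 1.0, calibration), 2.0, calibration)
        assert list(once.timestamps) == list(twice.timestamps)


class TestBoxGrowth:
    def test_constant_boxes_fold_one(self):
        tr = make_track([(5, 5)] * 12)
        _, fold = box_growth(tr, 3)
        assert fold == pytest.approx(1.0)

    def test_five_fold_ramp(self):
        samples = []
        for i in range(11):
            area = 100 + 40 * i  # 100 -> 500 px^2
            half = np.sqrt(area) / 2
            samples.append((float(i), Box(50 - half, 50 - half, 50 + half, 50 + half), 1.0))
        tr = Track.from_samples(samples)
        _, fold = box_growth(tr, 1)
        assert fold == pytest.approx(5.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            box_growth(make_track([(0, 0)]), 3)


class TestCompareTracks:
    def test_track_vs_itself_all_zero(self, calibration):
        tr = make_track([(i, i) for i in range(10)])
        cmp = compare_tracks(tr, tr, 1.0, calibration)
        assert cmp.mean_distance_mm == 0
        assert cmp.mean_motion_difference_mm == 0

    def test_constant_shift(self, calibration):
        tr = make_track([(i * 2.0, 0) for i in range(10)])
        ref = make_track([(i * 2.0 + 1.0, 0) for i in range(10)])
        cmp = compare_tracks(tr, ref, 1.0, calibration)
        assert cmp.centroid_distances_mm.tolist() == pytest.approx([0.1] * 10)
        assert cmp.mean_motion_difference_mm == pytest.approx(0.0, abs=1e-12)
        assert cmp.std_distance_mm == pytest.approx(0.0, abs=1e-12)

    def test_no_common_timestamps(self, calibration):
        a = make_track([(0, 0), (1, 1)])
        b = Track(a.data.assign(timestamp_min=[10.0, 11.0]))
        with pytest.raises(ValueError):
            compare_tracks(a, b, 1.0, calibration)

    def test_rayleigh_mean_under_gaussian_jitter(self, calibration, rng):
        """Isotropic jitter of std sigma gives mean centroid distance
        sigma * sqrt(pi/2) (Rayleigh mean), checked by Monte Carlo."""
        n, sigma = 10_000, 2.0
        pts = [(float(i % 500), float(i // 500)) for i in range(n)]
        ref = make_track(pts)
        jit = rng.normal(0, sigma, size=(n, 2))
        tr = make_track([(x + dx, y + dy) for (x, y), (dx, dy) in zip(pts, jit)])
        cmp = compare_tracks(tr, ref, 1.0, calibration)
        expected = sigma * np.sqrt(np.pi / 2) * calibration.mm_per_pixel
        assert cmp.mean_distance_mm == pytest.approx(expected, rel=0.05)
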