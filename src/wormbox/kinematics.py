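"""Centroid kinematics from per-frame bounding-box detections.

A :class:`Track` is the time-ordered series of (timestamp, centroid, box,
confidence) for a single animal. Frames where no detection qualifies are
*gaps*: the timestamp is simply absent, and no derived quantity (displacement,
velocity, smoothed area) is ever fabricated across a gap.

All timestamps are minutes; pixel quantities convert to mm through a
:class:`~wormbox.boxio.CalibrationConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .boxio import Box, CalibrationConfig, FrameRecord

__all__ = [
    "Track",
    "TrackComparison",
    "assemble_track",
    "centroid",
    "displacement_series",
    "smooth",
    "downsample",
    "box_growth",
    "compare_tracks",
]

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["timestamp_min", "x_px", "y_px", "x_min", "y_min", "x_max", "y_max", "confidence"]


def centroid(box: Box) -> tuple[float, float]:
    """Centerpoint of a bounding box — the animal's position estimate."""
    return box.center


@dataclass
class Track:
    """Single-animal centroid/box time series with explicit gaps.

    ``data`` has one row per detected timestamp, columns ``TRACK_COLUMNS``,
    strictly increasing ``timestamp_min``. Missing timestamps are gaps.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.data["timestamp_min"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("track timestamps must be strictly increasing")

    @classmethod
    def from_samples(
        cls, samples: Sequence[tuple[float, Box, float]]
    ) -> "Track":
        """Build a track from (timestamp, box, confidence) samples."""
        rows = []
        for t, box, conf in samples:
            cx, cy = box.center
            rows.append((t, cx, cy, box.x_min, box.y_min, box.x_max, box.y_max, conf))
        df = pd.DataFrame(rows, columns=TRACK_COLUMNS).sort_values("timestamp_min")
        return cls(df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> np.ndarray:
        return self.data["timestamp_min"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.data[["x_px", "y_px"]].to_numpy()

    def boxes(self) -> list[Box]:
        return [
            Box(r.x_min, r.y_min, r.x_max, r.y_max)
            for r in self.data.itertuples(index=False)
        ]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Track":
        return cls(pd.read_csv(path)[TRACK_COLUMNS])


def assemble_track(
    frames: Sequence[FrameRecord],
    label: str,
    confidence_threshold: float,
    policy: str = "highest_confidence",
) -> Track:
    """Select at most one detection of ``label`` per frame to form a track.

    Policies
    --------
    highest_confidence
        Take the highest-confidence qualifying detection.
    nearest_to_previous
        Among qualifying detections, take the one closest to the last known
        centroid (highest confidence until a first position is known). This
        rejects sporadic false positives far from the animal's true path.

    Frames without a qualifying detection become gaps. Frames must carry
    timestamps and arrive time-ordered.
    """
    if policy not in ("highest_confidence", "nearest_to_previous"):
        raise ValueError(f"unknown track policy: {policy!r}")

    samples: list[tuple[float, Box, float]] = []
    last_pos: np.ndarray | None = None
    for fr in frames:
        if fr.timestamp is None:
            raise ValueError(f"frame {fr.frame_id} has no timestamp")
        cands = [
            d for d in fr.detections
            if d.label == label and d.confidence >= confidence_threshold
        ]
        if not cands:
            continue
        if policy == "highest_confidence" or last_pos is None:
            chosen = max(cands, key=lambda d: d.confidence)
        else:
            chosen = min(
                cands,
                key=lambda d: float(np.hypot(*(np.asarray(d.box.center) - last_pos))),
            )
        samples.append((fr.timestamp, chosen.box, chosen.confidence))
        last_pos = np.asarray(chosen.box.center)

    if not samples:
        log.warning("assemble_track: no qualifying detections for label %r", label)
        return Track(pd.DataFrame(columns=TRACK_COLUMNS))
    return Track.from_samples(samples)


def displacement_series(
    track: Track, interval: float, calibration: CalibrationConfig
) -> pd.DataFrame:
    """Per-interval Euclidean centroid displacement and linear velocity.

    For each pair of timestamps (t, t + interval) both present in the track,
    reports the straight-line centroid distance in mm and the linear velocity
    displacement/interval in mm/min, assigned to the left endpoint t. Pairs
    spanning a gap are absent from the output, never zero-filled.

    ``interval`` must be a positive multiple of the native frame interval.
    """
    _check_interval(interval, calibration.frame_interval)
    t = track.timestamps
    pos = track.centroids
    index = {round(ti / calibration.frame_interval): i for i, ti in enumerate(t)}
    step = round(interval / calibration.frame_interval)
    rows = []
    for k, i in index.items():
        j = index.get(k + step)
        if j is None:
            continue
        d_px = float(np.hypot(*(pos[j] - pos[i])))
        d_mm = d_px * calibration.mm_per_pixel
        rows.append((t[i], d_mm, d_mm / interval))
    return pd.DataFrame(rows, columns=["timestamp_min", "displacement_mm", "velocity_mm_per_min"])


def _check_interval(interval: float, native: float) -> None:
    if interval <= 0:
        raise ValueError("interval must be positive")
    ratio = interval / native
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"interval {interval} min is not a positive multiple of the native "
            f"frame interval {native} min"
        )


def smooth(series: pd.Series, window_samples: int) -> pd.Series:
    """Centered moving average, truncated at series ends and at gaps.

    ``series`` is indexed by timestamp (minutes). A gap is any index step
    larger than the smallest step present; the window never crosses one, so
    separate detection runs are smoothed independently. A window of 1 is the
    identity.
    """
    if window_samples < 1:
        raise ValueError("window must be >= 1")
    if len(series) <= 1 or window_samples == 1:
        return series.copy()

    t = np.asarray(series.index, dtype=float)
    steps = np.diff(t)
    native = steps.min()
    breaks = np.where(steps > native * 1.5)[0] + 1  # start index of each new run
    segments = np.split(np.arange(len(series)), breaks)

    half = window_samples // 2
    out = np.empty(len(series))
    vals = series.to_numpy(dtype=float)
    for seg in segments:
        v = vals[seg]
        for k in range(len(v)):
            lo = max(0, k - half)
            hi = min(len(v), k + (window_samples - half))
            out[seg[k]] = v[lo:hi].mean()
    return pd.Series(out, index=series.index, name=series.name)


def downsample(track: Track, target_interval: float, calibration: CalibrationConfig) -> Track:
    """Keep samples whose timestamps are congruent to the first retained
    timestamp modulo ``target_interval``; no interpolation.

    Downsampling to the native interval is the identity; composing two
    downsamples equals a single downsample to the coarser interval.
    """
    _check_interval(target_interval, calibration.frame_interval)
    if len(track) == 0:
        return Track(track.data.copy())
    t0 = track.timestamps[0]
    keep = np.isclose(
        np.mod(track.timestamps - t0, target_interval), 0.0, atol=1e-9
    ) | np.isclose(np.mod(track.timestamps - t0, target_interval), target_interval, atol=1e-9)
    return Track(track.data.loc[keep].reset_index(drop=True))


def box_growth(track: Track, smooth_window: int = 10) -> tuple[pd.Series, float]:
    """Bounding-box area over time and its first-to-last fold change.

    Area (px^2) per non-gap sample is smoothed with a centered moving
    average; fold change is last smoothed area / first smoothed area. Used to
    quantify developmental growth of the animal.
    """
    if len(track) < 2:
        raise ValueError("box_growth needs at least 2 samples")
    area = pd.Series(
        (track.data["x_max"] - track.data["x_min"]).to_numpy()
        * (track.data["y_max"] - track.data["y_min"]).to_numpy(),
        index=track.timestamps,
        name="box_area_px2",
    )
    smoothed = smooth(area, smooth_window)
    fold = float(smoothed.iloc[-1] / smoothed.iloc[0])
    return smoothed, fold


@dataclass
class TrackComparison:
    """Agreement between a detector-derived track and a reference track."""

    centroid_distances_mm: pd.Series      # per common timestamp
    motion_differences_mm: pd.Series      # per common interval (left endpoint)
    mean_distance_mm: float
    std_distance_mm: float
    mean_motion_difference_mm: float
    std_motion_difference_mm: float

    def to_dict(self) -> dict:
        return {
            "n_common_timestamps": int(len(self.centroid_distances_mm)),
            "mean_distance_mm": self.mean_distance_mm,
            "std_distance_mm": self.std_distance_mm,
            "n_common_intervals": int(len(self.motion_differences_mm)),
            "mean_motion_difference_mm": self.mean_motion_difference_mm,
            "std_motion_difference_mm": self.std_motion_difference_mm,
        }


def compare_tracks(
    track: Track,
    reference: Track,
    interval: float,
    calibration: CalibrationConfig,
) -> TrackComparison:
    """Compare a track against a reference (e.g. hand-annotated) track.

    Reports the per-timestamp centroid distance and, for each interval both
    tracks cover, the absolute difference of their displacements — the two
    agreement statistics used to validate box-centroid tracking against
    hand-annotated positions. Summaries are mean and (population) std in mm.
    """
    a = track.data.set_index("timestamp_min")
    b = reference.data.set_index("timestamp_min")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("tracks share no timestamps")

    diff = a.loc[common, ["x_px", "y_px"]].to_numpy() - b.loc[common, ["x_px", "y_px"]].to_numpy()
    dist_mm = pd.Series(
        np.hypot(diff[:, 0], diff[:, 1]) * calibration.mm_per_pixel,
        index=common, name="centroid_distance_mm",
    )

    da = displacement_series(track, interval, calibration).set_index("timestamp_min")
    db = displacement_series(reference, interval, calibration).set_index("timestamp_min")
    common_iv = da.index.intersection(db.index)
    motion_diff = (
        (da.loc[common_iv, "displacement_mm"] - db.loc[common_iv, "displacement_mm"])
        .abs()
        .rename("motion_difference_mm")
    )

    return TrackComparison(
        centroid_distances_mm=dist_mm,
        motion_differences_mm=motion_diff,
        mean_distance_mm=float(dist_mm.mean()),
        std_distance_mm=float(dist_mm.std(ddof=0)) if len(dist_mm) else 0.0,
        mean_motion_difference_mm=float(motion_diff.mean()) if len(motion_diff) else float("nan"),
        std_motion_difference_mm=float(motion_diff.std(ddof=0)) if len(motion_diff) else float("nan"),
    )
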