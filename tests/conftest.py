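import numpy as np
import pytest

from wormbox.boxio import Box, CalibrationConfig, DetectionRecord, FrameRecord


@pytest.fixture
def calibration() -> CalibrationConfig:
    return CalibrationConfig(mm_per_pixel=0.1, frame_interval=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_box(rng: np.random.Generator, extent: float = 100.0) -> Box:
    x0, y0 = rng.uniform(0, extent, size=2)
    w, h = rng.uniform(1.0, extent / 2, size=2)
    return Box(x0, y0, x0 + w, y0 + h)


def random_frames(
    rng: np.random.Generator,
    n_frames: int,
    label: str = "worm",
    max_gt: int = 4,
    max_det: int = 6,
) -> list[FrameRecord]:
    """Frames with random ground truth and detections that partially overlap
    the ground truth (half the detections are perturbed copies of GTs)."""
    frames = []
    for i in range(n_frames):
        gts = [random_box(rng) for _ in range(rng.integers(0, max_gt + 1))]
        dets = []
        for _ in range(rng.integers(0, max_det + 1)):
            if gts and rng.random() < 0.6:
                src = gts[rng.integers(len(gts))]
                jit = rng.normal(0, src.width * 0.2, size=2)
                dets.append(DetectionRecord(src.translated(*jit), label, float(rng.random())))
            else:
                dets.append(DetectionRecord(random_box(rng), label, float(rng.random())))
        frames.append(
            FrameRecord(
                frame_id=f"f{i:04d}", timestamp=float(i),
                ground_truth=[(b, label) for b in gts], detections=dets,
            )
        )
    return frames
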