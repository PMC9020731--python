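"""Synthetic scenario generator: every input the pipeline consumes, plus the
hidden truth needed for recovery tests.

Three scenarios mirror the three experimental settings the pipeline serves:

* a developing animal tracked on a plate at 1-minute intervals — a two-state
  (roaming/dwelling) trajectory with bounding-box growth and detector noise;
* an egg-laying adult — burst-like Poisson egg deposition on/off a circular
  bacterial lawn, imaged as overlapping tiles at two snapshot times;
* an aging cohort in chambers — per-individual movement decline encoded as
  first/last box pairs whose IoU is exactly one minus the target movement
  score, with matching binary masks.

Trajectory model. Time advances in discrete steps of the native frame
interval dt. A two-state Markov chain picks the behavioral state s(t); the
animal then draws an instantaneous turn rate ω ~ N(0, σ_s) (deg/min) and a
speed v (mm/min, truncated positive), rotates its heading by ω·dt and
advances v·dt along the new heading. Because the turn drawn at time t is
applied to the step leaving t, the three-point angular velocity measured
from centroids at native sampling equals |ω(t)| exactly, so the observation
density per state is a folded wrapped normal — which makes the Bayes-optimal
classification accuracy of the generative model computable by quadrature
(:func:`bayes_accuracy`). Coarser sampling averages consecutive turn rates
and collapses the separation between states, reproducing the loss of
roaming/dwelling separability at low sampling frequency.

Every output is a deterministic function of (config, seed); each
sub-simulator consumes its own child stream of the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import norm

from .boxio import Box, CalibrationConfig, DetectionRecord, FrameRecord
from .kinematics import Track
from .behavior_states import ROAMING, DWELLING

__all__ = [
    "StateModel",
    "GrowthModel",
    "DetectorNoise",
    "EggModel",
    "AgingModel",
    "ScenarioConfig",
    "EggScenario",
    "AgingVideo",
    "AgingScenario",
    "simulate_trajectory",
    "simulate_detections",
    "simulate_eggs",
    "simulate_aging_cohort",
    "folded_wrapped_normal_pdf",
    "bayes_accuracy",
    "threshold_accuracy",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateModel:
    """Two-state roaming/dwelling kinematics.

    Turn rates are instantaneous centroid turn rates in deg/min (zero-mean
    normal per state); speeds are mm/min. Roaming is the fast, low-turning
    state; dwelling the slow, high-turning one. The defaults put the
    90 deg/min angular-velocity split close to the Bayes boundary of the
    observation densities at 1-minute sampling while keeping dwelling the
    majority state (stationary roaming occupancy 4/9).
    """

    p_roam_to_dwell: float = 0.10   # per minute
    p_dwell_to_roam: float = 0.08
    roam_speed_mean: float = 0.15   # mm/min
    roam_speed_sd: float = 0.05
    dwell_speed_mean: float = 0.02
    dwell_speed_sd: float = 0.01
    roam_turn_sd: float = 75.0      # deg/min
    dwell_turn_sd: float = 225.0

    def __post_init__(self) -> None:
        for p in (self.p_roam_to_dwell, self.p_dwell_to_roam):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must lie in [0, 1]")
        for v in (self.roam_speed_mean, self.dwell_speed_mean,
                  self.roam_turn_sd, self.dwell_turn_sd):
            if v <= 0:
                raise ValueError("speeds and turn sds must be positive")
        if self.roam_turn_sd >= self.dwell_turn_sd:
            import warnings
            warnings.warn("roam turn-sd should be below dwell turn-sd", stacklevel=2)

    @property
    def stationary_roam(self) -> float:
        """Stationary probability of roaming for the two-state chain."""
        denom = self.p_roam_to_dwell + self.p_dwell_to_roam
        return 0.5 if denom == 0 else self.p_dwell_to_roam / denom


@dataclass(frozen=True)
class GrowthModel:
    """Developmental bounding-box growth: logistic in log-area from the
    initial area to ``fold_change`` times it over the scenario duration."""

    initial_area_px2: float = 124.0   # typical smallest tracked animal
    fold_change: float = 5.0
    aspect_ratio: float = 2.0         # box width / height
    steepness: float = 6.0            # logistic steepness over the unit interval

    def area_at(self, frac: np.ndarray) -> np.ndarray:
        """Smoothed area at scenario fraction ``frac`` in [0, 1]; hits the
        endpoints exactly so the realized fold change equals fold_change."""
        frac = np.asarray(frac, dtype=float)
        k = self.steepness
        raw = 1.0 / (1.0 + np.exp(-k * (frac - 0.5)))
        lo, hi = 1.0 / (1.0 + np.exp(k * 0.5)), 1.0 / (1.0 + np.exp(-k * 0.5))
        s = (raw - lo) / (hi - lo)
        return self.initial_area_px2 * self.fold_change ** s


@dataclass(frozen=True)
class DetectorNoise:
    """Emulated detector imperfection applied to true boxes."""

    centroid_jitter_sd_px: float = 1.0
    box_jitter_frac: float = 0.05
    miss_prob: float = 0.05
    false_positive_rate: float = 0.05  # mean spurious boxes per frame
    true_conf_beta: tuple[float, float] | None = (8.0, 2.0)  # None -> conf 1.0
    false_conf_beta: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be non-negative")


#: a perfect detector: no jitter, no misses, no false positives, certain
NOISELESS = DetectorNoise(
    centroid_jitter_sd_px=0.0, box_jitter_frac=0.0, miss_prob=0.0,
    false_positive_rate=0.0, true_conf_beta=None,
)


@dataclass(frozen=True)
class EggModel:
    """Burst-like egg deposition of one adult over a few hours.

    Egg-laying events cluster: bursts arrive as a Poisson process with rate
    ``rate_eggs_per_hr / mean burst size`` so the expected egg rate equals
    ``rate_eggs_per_hr`` (within the commonly reported 4-10 eggs/hr band).
    Burst sizes are geometric with the given mean. Each egg independently
    lands on the lawn with probability ``p_on``.
    """

    rate_eggs_per_hr: float = 6.0
    mean_burst_size: float = 2.0
    cluster_spread_px: float = 12.0
    p_on: float = 0.8
    duration_hr: float = 5.0
    snapshot_times_hr: tuple[float, float] = (2.0, 5.0)
    brood_cap: int = 300
    lawn_center_frac: tuple[float, float] = (0.5, 0.5)   # of arena
    lawn_radius_frac: float = 0.25
    tile_grid: tuple[int, int] = (2, 2)
    tile_overlap_frac: float = 0.10
    egg_box_px: float = 5.0   # ~50 um egg at 10 um/px

    def __post_init__(self) -> None:
        if self.rate_eggs_per_hr < 0 or self.mean_burst_size < 1:
            raise ValueError("need rate >= 0 and mean burst size >= 1")
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError("p_on must lie in [0, 1]")


@dataclass(frozen=True)
class AgingModel:
    """Per-individual movement decline per food level.

    The target movement score follows a logistic decline
    ``m(age) = m_min + (m_max - m_min) / (1 + exp((age - midpoint)/scale))``
    plus individual noise, clipped to [0, 1]. Dietary restriction
    (the lower-OD600 food level) delays the midpoint, preserving movement at
    older ages.
    """

    n_individuals: int = 30
    ages: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)
    m_max: float = 0.9
    m_min: float = 0.05
    midpoints: dict = field(
        default_factory=lambda: {"OD600_10": 6.0, "OD600_2.5": 9.0}
    )
    scale_days: float = 2.0
    noise_sd: float = 0.08
    chamber_px: int = 150
    worm_box: tuple[float, float] = (44.0, 16.0)  # adult worm box, px

    def curve(self, food_level: str, age: np.ndarray) -> np.ndarray:
        mid = self.midpoints[food_level]
        age = np.asarray(age, dtype=float)
        return self.m_min + (self.m_max - self.m_min) / (
            1.0 + np.exp((age - mid) / self.scale_days)
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full synthetic-study configuration with the default study conditions."""

    arena_px: float = 2000.0
    calibration: CalibrationConfig = field(
        default_factory=lambda: CalibrationConfig(mm_per_pixel=0.01, frame_interval=1.0)
    )
    duration_min: float = 1000.0
    states: StateModel = field(default_factory=StateModel)
    growth: GrowthModel = field(default_factory=GrowthModel)
    noise: DetectorNoise = field(default_factory=DetectorNoise)
    eggs: EggModel = field(default_factory=EggModel)
    aging: AgingModel = field(default_factory=AgingModel)

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("scenario duration must be positive")


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    """One independent child stream per sub-simulator."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    return max(mean, lo + sd * 1e-3)


def simulate_trajectory(
    config: ScenarioConfig, seed: int, start_state: str | None = None
) -> tuple[Track, pd.Series]:
    """Simulate one animal's centroid/box track plus true state labels.

    Returns ``(track, states)`` where ``states`` is indexed by timestamp in
    minutes with values roaming/dwelling. Deterministic given (config, seed).
    The arena has reflective boundaries; boxes follow the growth schedule and
    are clipped to the arena.
    """
    rng = _streams(seed)[0]
    st = config.states
    dt = config.calibration.frame_interval
    n = int(round(config.duration_min / dt))
    if n < 1:
        raise ValueError("zero-duration trajectory")
    px_per_mm = 1.0 / config.calibration.mm_per_pixel

    if start_state is None:
        state = ROAMING if rng.random() < st.stationary_roam else DWELLING
    else:
        state = start_state

    arena = config.arena_px
    pos = np.array([arena / 2.0, arena / 2.0])
    heading = rng.uniform(-180.0, 180.0)
    area = config.growth.area_at(np.arange(n) / max(n - 1, 1))

    samples = []
    labels = []
    times = []
    for t in range(n):
        # box for the current position
        w = math.sqrt(area[t] * config.growth.aspect_ratio)
        h = math.sqrt(area[t] / config.growth.aspect_ratio)
        box = Box(
            max(0.0, pos[0] - w / 2), max(0.0, pos[1] - h / 2),
            min(arena, pos[0] + w / 2), min(arena, pos[1] + h / 2),
        )
        samples.append((t * dt, box, 1.0))
        labels.append(state)
        times.append(t * dt)

        # turn drawn at t is applied to the step leaving t, so the measured
        # three-point turn at t is exactly this draw (at native sampling)
        if state == ROAMING:
            omega = rng.normal(0.0, st.roam_turn_sd)
            speed = _truncated_normal(rng, st.roam_speed_mean, st.roam_speed_sd, 1e-4)
        else:
            omega = rng.normal(0.0, st.dwell_turn_sd)
            speed = _truncated_normal(rng, st.dwell_speed_mean, st.dwell_speed_sd, 1e-4)
        heading += omega * dt
        step = speed * px_per_mm * dt
        pos = pos + step * np.array(
            [math.cos(math.radians(heading)), math.sin(math.radians(heading))]
        )
        # reflective boundaries
        for ax in (0, 1):
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                heading = -heading if ax == 1 else 180.0 - heading
            elif pos[ax] > arena:
                pos[ax] = 2 * arena - pos[ax]
                heading = -heading if ax == 1 else 180.0 - heading

        # state transition for the next step; per-minute probabilities are
        # converted to the step scale so occupancy is invariant to dt
        if state == ROAMING:
            if rng.random() < 1.0 - (1.0 - st.p_roam_to_dwell) ** dt:
                state = DWELLING
        else:
            if rng.random() < 1.0 - (1.0 - st.p_dwell_to_roam) ** dt:
                state = ROAMING

    track = Track.from_samples(samples)
    return track, pd.Series(labels, index=times, name="state")


# ---------------------------------------------------------------------------
# Detector emulation
# ---------------------------------------------------------------------------

def simulate_detections(
    track: Track,
    config: ScenarioConfig,
    seed: int,
    label: str = "worm",
    noise: DetectorNoise | None = None,
) -> list[FrameRecord]:
    """Emulate detector output over a true track.

    Each true box is jittered in position and size, dropped with the miss
    probability, and supplemented by spurious boxes at the false-positive
    rate; confidences follow separate Beta laws for true and false
    detections. Output frames also carry the true boxes as ground truth, so
    they feed directly into :func:`wormbox.detect_eval.evaluate`.
    """
    nz = config.noise if noise is None else noise
    rng = _streams(seed)[1]
    arena = config.arena_px
    size = (int(arena), int(arena))
    frames: list[FrameRecord] = []
    for i, (t, box) in enumerate(zip(track.timestamps, track.boxes())):
        fr = FrameRecord(
            frame_id=f"frame_{i:06d}", image_size=size, timestamp=float(t),
            ground_truth=[(box, label)],
        )
        if rng.random() >= nz.miss_prob:
            cx, cy = box.center
            cx += rng.normal(0.0, nz.centroid_jitter_sd_px) if nz.centroid_jitter_sd_px else 0.0
            cy += rng.normal(0.0, nz.centroid_jitter_sd_px) if nz.centroid_jitter_sd_px else 0.0
            w = box.width * max(0.1, 1.0 + (rng.normal(0.0, nz.box_jitter_frac) if nz.box_jitter_frac else 0.0))
            h = box.height * max(0.1, 1.0 + (rng.normal(0.0, nz.box_jitter_frac) if nz.box_jitter_frac else 0.0))
            conf = 1.0 if nz.true_conf_beta is None else float(rng.beta(*nz.true_conf_beta))
            fr.detections.append(
                DetectionRecord(Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2), label, conf)
            )
        n_fp = rng.poisson(nz.false_positive_rate) if nz.false_positive_rate > 0 else 0
        for _ in range(n_fp):
            fx, fy = rng.uniform(0, arena, size=2)
            fw = max(2.0, box.width * rng.uniform(0.5, 1.5))
            fh = max(2.0, box.height * rng.uniform(0.5, 1.5))
            fr.detections.append(
                DetectionRecord(
                    Box(fx, fy, fx + fw, fy + fh), label, float(rng.beta(*nz.false_conf_beta))
                )
            )
        frames.append(fr)
    return frames


# ---------------------------------------------------------------------------
# Egg scenario
# ---------------------------------------------------------------------------

@dataclass
class EggScenario:
    """Observable tiled snapshots plus hidden truth for the egg pipeline."""

    frames_t1: list[FrameRecord]
    frames_t2: list[FrameRecord]
    layout: "TileLayout"
    lawn: "LawnRegion"
    truth: pd.DataFrame  # columns: time_hr, x, y, on_lawn


def simulate_eggs(config: ScenarioConfig, seed: int) -> EggScenario:
    """Simulate burst-like egg laying and its tiled imaging.

    Bursts arrive by a Poisson process along the worm's path; each egg
    scatters around the burst center by the cluster spread and lands on the
    lawn with probability ``p_on`` (position and flag are consistent by
    construction). Snapshots at the two configured times are tiled into an
    overlapping grid; an egg appears once in *every* tile that covers it, so
    the double-count structure the dedup step removes is real.
    """
    from .egg_analysis import LawnRegion, TileLayout  # local import to avoid cycle

    em = config.eggs
    rng = _streams(seed)[2]
    arena = config.arena_px
    lawn = LawnRegion(
        center=(arena * em.lawn_center_frac[0], arena * em.lawn_center_frac[1]),
        radius=arena * em.lawn_radius_frac,
    )

    # worm path at 1-min resolution over the full duration
    path_cfg = replace(config, duration_min=em.duration_hr * 60.0)
    track, _ = simulate_trajectory(path_cfg, seed=int(rng.integers(2**31 - 1)))
    path = track.centroids

    burst_rate = em.rate_eggs_per_hr / em.mean_burst_size  # bursts per hr
    eggs: list[tuple[float, float, float, bool]] = []
    t_hr = 0.0
    while em.rate_eggs_per_hr > 0:
        t_hr += rng.exponential(1.0 / burst_rate)
        if t_hr >= em.duration_hr or len(eggs) >= em.brood_cap:
            break
        minute = min(int(t_hr * 60.0), len(path) - 1)
        center = path[minute]
        # geometric burst size with the configured mean (support >= 1)
        p = 1.0 / em.mean_burst_size
        size = int(rng.geometric(p))
        for _ in range(size):
            if len(eggs) >= em.brood_cap:
                break
            on = bool(rng.random() < em.p_on)
            pos = _place_egg(rng, center, em.cluster_spread_px, on, lawn, arena,
                             existing=[(e[1], e[2]) for e in eggs],
                             min_spacing=1.05 * em.egg_box_px)
            eggs.append((t_hr, pos[0], pos[1], on))

    truth = pd.DataFrame(eggs, columns=["time_hr", "x", "y", "on_lawn"])
    layout = _tile_layout(arena, em.tile_grid, em.tile_overlap_frac)

    t1, t2 = em.snapshot_times_hr
    frames_t1 = _tile_frames(truth[truth.time_hr <= t1], layout, em, rng, snapshot_hr=t1)
    frames_t2 = _tile_frames(truth[truth.time_hr <= t2], layout, em, rng, snapshot_hr=t2)
    return EggScenario(frames_t1=frames_t1, frames_t2=frames_t2, layout=layout,
                       lawn=lawn, truth=truth)


def _place_egg(
    rng, center, spread, on_lawn, lawn, arena,
    existing=(), min_spacing: float = 0.0,
) -> tuple[float, float]:
    """Scatter around the burst center, honoring the egg's on/off-lawn side.

    Eggs are rigid bodies: a candidate closer than ``min_spacing`` (one egg
    diameter) to an already-laid egg is rejected, so distinct eggs never
    overlap."""

    def clear(pos) -> bool:
        return all(
            (pos[0] - ex) ** 2 + (pos[1] - ey) ** 2 >= min_spacing**2
            for ex, ey in existing
        )

    for _ in range(200):
        pos = (
            float(np.clip(center[0] + rng.normal(0, spread), 0, arena)),
            float(np.clip(center[1] + rng.normal(0, spread), 0, arena)),
        )
        if lawn.contains(pos) == on_lawn and clear(pos):
            return pos
    # fall back to sampling the target region directly
    for _ in range(2000):
        if on_lawn:
            r = lawn.radius * math.sqrt(rng.random())
            a = rng.uniform(0, 2 * math.pi)
            pos = (lawn.center[0] + r * math.cos(a), lawn.center[1] + r * math.sin(a))
            if 0 <= pos[0] <= arena and 0 <= pos[1] <= arena and clear(pos):
                return pos
        else:
            pos = (rng.uniform(0, arena), rng.uniform(0, arena))
            if not lawn.contains(pos) and clear(pos):
                return pos
    raise RuntimeError("could not place egg on the requested lawn side")


def _tile_layout(arena: float, grid: tuple[int, int], overlap: float):
    from .egg_analysis import TileLayout

    nx, ny = grid
    tw = arena / (nx - (nx - 1) * overlap) if nx > 1 else arena
    th = arena / (ny - (ny - 1) * overlap) if ny > 1 else arena
    offsets = {}
    for ix in range(nx):
        for iy in range(ny):
            offsets[f"tile_{ix}_{iy}"] = (ix * tw * (1 - overlap), iy * th * (1 - overlap))
    return TileLayout(offsets=offsets, tile_size=(tw, th))


def _tile_frames(
    truth: pd.DataFrame, layout, em: EggModel, rng, snapshot_hr: float
) -> list[FrameRecord]:
    # frame_id equals the tile id so TileLayout.to_global applies directly;
    # ids are unique within one snapshot's frame set
    tw, th = layout.tile_size
    half = em.egg_box_px / 2.0
    frames = []
    for tile_id, (ox, oy) in layout.offsets.items():
        fr = FrameRecord(
            frame_id=tile_id,
            image_size=(int(math.ceil(tw)), int(math.ceil(th))),
            timestamp=snapshot_hr * 60.0,
        )
        for row in truth.itertuples(index=False):
            lx, ly = row.x - ox, row.y - oy
            if 0 <= lx <= tw and 0 <= ly <= th:
                conf = float(rng.beta(8.0, 2.0))
                fr.detections.append(
                    DetectionRecord(
                        Box(lx - half, ly - half, lx + half, ly + half), "egg", conf
                    )
                )
        frames.append(fr)
    return frames


# ---------------------------------------------------------------------------
# Aging cohort
# ---------------------------------------------------------------------------

@dataclass
class AgingVideo:
    """First/last frame observables for one (individual, age) video."""

    individual_id: str
    age: float
    food_level: str
    first_box: Box
    last_box: Box
    mask_first: np.ndarray
    mask_last: np.ndarray


@dataclass
class AgingScenario:
    manifest: pd.DataFrame           # individual_id, age_days, food_level
    videos: list[AgingVideo]
    truth: dict                      # food_level -> DataFrame individuals x ages


def _box_pair_for_iou(w: float, h: float, x0: float, y0: float, target_iou: float) -> tuple[Box, Box]:
    """Construct two w x h boxes whose IoU is exactly ``target_iou``.

    A pure horizontal shift dx gives IoU = (w - dx) / (w + dx) for dx <= w,
    hence dx = w (1 - IoU) / (1 + IoU); IoU 0 maps to edge-touching boxes
    (dx = w) and larger separations for clarity are unnecessary.
    """
    dx = w * (1.0 - target_iou) / (1.0 + target_iou)
    first = Box(x0, y0, x0 + w, y0 + h)
    if target_iou >= 1.0:
        return first, Box(x0, y0, x0 + w, y0 + h)
    if target_iou <= 0.0:
        dx = w * 1.2  # clearly disjoint
    last = first.translated(dx, 0.0)
    return first, last


def _render_mask(box: Box, shape: tuple[int, int]) -> np.ndarray:
    """Filled-rectangle binary mask of a box on an integer pixel grid."""
    m = np.zeros(shape, dtype=bool)
    x0 = max(0, int(round(box.x_min)))
    x1 = min(shape[1], int(round(box.x_max)))
    y0 = max(0, int(round(box.y_min)))
    y1 = min(shape[0], int(round(box.y_max)))
    m[y0:y1, x0:x1] = True
    return m


def simulate_aging_cohort(config: ScenarioConfig, seed: int) -> AgingScenario:
    """Simulate an aging cohort per food level with known decline curves.

    For each individual and age, the target movement score m is the food
    level's decline curve plus individual noise, clipped to [0, 1]; the
    emitted first/last bounding boxes have IoU exactly 1 - m (continuous
    coordinates), and matching filled-rectangle masks make the pixel-change
    metric computable. The truth matrices are returned for recovery tests.
    """
    am = config.aging
    rng = _streams(seed)[3]
    w, h = am.worm_box
    shape = (am.chamber_px, 2 * am.chamber_px)  # wide enough for disjoint pairs

    videos: list[AgingVideo] = []
    truth: dict[str, pd.DataFrame] = {}
    manifest_rows = []
    for food_level in sorted(am.midpoints):
        ids = [f"{food_level}_w{i:03d}" for i in range(am.n_individuals)]
        mat = pd.DataFrame(index=ids, columns=list(am.ages), dtype=float)
        for ind in ids:
            base = am.curve(food_level, np.asarray(am.ages))
            m_vals = np.clip(base + rng.normal(0.0, am.noise_sd, size=len(am.ages)), 0.0, 1.0)
            for age, m in zip(am.ages, m_vals):
                first, last = _box_pair_for_iou(w, h, x0=10.0, y0=am.chamber_px / 2 - h / 2,
                                                target_iou=1.0 - float(m))
                videos.append(
                    AgingVideo(
                        individual_id=ind, age=float(age), food_level=food_level,
                        first_box=first, last_box=last,
                        mask_first=_render_mask(first, shape),
                        mask_last=_render_mask(last, shape),
                    )
                )
                mat.loc[ind, age] = float(m)
                manifest_rows.append((ind, float(age), food_level))
        truth[food_level] = mat
    manifest = pd.DataFrame(manifest_rows, columns=["individual_id", "age_days", "food_level"])
    return AgingScenario(manifest=manifest, videos=videos, truth=truth)


# ---------------------------------------------------------------------------
# Closed-form observation densities and reference accuracies
# ---------------------------------------------------------------------------

def folded_wrapped_normal_pdf(x: np.ndarray, sigma: float, kmax: int = 8) -> np.ndarray:
    """Density on [0, 180] of |wrap(N(0, sigma))| with wrapping into
    (-180, 180] — the angular-velocity observation density of one state at
    native sampling (degrees)."""
    x = np.asarray(x, dtype=float)
    tot = np.zeros_like(x)
    for k in range(-kmax, kmax + 1):
        tot += norm.pdf((x + 360.0 * k) / sigma) / sigma
        tot += norm.pdf((-x + 360.0 * k) / sigma) / sigma
    return tot


def bayes_accuracy(states: StateModel) -> float:
    """Bayes-optimal single-timestamp state classification accuracy from the
    angular-velocity observable at native sampling, by quadrature."""
    pi_r = states.stationary_roam
    f = lambda x: max(
        pi_r * folded_wrapped_normal_pdf(x, states.roam_turn_sd),
        (1 - pi_r) * folded_wrapped_normal_pdf(x, states.dwell_turn_sd),
    )
    val, _ = quad(f, 0.0, 180.0, limit=500)
    return float(val)


def threshold_accuracy(states: StateModel, threshold: float = 90.0) -> float:
    """Expected accuracy of the angular-velocity threshold classifier under
    the generative model at native sampling."""
    pi_r = states.stationary_roam
    p_r, _ = quad(lambda x: folded_wrapped_normal_pdf(x, states.roam_turn_sd),
                  0.0, threshold, limit=500)
    p_d, _ = quad(lambda x: folded_wrapped_normal_pdf(x, states.dwell_turn_sd),
                  threshold, 180.0, limit=500)
    return float(pi_r * p_r + (1 - pi_r) * p_d)
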