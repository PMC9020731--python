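"""Egg-laying phenotypes: counting, tile deduplication, laying rates,
lawn preference, and two-sample distribution comparison.

Eggs are detected as boxes at a deliberately low confidence threshold
(default 0.01) because eggs are small and frequently occluded; the box
centroid serves as the egg position. Arenas larger than one field of view are
imaged as overlapping tiles, so an egg in an overlap region appears in more
than one image: observations from *different* tiles closer than a merge
radius are collapsed (single linkage, keeping the highest-confidence one),
while nearby observations within a single tile are distinct eggs.

The spatial phenotype is the lawn preference score
``(eggs_on - eggs_off) / (eggs_on + eggs_off)`` in [-1, 1]; +1 means every
egg was laid on the bacterial lawn. Group distributions are compared with the
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp
from shapely.geometry import Point, Polygon

from .boxio import FrameRecord, filter_confidence

__all__ = [
    "EggObservation",
    "LawnRegion",
    "TileLayout",
    "KSResult",
    "count_eggs",
    "dedup_tiles",
    "egg_rates",
    "assign_lawn",
    "preference_score",
    "ks_two_sample",
]

log = logging.getLogger(__name__)

EGG_LABEL = "egg"
#: default egg diameter used to derive the tile-dedup merge radius, mm
EGG_DIAMETER_MM = 0.05


@dataclass(frozen=True)
class EggObservation:
    """One detected egg in the global (stitched) coordinate frame."""

    position: tuple[float, float]  # global pixels
    confidence: float
    tile_id: str
    on_lawn: bool | None = None


@dataclass(frozen=True)
class LawnRegion:
    """Bacterial-lawn geometry: a disk (center, radius) or a polygon.

    Boundary points count as on-lawn (inclusive rule).
    """

    center: tuple[float, float] | None = None
    radius: float | None = None
    polygon: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.polygon is not None:
            if len(self.polygon) < 3:
                raise ValueError("lawn polygon needs at least 3 vertices")
            if Polygon(self.polygon).area <= 0:
                raise ValueError("lawn polygon has non-positive area")
        elif self.center is None or self.radius is None or self.radius <= 0:
            raise ValueError("lawn needs a polygon or a center with positive radius")

    def contains(self, point: tuple[float, float]) -> bool:
        if self.polygon is not None:
            return Polygon(self.polygon).covers(Point(point))
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        return dx * dx + dy * dy <= self.radius * self.radius


@dataclass(frozen=True)
class TileLayout:
    """Offsets of each image tile's origin in the global frame, pixels.

    ``offsets`` maps tile id -> (x, y); ``tile_size`` is (width, height).
    Tiles may overlap — that is the point of the dedup step.
    """

    offsets: dict[str, tuple[float, float]]
    tile_size: tuple[float, float]

    def to_global(self, tile_id: str, local: tuple[float, float]) -> tuple[float, float]:
        ox, oy = self.offsets[tile_id]
        return (ox + local[0], oy + local[1])


def count_eggs(
    frames: Sequence[FrameRecord],
    confidence_threshold: float = 0.01,
    layout: TileLayout | None = None,
    label: str = EGG_LABEL,
) -> tuple[int, list[EggObservation]]:
    """Count egg detections at the given confidence threshold.

    Each frame is treated as one tile (tile id = frame id); box centroids
    become egg positions, mapped to the global frame when a layout is given.
    Returns ``(count, observations)``.
    """
    filtered = filter_confidence(frames, label, confidence_threshold)
    obs: list[EggObservation] = []
    for fr in filtered:
        for det in fr.detections:
            if det.label != label:
                continue
            pos = det.box.center
            if layout is not None:
                pos = layout.to_global(fr.frame_id, pos)
            obs.append(EggObservation(position=pos, confidence=det.confidence, tile_id=fr.frame_id))
    return len(obs), obs


def dedup_tiles(
    observations: Sequence[EggObservation],
    merge_radius: float,
) -> list[EggObservation]:
    """Collapse cross-tile duplicates of the same physical egg.

    Observations from different tiles within ``merge_radius`` (global pixels)
    are linked; each single-linkage cluster keeps only its highest-confidence
    member. Observations from the same tile are never linked — two nearby
    detections in one image are two eggs. Never increases the count.
    """
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")
    n = len(observations)
    if n == 0:
        return []

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    pts = np.array([o.position for o in observations])
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(merge_radius):
        if observations[i].tile_id != observations[j].tile_id:
            union(i, j)

    best: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        if r not in best or observations[i].confidence > observations[best[r]].confidence:
            best[r] = i
    return [observations[i] for i in sorted(best.values())]


def egg_rates(
    count_t1: int, count_t2: int, t1: float = 2.0, t2: float = 5.0
) -> tuple[float, float]:
    """Two egg-laying rates (eggs/hr) from brood counts at two time points.

    ``count_t1`` eggs accumulated over the first ``t1`` hours after transfer,
    so rate1 = count_t1 / t1; rate2 covers the second window,
    (count_t2 - count_t1) / (t2 - t1). A decreasing count (possible with
    noisy detection) is logged and the second rate floored at 0.
    """
    if t2 <= t1 or t1 <= 0:
        raise ValueError("need 0 < t1 < t2")
    if count_t1 < 0 or count_t2 < 0:
        raise ValueError("egg counts must be non-negative")
    if count_t2 < count_t1:
        log.warning("egg count decreased between time points (%d -> %d)", count_t1, count_t2)
    rate1 = count_t1 / t1
    rate2 = max(0.0, (count_t2 - count_t1) / (t2 - t1))
    return rate1, rate2


def assign_lawn(
    observations: Sequence[EggObservation], lawn: LawnRegion
) -> list[EggObservation]:
    """Set each observation's on_lawn flag from the lawn geometry
    (boundary inclusive)."""
    return [replace(o, on_lawn=lawn.contains(o.position)) for o in observations]


def preference_score(eggs_on: int, eggs_off: int) -> float:
    """Lawn preference score (eggs_on - eggs_off) / (eggs_on + eggs_off).

    +1: all eggs on the lawn; -1: all off; antisymmetric under swapping the
    arguments. Undefined (raises) when no eggs were observed.
    """
    if eggs_on < 0 or eggs_off < 0:
        raise ValueError("egg counts must be non-negative")
    total = eggs_on + eggs_off
    if total == 0:
        raise ValueError("preference score undefined with zero eggs")
    return (eggs_on - eggs_off) / total


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison outcome."""

    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "method": self.method,
        }


def ks_two_sample(a: Sequence[float], b: Sequence[float], method: str = "auto") -> KSResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| plus its p-value.

    ``method`` follows scipy (``auto`` uses the exact distribution for small
    samples and the asymptotic one otherwise); the method selected by sample
    size is recorded in the result (scipy falls back to the asymptotic form
    when the exact computation is unavailable, e.g. with heavy ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test needs two nonempty samples")
    res = ks_2samp(a, b, method=method)
    resolved = method
    if method == "auto":
        resolved = "exact" if len(a) * len(b) <= 10_000 else "asymp"
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        method=resolved,
    )
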