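"""Aging movement decline from per-video bounding boxes and masks.

For worms confined in small chambers, centroid distance saturates and stops
discriminating activity levels. Two per-video metrics work instead:

* movement score = 1 - IoU between the worm's bounding box in the first and
  last frames of a short video. Active young worms move clear of their
  starting box (score near 1); old, nearly paralyzed worms overlap almost
  completely (score near 0).
* pixel change = sum of absolute differences between the first- and
  last-frame binary worm masks, normalized by the mean of the two mask
  areas: ``sum|m1 - m2| / ((sum m1 + sum m2) / 2)``, in [0, 2].

Cohorts are summarized as a per-individual score matrix over age plus
per-age mean and SEM for each food level; food levels (e.g. dietary
restriction vs ad libitum) are compared with a two-sample KS test on pooled
per-video scores from ages at or after the intervention age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boxio import Box
from .detect_eval import iou
from .egg_analysis import KSResult, ks_two_sample

__all__ = [
    "VideoScore",
    "DeclineSummary",
    "movement_score",
    "pixel_change",
    "score_cohort",
    "compare_food_levels",
]


def movement_score(first_box: Box, last_box: Box) -> float:
    """1 - IoU of the first- and last-frame worm boxes; 0 for a static worm,
    1 when the boxes are disjoint."""
    return 1.0 - iou(first_box, last_box)


def pixel_change(mask_first: np.ndarray, mask_last: np.ndarray) -> float:
    """Normalized mask difference: sum|m1 - m2| / ((sum m1 + sum m2) / 2).

    Masks are binary arrays of equal shape (any nonzero value counts as
    worm). 0 iff the masks are identical; 2 when they are disjoint.
    """
    m1 = np.asarray(mask_first).astype(bool)
    m2 = np.asarray(mask_last).astype(bool)
    if m1.shape != m2.shape:
        raise ValueError(f"mask shapes differ: {m1.shape} vs {m2.shape}")
    a1, a2 = int(m1.sum()), int(m2.sum())
    if a1 + a2 == 0:
        raise ValueError("both masks are empty")
    return float(np.sum(m1 ^ m2) / ((a1 + a2) / 2.0))


@dataclass(frozen=True)
class VideoScore:
    """Movement metrics for one (individual, age) video."""

    individual_id: str
    age: float  # days of adulthood
    food_level: str
    movement_score: float
    pixel_change: float | None = None


@dataclass
class DeclineSummary:
    """Population-level decline: score matrix and per-age mean/SEM.

    ``matrix`` is individuals x ages with NaN for missing videos;
    ``per_age`` has columns mean, sem, n indexed by age. SEM uses the sample
    standard deviation over n; a single individual reports SEM 0 with n = 1.
    """

    food_level: str
    matrix: pd.DataFrame
    per_age: pd.DataFrame
    scores: list[VideoScore]

    def to_dict(self) -> dict:
        return {
            "food_level": self.food_level,
            "n_individuals": int(self.matrix.shape[0]),
            "ages": [float(a) for a in self.per_age.index],
            "mean": self.per_age["mean"].tolist(),
            "sem": self.per_age["sem"].tolist(),
            "n": self.per_age["n"].astype(int).tolist(),
        }


def score_cohort(scores: list[VideoScore], food_level: str | None = None) -> DeclineSummary:
    """Assemble per-video scores into a decline summary for one food level.

    Duplicate (individual, age) entries are an input error and are reported
    explicitly. Missing (individual, age) combinations stay NaN in the
    matrix and are excluded from the per-age mean/SEM.
    """
    if food_level is not None:
        scores = [s for s in scores if s.food_level == food_level]
    if not scores:
        raise ValueError(f"no video scores for food level {food_level!r}")
    levels = {s.food_level for s in scores}
    if len(levels) > 1:
        raise ValueError(f"mixed food levels in one cohort summary: {sorted(levels)}")

    seen: dict[tuple[str, float], int] = {}
    dups = []
    for s in scores:
        key = (s.individual_id, s.age)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == 2:
            dups.append(key)
    if dups:
        raise ValueError(f"duplicate (individual, age) video scores: {dups}")

    individuals = sorted({s.individual_id for s in scores})
    ages = sorted({s.age for s in scores})
    matrix = pd.DataFrame(np.nan, index=individuals, columns=ages)
    for s in scores:
        matrix.loc[s.individual_id, s.age] = s.movement_score

    rows = []
    for age in ages:
        col = matrix[age].dropna()
        n = len(col)
        sem = float(col.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append((age, float(col.mean()), sem, n))
    per_age = pd.DataFrame(rows, columns=["age", "mean", "sem", "n"]).set_index("age")
    return DeclineSummary(
        food_level=next(iter(levels)), matrix=matrix, per_age=per_age, scores=list(scores)
    )


def compare_food_levels(
    summary_a: DeclineSummary,
    summary_b: DeclineSummary,
    min_age: float = 2.0,
    unit: str = "per_video",
) -> dict:
    """KS comparison of movement scores between two food-level cohorts.

    Pools scores from ages >= ``min_age`` (the dietary-restriction start,
    day 2 of adulthood by default). ``unit`` selects the comparison sample:
    ``per_video`` pools every video score; ``per_individual`` first averages
    each individual's scores over the age window.
    """
    def sample(summary: DeclineSummary) -> np.ndarray:
        ages = [a for a in summary.matrix.columns if a >= min_age]
        if not ages:
            raise ValueError(f"no ages >= {min_age} in cohort {summary.food_level}")
        sub = summary.matrix[ages]
        if unit == "per_video":
            vals = sub.to_numpy().ravel()
            return vals[~np.isnan(vals)]
        if unit == "per_individual":
            means = sub.mean(axis=1, skipna=True).dropna()
            return means.to_numpy()
        raise ValueError(f"unknown comparison unit: {unit!r}")

    a, b = sample(summary_a), sample(summary_b)
    ks: KSResult = ks_two_sample(a, b)
    return {
        "group_a": summary_a.food_level,
        "group_b": summary_b.food_level,
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "min_age": min_age,
        "unit": unit,
        "ks": ks.to_dict(),
    }
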