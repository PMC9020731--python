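"""Roaming/dwelling classification from centroid angular velocity.

*C. elegans* alternates between a fast, low-turning exploratory state
(roaming) and a slow, high-turning localized state (dwelling). At 1-minute
sampling the angular velocity of the centroid separates the two states well:
timestamps turning slower than 90 deg/min are classified roaming, faster (or
equal) dwelling.

Angular velocity at time t is the three-point turn magnitude: the absolute
wrapped difference between the heading of c(t) - c(t-Δ) and the heading of
c(t+Δ) - c(t), divided by Δ. It is undefined wherever a centroid is missing
or a displacement vector has zero length (heading is meaningless for a
stationary animal); undefined timestamps are explicit NaNs, propagate into
the state series as ``undefined``, and are excluded from accuracy scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boxio import CalibrationConfig
from .kinematics import Track

__all__ = [
    "SplitRule",
    "angular_velocity",
    "classify",
    "ground_truth_states",
    "state_accuracy",
    "ROAMING",
    "DWELLING",
    "UNDEFINED",
]

log = logging.getLogger(__name__)

ROAMING = "roaming"
DWELLING = "dwelling"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class SplitRule:
    """Decision rule separating roaming from dwelling.

    Threshold form: ``angular_threshold`` in deg/min — angular velocity below
    the threshold is roaming, at or above it dwelling (inclusive boundary).

    2-D linear form: a line ``angular = slope * linear + intercept`` in
    (linear velocity mm/min, angular velocity deg/min) space; points on or
    above the line are dwelling, below it roaming. Used for labeling
    ground-truth states from higher-frequency reference data; its
    parameters must be supplied explicitly.
    """

    angular_threshold: float | None = None
    line_slope: float | None = None
    line_intercept: float | None = None

    def __post_init__(self) -> None:
        if self.angular_threshold is not None:
            if self.angular_threshold <= 0:
                raise ValueError("angular threshold must be positive")
        elif self.line_slope is None or self.line_intercept is None:
            raise ValueError(
                "SplitRule needs either angular_threshold or both line_slope "
                "and line_intercept"
            )

    @property
    def is_threshold(self) -> bool:
        return self.angular_threshold is not None


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180]."""
    return 180.0 - np.mod(180.0 - a, 360.0)


def angular_velocity(track: Track, delta: float, calibration: CalibrationConfig) -> pd.Series:
    """Three-point angular velocity in deg/min, indexed by timestamp.

    Defined at t only when centroids exist at t - delta, t and t + delta and
    both displacement vectors are nonzero; elsewhere NaN. ``delta`` must be a
    positive multiple of the native frame interval.
    """
    ratio = delta / calibration.frame_interval
    if delta <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"delta {delta} min is not a positive multiple of the native interval"
        )
    t = track.timestamps
    pos = track.centroids
    index = {round(ti / calibration.frame_interval): i for i, ti in enumerate(t)}
    step = round(ratio)

    out = np.full(len(t), np.nan)
    for k, i in index.items():
        ip = index.get(k - step)
        inx = index.get(k + step)
        if ip is None or inx is None:
            continue
        v1 = pos[i] - pos[ip]
        v2 = pos[inx] - pos[i]
        if np.hypot(*v1) == 0.0 or np.hypot(*v2) == 0.0:
            continue
        h1 = np.degrees(np.arctan2(v1[1], v1[0]))
        h2 = np.degrees(np.arctan2(v2[1], v2[0]))
        out[i] = abs(float(_wrap_deg(np.array(h2 - h1)))) / delta
    return pd.Series(out, index=t, name="angular_deg_per_min")


def classify(angular: pd.Series, rule: SplitRule) -> pd.Series:
    """Label each timestamp roaming/dwelling by the threshold rule.

    Angular velocity strictly below the threshold is roaming; at or above it
    dwelling. NaN (undefined) entries stay ``undefined``. Raising the
    threshold can only move timestamps from dwelling to roaming.
    """
    if not rule.is_threshold:
        raise ValueError("classify requires the threshold form of SplitRule")
    vals = angular.to_numpy(dtype=float)
    labels = np.where(vals < rule.angular_threshold, ROAMING, DWELLING)
    labels = np.where(np.isnan(vals), UNDEFINED, labels)
    return pd.Series(labels, index=angular.index, name="state")


def ground_truth_states(
    linear: pd.Series, angular: pd.Series, rule: SplitRule
) -> pd.Series:
    """Label states by a configured line in (linear, angular) velocity space.

    Both series must share a time grid (the intersection is used). Points on
    or above the line ``angular = slope * linear + intercept`` are dwelling,
    below it roaming — the same inclusive convention as the 1-D threshold.
    """
    if rule.is_threshold:
        raise ValueError("ground_truth_states requires the 2-D linear form of SplitRule")
    common = linear.index.intersection(angular.index)
    lin = linear.loc[common].to_numpy(dtype=float)
    ang = angular.loc[common].to_numpy(dtype=float)
    boundary = rule.line_slope * lin + rule.line_intercept
    labels = np.where(ang >= boundary, DWELLING, ROAMING)
    labels = np.where(np.isnan(ang) | np.isnan(lin), UNDEFINED, labels)
    return pd.Series(labels, index=common, name="state")


def state_accuracy(
    predicted: pd.Series, truth: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Fraction of agreeing timestamps among those defined in both series.

    Returns ``(accuracy, confusion)`` where ``confusion`` is the 2x2 table of
    truth (rows) vs prediction (columns) over roaming/dwelling. Undefined
    timestamps are excluded and their count logged.
    """
    common = predicted.index.intersection(truth.index)
    p = predicted.loc[common]
    t = truth.loc[common]
    defined = (p != UNDEFINED) & (t != UNDEFINED)
    n_excluded = int((~defined).sum())
    if n_excluded:
        log.info("state_accuracy: excluded %d undefined timestamps", n_excluded)
    p, t = p[defined], t[defined]
    if len(p) == 0:
        raise ValueError("no timestamps with both states defined")

    states = [ROAMING, DWELLING]
    confusion = pd.DataFrame(0, index=states, columns=states, dtype=int)
    for ts, ps in zip(t, p):
        confusion.loc[ts, ps] += 1
    accuracy = float((p.to_numpy() == t.to_numpy()).mean())
    return accuracy, confusion
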