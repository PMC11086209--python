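"""Posture metrics from pose-landmark time series.

A side-view camera and a 33-point whole-body landmark model provide image
coordinates of the right shoulder and right elbow (landmark ids 12 and 14
in the standard numbering).  The ergonomic summary is the time-averaged
absolute vertical velocity of each joint -- how much the arm bobs per
second -- plus its peak-to-peak vertical range as a secondary column.
Because only absolute vertical differences enter, the image convention
that y grows downward is immaterial.

Posture is recorded offline from video, so its clock is aligned to the
UNIX-stamped streams with a per-trial manual offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingLandmarkError

__all__ = [
    "LandmarkSeries",
    "PostureSummary",
    "RIGHT_SHOULDER",
    "RIGHT_ELBOW",
    "posture_summary",
    "align_posture_clock",
]

RIGHT_SHOULDER = 12
RIGHT_ELBOW = 14
N_LANDMARKS = 33


@dataclass(frozen=True)
class LandmarkSeries:
    """Long-form landmark track: per row one (t, landmark_id, x, y) sample."""

    t: np.ndarray
    landmark_id: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        lid = np.asarray(self.landmark_id, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("t", t), ("landmark_id", lid), ("x", x), ("y", y)):
            if arr.ndim != 1 or arr.size != t.size:
                raise ValueError(f"{name} must be 1-D and same length as t")
        if lid.size and (lid.min() < 0 or lid.max() >= N_LANDMARKS):
            raise ValueError(f"landmark ids must lie in 0..{N_LANDMARKS - 1}")
        for i in np.unique(lid):
            ti = t[lid == i]
            if ti.size > 1 and np.any(np.diff(ti) < 0):
                raise ValueError(f"timestamps for landmark {i} must be non-decreasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "landmark_id", lid)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.t.size)

    def for_landmark(
        self, landmark_id: int, window: tuple[float, float] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t, x, y) of one landmark, optionally restricted to [t0, t1)."""
        mask = self.landmark_id == landmark_id
        if window is not None:
            t0, t1 = window
            mask &= (self.t >= t0) & (self.t < t1)
        return self.t[mask], self.x[mask], self.y[mask]


@dataclass(frozen=True)
class PostureSummary:
    """Vertical-displacement metrics, coordinate-units per second / units."""

    elbow_vy: float
    shoulder_vy: float
    elbow_range_y: float
    shoulder_range_y: float


def _vy(t: np.ndarray, y: np.ndarray, name: str) -> tuple[float, float]:
    if t.size < 2:
        raise MissingLandmarkError(
            f"landmark '{name}' has {t.size} samples in window; need >= 2"
        )
    # mean |dy| / mean dt == sum |dy| / elapsed time
    vy = float(np.abs(np.diff(y)).sum() / (t[-1] - t[0]))
    return vy, float(y.max() - y.min())


def posture_summary(
    series: LandmarkSeries,
    task_window: tuple[float, float] | None = None,
    shoulder_id: int = RIGHT_SHOULDER,
    elbow_id: int = RIGHT_ELBOW,
) -> PostureSummary:
    """Time-averaged absolute vertical velocity of shoulder and elbow.

    The primary metric for each joint is ``sum(|dy|) / (t_end - t_start)``,
    i.e. the mean absolute first difference of y divided by the mean
    sampling interval.  Peak-to-peak vertical range is exported alongside.
    """
    te, _, ye = series.for_landmark(elbow_id, task_window)
    ts, _, ys = series.for_landmark(shoulder_id, task_window)
    elbow_vy, elbow_rng = _vy(te, ye, "right elbow")
    shoulder_vy, shoulder_rng = _vy(ts, ys, "right shoulder")
    return PostureSummary(
        elbow_vy=elbow_vy,
        shoulder_vy=shoulder_vy,
        elbow_range_y=elbow_rng,
        shoulder_range_y=shoulder_rng,
    )


def align_posture_clock(series: LandmarkSeries, offset_s: float) -> LandmarkSeries:
    """Shift all timestamps by ``offset_s`` (manual video synchronization)."""
    if not np.isfinite(offset_s):
        raise ValueError("offset must be finite")
    return LandmarkSeries(series.t + offset_s, series.landmark_id, series.x, series.y)
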