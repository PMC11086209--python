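"""Fiducial-marker hand kinematics.

The two hand controllers of a telesurgical console each carry a printed
marker; a third marker is fixed to the armrest as a stable reference so
that a loosely mounted camera can still deliver console-frame positions.
Each detection yields an axis-angle rotation ``rvec`` and a translation
``tvec`` in the camera frame; the camera's own depth estimate may replace
the less accurate ``tvec`` z-component.  Poses are lifted to homogeneous
rigid transforms via the Rodrigues map and rebased into the reference
marker's frame::

    H_k->ref = H_ref^-1 . H_k

Only the translation of the rebased pose is kept (the marker placement on
the controllers discards orientation by design).  Per-hand trajectories are
then reduced to the standard motion-analysis battery: 3-D spatial standard
deviation, bounding-box diagonal, total path length, average speed, and
mean jerk magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InsufficientDataError, MissingStreamError, UndefinedRatioError

__all__ = [
    "MarkerObservation",
    "RigidTransform",
    "Trajectory",
    "KinematicSummary",
    "REFERENCE_MARKER_ID",
    "HAND_MARKER_IDS",
    "substitute_depth",
    "to_homogeneous",
    "rebase",
    "build_trajectory",
    "kinematic_summary",
    "bimanuality_ratios",
]

REFERENCE_MARKER_ID = 1
HAND_MARKER_IDS = {"left": 2, "right": 3}

MARKER_COLUMNS = ["t_unix", "marker_id", "rx", "ry", "rz", "tx", "ty", "tz", "depth_m"]


@dataclass(frozen=True)
class MarkerObservation:
    """One marker detection: axis-angle rotation + translation, camera frame."""

    t: float
    marker_id: int
    rvec: np.ndarray
    tvec: np.ndarray
    depth_m: float | None = None

    def __post_init__(self) -> None:
        rvec = np.asarray(self.rvec, dtype=float)
        tvec = np.asarray(self.tvec, dtype=float)
        object.__setattr__(self, "rvec", rvec)
        object.__setattr__(self, "tvec", tvec)
        if rvec.shape != (3,) or tvec.shape != (3,):
            raise ValueError("rvec and tvec must be length-3 vectors")
        if np.linalg.norm(rvec) >= 2.0 * np.pi:
            raise ValueError("|rvec| must be < 2*pi")
        if self.depth_m is not None and not self.depth_m > 0:
            raise ValueError("depth_m must be positive when present")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: 3x3 rotation ``R`` and translation ``p`` (m)."""

    R: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "p", p)
        if R.shape != (3, 3) or p.shape != (3,):
            raise ValueError("R must be 3x3 and p length-3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal to 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("det(R) must be +1 (proper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.p)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.R @ other.R, self.R @ other.p + self.p)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.p

    def as_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.R
        H[:3, 3] = self.p
        return H


@dataclass(frozen=True)
class Trajectory:
    """Reference-frame position track of one hand marker.

    ``n_dropped`` counts the frames of the source stream in which either
    the reference or the hand marker was not detected.
    """

    t: np.ndarray
    pos: np.ndarray
    hand: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        pos = np.asarray(self.pos, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pos", pos)
        if t.size != pos.shape[0]:
            raise ValueError("t and pos lengths differ")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        if self.hand not in ("left", "right"):
            raise ValueError("hand must be 'left' or 'right'")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class KinematicSummary:
    """Per-hand motion metrics; all non-negative."""

    std3d_m: float
    range_m: float
    total_dist_m: float
    avg_speed_mps: float
    jerk_mps3: float
    extent_m: tuple[float, float, float] = (0.0, 0.0, 0.0)


def substitute_depth(obs: MarkerObservation) -> MarkerObservation:
    """Replace the tvec z-component with the RGB-D depth when available."""
    if obs.depth_m is None:
        return obs
    tvec = obs.tvec.copy()
    tvec[2] = obs.depth_m
    return replace(obs, tvec=tvec)


def to_homogeneous(rvec: np.ndarray, tvec: np.ndarray) -> RigidTransform:
    """Lift an axis-angle pose to a rigid transform via the Rodrigues map.

    ``rvec`` rotates by angle ``|rvec|`` about axis ``rvec/|rvec|``;
    ``rvec = 0`` yields the identity rotation.
    """
    rvec = np.asarray(rvec, dtype=float)
    tvec = np.asarray(tvec, dtype=float)
    if not (np.all(np.isfinite(rvec)) and np.all(np.isfinite(tvec))):
        raise ValueError("rvec/tvec must be finite")
    return RigidTransform(Rotation.from_rotvec(rvec).as_matrix(), tvec)


def rebase(h_ref: RigidTransform, h_k: RigidTransform) -> RigidTransform:
    """Express pose ``h_k`` in the frame of ``h_ref``: returns h_ref^-1 . h_k."""
    return h_ref.inverse() @ h_k


def _observations_to_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    rows = [
        {
            "t_unix": o.t,
            "marker_id": o.marker_id,
            "rx": o.rvec[0],
            "ry": o.rvec[1],
            "rz": o.rvec[2],
            "tx": o.tvec[0],
            "ty": o.tvec[1],
            "tz": o.tvec[2],
            "depth_m": np.nan if o.depth_m is None else o.depth_m,
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def build_trajectory(
    observations,
    hand: str,
    reference_id: int = REFERENCE_MARKER_ID,
    hand_ids: dict[str, int] | None = None,
) -> Trajectory:
    """Rebase one hand marker's detections into the reference-marker frame.

    ``observations`` is either a DataFrame with columns
    ``t_unix, marker_id, rx, ry, rz, tx, ty, tz, depth_m`` or a sequence of
    :class:`MarkerObservation`.  Per frame (identical timestamp) the hand
    pose is depth-substituted and rebased; the translation is kept and the
    orientation discarded.  Frames missing either marker are dropped and
    counted in ``n_dropped``.
    """
    hand_ids = HAND_MARKER_IDS if hand_ids is None else hand_ids
    df = _observations_to_frame(observations)
    marker_id = hand_ids[hand]

    ref = df[df["marker_id"] == reference_id]
    if ref.empty:
        raise MissingStreamError("reference marker never observed")
    mov = df[df["marker_id"] == marker_id]

    frames = np.unique(df["t_unix"].to_numpy())
    t_common, i_ref, i_mov = np.intersect1d(
        ref["t_unix"].to_numpy(), mov["t_unix"].to_numpy(), return_indices=True
    )
    n_dropped = int(frames.size - t_common.size)
    if t_common.size == 0:
        return Trajectory(
            np.empty(0), np.empty((0, 3)), hand=hand, n_dropped=n_dropped
        )

    def poses(sub: pd.DataFrame, idx: np.ndarray):
        rvecs = sub[["rx", "ry", "rz"]].to_numpy()[idx]
        tvecs = sub[["tx", "ty", "tz"]].to_numpy()[idx].copy()
        depth = sub["depth_m"].to_numpy()[idx]
        has_depth = np.isfinite(depth)
        tvecs[has_depth, 2] = depth[has_depth]
        return Rotation.from_rotvec(rvecs), tvecs

    r_ref, p_ref = poses(ref, i_ref)
    _, p_mov = poses(mov, i_mov)
    # translation of H_ref^-1 . H_mov (batch)
    pos = r_ref.inv().apply(p_mov - p_ref)
    return Trajectory(t_common, pos, hand=hand, n_dropped=n_dropped)


def _segment_bounds(t: np.ndarray, max_gap_s: float) -> list[tuple[int, int]]:
    """Index ranges [i, j) of contiguous runs with inter-sample gaps <= max_gap_s."""
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > max_gap_s) + 1
    edges = np.concatenate([[0], breaks, [t.size]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _mean_jerk(
    t: np.ndarray, pos: np.ndarray, grid_hz: float, max_gap_s: float
) -> float:
    """Duration-weighted mean |jerk| over gap-free segments.

    Each segment is resampled onto a uniform grid by linear interpolation;
    the third derivative is taken with the 5-point central stencil
    (x[i+2] - 2 x[i+1] + 2 x[i-1] - x[i-2]) / (2 h^3).  Gaps longer than
    ``max_gap_s`` are never interpolated across; segments too short for the
    stencil contribute nothing.  Returns 0.0 if no segment is long enough.
    """
    h = 1.0 / grid_hz
    total_w = 0.0
    acc = 0.0
    for a, b in _segment_bounds(t, max_gap_s):
        dur = t[b - 1] - t[a]
        n_grid = int(np.floor(dur * grid_hz + 1e-9)) + 1
        if n_grid < 5:
            continue
        tg = t[a] + np.arange(n_grid) * h
        x = np.column_stack(
            [np.interp(tg, t[a:b], pos[a:b, k]) for k in range(3)]
        )
        d3 = (x[4:] - 2.0 * x[3:-1] + 2.0 * x[1:-3] - x[:-4]) / (2.0 * h**3)
        seg_jerk = float(np.linalg.norm(d3, axis=1).mean())
        acc += seg_jerk * dur
        total_w += dur
    return acc / total_w if total_w > 0 else 0.0


def kinematic_summary(
    traj: Trajectory, grid_hz: float = 10.0, max_gap_s: float = 0.5
) -> KinematicSummary:
    """Reduce a trajectory to the hand-movement metric battery.

    * ``std3d_m``: sqrt of the summed per-axis population variances (3-D
      spatial standard deviation);
    * ``range_m``: Euclidean norm of the per-axis extents, i.e. the
      bounding-box diagonal (per-axis extents exported in ``extent_m``);
    * ``total_dist_m``: summed consecutive Euclidean steps;
    * ``avg_speed_mps``: total distance over elapsed time;
    * ``jerk_mps3``: mean third-derivative magnitude, see :func:`_mean_jerk`.
    """
    n = len(traj)
    if n < 2:
        raise InsufficientDataError(
            f"kinematic summary requires >= 2 samples (got {n})"
        )
    if n < 4:
        raise InsufficientDataError(f"jerk requires >= 4 samples (got {n})")
    pos = traj.pos
    var = pos.var(axis=0)  # population variance
    std3d = float(np.sqrt(var.sum()))
    extent = pos.max(axis=0) - pos.min(axis=0)
    rng = float(np.linalg.norm(extent))
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    total = float(steps.sum())
    elapsed = float(traj.t[-1] - traj.t[0])
    speed = total / elapsed
    jerk = _mean_jerk(traj.t, pos, grid_hz=grid_hz, max_gap_s=max_gap_s)
    return KinematicSummary(
        std3d_m=std3d,
        range_m=rng,
        total_dist_m=total,
        avg_speed_mps=speed,
        jerk_mps3=jerk,
        extent_m=tuple(float(e) for e in extent),
    )


def bimanuality_ratios(
    right: KinematicSummary, left: KinematicSummary
) -> tuple[float, float]:
    """Dominant/non-dominant ratios of total distance and bounding-box range.

    The dominant hand is the right one (all study subjects right-handed);
    callers with left-dominant subjects can swap the arguments.
    """
    if left.total_dist_m == 0.0 or left.range_m == 0.0:
        raise UndefinedRatioError(
            "non-dominant hand metric is zero; bimanuality ratio undefined"
        )
    return (
        right.total_dist_m / left.total_dist_m,
        right.range_m / left.range_m,
    )
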