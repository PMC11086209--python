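"""Per-trial metric table assembly and the stress-correlation screen.

One trial bundles all sensor streams of one subject performing one task:
the RR series (wearable chest band), the two rebased hand trajectories,
the posture landmark series, the six-question SURG-TLX workload responses
(each 1..20), and manually recorded task scores.  The metric table holds
one row per trial: the Baevsky stress index plus the 25-metric battery
(10 hand-kinematic, 2 bimanuality ratios, 2 posture, 6 SURG-TLX, 5
manual).  Each non-BSI metric is screened against BSI with a Pearson
correlation; two-sided p-values are tiered as::

    p < 0.05          strong (statistically significant)
    0.05 <= p <= 0.08 weak   (possible, worth a larger dataset)
    p > 0.08          none

Degenerate metrics are flagged as missing (NaN), never zero-filled, and
are removed pairwise per correlation, so each report row carries its own
pair count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    MissingStreamError,
    SurgStressError,
    UndefinedCorrelationError,
)
from .hrv import RRSeries, per_task_bsi
from .kinematics import Trajectory, bimanuality_ratios, kinematic_summary
from .posture import LandmarkSeries, align_posture_clock, posture_summary

__all__ = [
    "SurgTLX",
    "ManualScores",
    "TrialRecord",
    "TABLE_METRICS",
    "synchronize",
    "build_metric_table",
    "pearson_with_p",
    "significance_tier",
    "correlation_report",
]

GROUPS = ("novice", "resident", "surgeon")

#: Battery of screened metrics, in report order.
TABLE_METRICS = [
    "Lefthand_std",
    "Lefthand_range",
    "Lefthand_total_dist",
    "Lefthand_avg_speed",
    "Left_jerk",
    "Righthand_std",
    "Righthand_range",
    "Righthand_total_dist",
    "Righthand_avg_speed",
    "Right_jerk",
    "Total_dist_rate",
    "Range_rate",
    "Elbow_vy",
    "Shoulder_vy",
    "Mental_fatigue",
    "Physical_fatigue",
    "Temporal_demands",
    "Complexity",
    "Situational_stress",
    "Distractions",
    "Collisions_phantom",
    "Collision_robot_arms",
    "Rings_placed",
    "Ring_drops",
    "Spike_color_missed",
]


@dataclass(frozen=True)
class SurgTLX:
    """Six-dimension surgical task-load questionnaire, each answer 1..20."""

    mental: int
    physical: int
    temporal: int
    complexity: int
    situational_stress: int
    distractions: int

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (1 <= int(v) <= 20):
                raise ValueError(f"SURG-TLX '{f.name}' must be in 1..20, got {v}")
            object.__setattr__(self, f.name, int(v))

    def as_metrics(self) -> dict[str, int]:
        return {
            "Mental_fatigue": self.mental,
            "Physical_fatigue": self.physical,
            "Temporal_demands": self.temporal,
            "Complexity": self.complexity,
            "Situational_stress": self.situational_stress,
            "Distractions": self.distractions,
        }


@dataclass(frozen=True)
class ManualScores:
    """Manually recorded per-trial task scores (non-negative counts)."""

    collisions_phantom: int
    collision_robot_arms: int
    rings_placed: int
    ring_drops: int
    spike_color_missed: int

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = int(getattr(self, f.name))
            if v < 0:
                raise ValueError(f"manual score '{f.name}' must be >= 0")
            object.__setattr__(self, f.name, v)

    def as_metrics(self) -> dict[str, int]:
        return {
            "Collisions_phantom": self.collisions_phantom,
            "Collision_robot_arms": self.collision_robot_arms,
            "Rings_placed": self.rings_placed,
            "Ring_drops": self.ring_drops,
            "Spike_color_missed": self.spike_color_missed,
        }


@dataclass(frozen=True)
class TrialRecord:
    """One subject-task unit bundling all streams and scores."""

    subject_id: str
    group: str
    task_id: int
    task_window: tuple[float, float]
    rr: RRSeries
    left: Trajectory
    right: Trajectory
    posture: LandmarkSeries
    tlx: SurgTLX
    manual: ManualScores
    posture_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        t0, t1 = self.task_window
        if not t1 > t0:
            raise ValueError("task window must be well-ordered (t_end > t_start)")


def _resample_traj(traj: Trajectory, grid: np.ndarray, name: str) -> Trajectory:
    if len(traj) == 0 or traj.t[-1] < grid[0] or traj.t[0] > grid[-1]:
        raise MissingStreamError(f"{name} trajectory does not overlap the task window")
    pos = np.column_stack(
        [np.interp(grid, traj.t, traj.pos[:, k]) for k in range(3)]
    )
    return Trajectory(grid, pos, hand=traj.hand, n_dropped=traj.n_dropped)


def _task_grid(task_window: tuple[float, float], grid_hz: float) -> np.ndarray:
    t0, t1 = task_window
    n = int(np.floor((t1 - t0) * grid_hz + 1e-9)) + 1
    return t0 + np.arange(n) / grid_hz


def _resample_posture(
    posture: LandmarkSeries, offset_s: float, grid: np.ndarray
) -> LandmarkSeries:
    shifted = align_posture_clock(posture, offset_s)
    ts, lids, xs, ys = [], [], [], []
    for lid in np.unique(shifted.landmark_id):
        t, x, y = shifted.for_landmark(int(lid))
        if t.size == 0 or t[-1] < grid[0] or t[0] > grid[-1]:
            raise MissingStreamError(
                f"posture landmark {lid} does not overlap the task window"
            )
        ts.append(grid)
        lids.append(np.full(grid.size, lid, dtype=int))
        xs.append(np.interp(grid, t, x))
        ys.append(np.interp(grid, t, y))
    if not ts:
        raise MissingStreamError("posture stream is empty")
    return LandmarkSeries(
        np.concatenate(ts), np.concatenate(lids), np.concatenate(xs), np.concatenate(ys)
    )


def synchronize(trial: TrialRecord, grid_hz: float = 10.0) -> TrialRecord:
    """Resample trajectories and posture onto a common grid over the window.

    All UNIX-stamped streams are linearly interpolated onto a ``grid_hz``
    grid spanning the task window; the posture clock is first shifted by
    the trial's manual offset.  The RR series is left as an event series
    and consumed per-window by the HRV stage.
    """
    grid = _task_grid(trial.task_window, grid_hz)
    left = _resample_traj(trial.left, grid, "left")
    right = _resample_traj(trial.right, grid, "right")
    posture_grid = _resample_posture(trial.posture, trial.posture_offset_s, grid)
    return dataclasses.replace(
        trial, left=left, right=right, posture=posture_grid, posture_offset_s=0.0
    )


def build_metric_table(
    trials: list[TrialRecord], grid_hz: float = 10.0
) -> pd.DataFrame:
    """Assemble the per-trial metric table (one row per trial).

    Columns: ``subject_id, group, task_id, BSI`` plus :data:`TABLE_METRICS`.
    Degenerate per-metric computations (too few beats, zero-denominator
    ratios, missing landmarks, ...) are flagged as NaN rather than failing
    the table; those rows are excluded pairwise from the flagged metric's
    correlation downstream.
    """
    if len(trials) < 3:
        raise InsufficientDataError("metric table requires >= 3 trials")
    rows = []
    for trial in trials:
        row: dict[str, object] = {
            "subject_id": trial.subject_id,
            "group": trial.group,
            "task_id": trial.task_id,
        }
        row.update({m: np.nan for m in ["BSI"] + TABLE_METRICS})
        try:
            row["BSI"] = per_task_bsi(trial.rr, trial.task_window).si
        except SurgStressError:
            pass
        grid = _task_grid(trial.task_window, grid_hz)
        summaries = {}
        for hand, prefix in (("left", "Lefthand"), ("right", "Righthand")):
            try:
                traj = _resample_traj(getattr(trial, hand), grid, hand)
                ks = kinematic_summary(traj, grid_hz=grid_hz)
                summaries[hand] = ks
                row[f"{prefix}_std"] = ks.std3d_m
                row[f"{prefix}_range"] = ks.range_m
                row[f"{prefix}_total_dist"] = ks.total_dist_m
                row[f"{prefix}_avg_speed"] = ks.avg_speed_mps
                row[f"{prefix.split('hand')[0]}_jerk"] = ks.jerk_mps3
            except SurgStressError:
                pass
        if "left" in summaries and "right" in summaries:
            try:
                dist_rate, range_rate = bimanuality_ratios(
                    summaries["right"], summaries["left"]
                )
                row["Total_dist_rate"] = dist_rate
                row["Range_rate"] = range_rate
            except SurgStressError:
                pass
        try:
            posture = _resample_posture(trial.posture, trial.posture_offset_s, grid)
            ps = posture_summary(posture, trial.task_window)
            row["Elbow_vy"] = ps.elbow_vy
            row["Shoulder_vy"] = ps.shoulder_vy
        except SurgStressError:
            pass
        row.update(trial.tlx.as_metrics())
        row.update(trial.manual.as_metrics())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "group", "task_id", "BSI"] + TABLE_METRICS)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided p-value.

    NaN pairs are deleted pairwise; the p-value comes from the exact
    t-distribution of ``t = r sqrt((n-2)/(1-r^2))`` with n-2 degrees of
    freedom.  Requires >= 3 complete pairs and nonzero variance in both
    variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("zero variance; correlation undefined")
    res = stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue), n


def significance_tier(p: float) -> str:
    """Tier a p-value: 'strong' (<0.05), 'weak' (0.05..0.08 closed), 'none'."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.05:
        return "strong"
    if p <= 0.08:
        return "weak"
    return "none"


def correlation_report(table: pd.DataFrame) -> pd.DataFrame:
    """Screen every battery metric against BSI.

    Returns one row per metric in :data:`TABLE_METRICS` order with columns
    ``metric, r, p, n_pairs, tier, sign``.  Metrics with too few valid
    pairs or zero variance are emitted with tier ``insufficient data``.
    """
    bsi = table["BSI"].to_numpy(dtype=float)
    if int(np.isfinite(bsi).sum()) < 3:
        raise InsufficientDataError("BSI column has fewer than 3 valid entries")
    rows = []
    for metric in TABLE_METRICS:
        vals = table[metric].to_numpy(dtype=float)
        try:
            r, p, n = pearson_with_p(vals, bsi)
            tier = significance_tier(p)
            sign = "+" if r > 0 else ("-" if r < 0 else "")
        except SurgStressError:
            r, p = np.nan, np.nan
            n = int((np.isfinite(vals) & np.isfinite(bsi)).sum())
            tier, sign = "insufficient data", ""
        rows.append(
            {"metric": metric, "r": r, "p": p, "n_pairs": n, "tier": tier, "sign": sign}
        )
    return pd.DataFrame(rows, columns=["metric", "r", "p", "n_pairs", "tier", "sign"])
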