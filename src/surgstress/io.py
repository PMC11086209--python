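"""Plain-text stream formats and the trial manifest.

All streams travel as headered CSV:

* RR:        ``t_unix,rr_ms``                   (one row per beat)
* markers:   ``t_unix,marker_id,rx,ry,rz,tx,ty,tz,depth_m``
* posture:   ``t_unix,landmark_id,x,y``
* trajectory:``t_unix,hand,x,y,z``

A cohort on disk is a directory of per-trial stream files plus a YAML
manifest listing, per trial: the stream paths, the task window, the
posture clock offset, SURG-TLX answers and manual scores.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correlation import ManualScores, SurgTLX, TrialRecord
from .hrv import RRSeries
from .kinematics import MARKER_COLUMNS, Trajectory, build_trajectory
from .posture import LandmarkSeries

__all__ = [
    "read_rr_csv",
    "write_rr_csv",
    "read_markers_csv",
    "write_markers_csv",
    "read_posture_csv",
    "write_posture_csv",
    "write_trajectory_csv",
    "write_cohort",
    "read_manifest",
    "write_bsi_json",
]


def read_rr_csv(path) -> RRSeries:
    df = pd.read_csv(path)
    return RRSeries(df["t_unix"].to_numpy(), df["rr_ms"].to_numpy())


def write_rr_csv(rr: RRSeries, path) -> None:
    pd.DataFrame({"t_unix": rr.t, "rr_ms": rr.rr_ms}).to_csv(path, index=False)


def read_markers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker CSV missing columns: {sorted(missing)}")
    return df[MARKER_COLUMNS]


def write_markers_csv(observations: pd.DataFrame, path) -> None:
    observations[MARKER_COLUMNS].to_csv(path, index=False)


def read_posture_csv(path) -> LandmarkSeries:
    df = pd.read_csv(path)
    return LandmarkSeries(
        df["t_unix"].to_numpy(),
        df["landmark_id"].to_numpy(),
        df["x"].to_numpy(),
        df["y"].to_numpy(),
    )


def write_posture_csv(series: LandmarkSeries, path) -> None:
    pd.DataFrame(
        {
            "t_unix": series.t,
            "landmark_id": series.landmark_id,
            "x": series.x,
            "y": series.y,
        }
    ).to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {
            "t_unix": traj.t,
            "hand": traj.hand,
            "x": traj.pos[:, 0],
            "y": traj.pos[:, 1],
            "z": traj.pos[:, 2],
        }
    ).to_csv(path, index=False)


def write_bsi_json(result, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def write_cohort(trials, out_dir, observations=None, ground_truth=None) -> Path:
    """Write a cohort to ``out_dir`` as stream CSVs + ``manifest.yaml``.

    ``observations`` optionally maps trial index -> raw marker DataFrame;
    when absent the rebased trajectories are written instead (the manifest
    records which form each trial uses).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, trial in enumerate(trials):
        stem = f"trial_{i:03d}"
        rr_path = f"{stem}_rr.csv"
        posture_path = f"{stem}_posture.csv"
        write_rr_csv(trial.rr, out / rr_path)
        write_posture_csv(trial.posture, out / posture_path)
        entry = {
            "subject_id": trial.subject_id,
            "group": trial.group,
            "task_id": int(trial.task_id),
            "task_window": [float(trial.task_window[0]), float(trial.task_window[1])],
            "posture_offset_s": float(trial.posture_offset_s),
            "rr_csv": rr_path,
            "posture_csv": posture_path,
            "surg_tlx": {
                "mental": trial.tlx.mental,
                "physical": trial.tlx.physical,
                "temporal": trial.tlx.temporal,
                "complexity": trial.tlx.complexity,
                "situational_stress": trial.tlx.situational_stress,
                "distractions": trial.tlx.distractions,
            },
            "manual_scores": {
                "collisions_phantom": trial.manual.collisions_phantom,
                "collision_robot_arms": trial.manual.collision_robot_arms,
                "rings_placed": trial.manual.rings_placed,
                "ring_drops": trial.manual.ring_drops,
                "spike_color_missed": trial.manual.spike_color_missed,
            },
        }
        if observations is not None and i in observations:
            markers_path = f"{stem}_markers.csv"
            write_markers_csv(observations[i], out / markers_path)
            entry["markers_csv"] = markers_path
        else:
            for hand in ("left", "right"):
                traj_path = f"{stem}_{hand}.csv"
                write_trajectory_csv(getattr(trial, hand), out / traj_path)
                entry[f"{hand}_csv"] = traj_path
        entries.append(entry)
    manifest = {"trials": entries}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return out / "manifest.yaml"


def _read_trajectory_csv(path, hand) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        df["t_unix"].to_numpy(), df[["x", "y", "z"]].to_numpy(), hand=hand
    )


def read_manifest(manifest_path) -> list[TrialRecord]:
    """Load a cohort manifest back into trial records.

    Trials listing a raw ``markers_csv`` are rebased through
    :func:`surgstress.kinematics.build_trajectory`; trials listing
    pre-rebased trajectory CSVs are loaded as-is.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    trials = []
    for entry in manifest["trials"]:
        if "markers_csv" in entry:
            obs = read_markers_csv(base / entry["markers_csv"])
            left = build_trajectory(obs, "left")
            right = build_trajectory(obs, "right")
        else:
            left = _read_trajectory_csv(base / entry["left_csv"], "left")
            right = _read_trajectory_csv(base / entry["right_csv"], "right")
        trials.append(
            TrialRecord(
                subject_id=entry["subject_id"],
                group=entry["group"],
                task_id=int(entry["task_id"]),
                task_window=tuple(entry["task_window"]),
                rr=read_rr_csv(base / entry["rr_csv"]),
                left=left,
                right=right,
                posture=read_posture_csv(base / entry["posture_csv"]),
                tlx=SurgTLX(**entry["surg_tlx"]),
                manual=ManualScores(**entry["manual_scores"]),
                posture_offset_s=float(entry.get("posture_offset_s", 0.0)),
            )
        )
    return trials
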