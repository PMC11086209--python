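"""Synthetic cohort generator with planted stress and skill structure.

No public recording of the study streams exists, so every pipeline stage
is exercised on synthetic trials that emulate the experimental design:
three skill groups (novice / resident / surgeon, five subjects each),
four console tasks per subject of about two minutes, 58 trials in total.

Each trial carries a latent stress level ``s ~ Uniform(0, 1)`` and a group
skill level.  The planted causal structure is:

* RR intervals are truncated-Gaussian with mean ``900 - 150 s`` ms and
  spread ``90 (1 - 0.7 s)`` ms, so higher stress compresses variability
  and drives the Baevsky index up (a deliberate simplification: the index
  only consumes histogram statistics, not beat morphology).
* Hand trajectories are band-limited noise rescaled into per-hand
  bounding boxes.  The left (non-dominant) box grows with stress
  (``0.05 + 0.06 s`` m); the right box is fixed at the size that puts the
  box-diagonal ratio at 6.2 for mid stress.  The right hand's temporal
  bandwidth falls with stress, so its path length drops while the
  dominant/non-dominant path ratio is calibrated to 1.7 at mid stress.
  A small high-frequency jitter whose amplitude grows with stress feeds
  the jerk metrics and the approximate-entropy features.
* Markers are emitted in *camera* frame through a slowly wobbling
  synthetic camera pose, so the reference-frame rebasing is exercised
  nontrivially and must recover the planted trajectories exactly.
* Posture oscillation amplitude grows with stress; questionnaire answers
  for physical fatigue and distractions follow ``1 + 12 s`` plus
  discretized Gaussian noise clipped into 1..20, the remaining four
  questions are stress-independent noise; manual error counts are Poisson
  with rates decreasing in skill (and independent of stress).

``generate_cohort`` returns the trials plus a ground-truth table of the
planted latents and the expected correlation sign of every battery metric
against the stress index.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .correlation import TABLE_METRICS, ManualScores, SurgTLX, TrialRecord
from .hrv import RRSeries
from .kinematics import (
    HAND_MARKER_IDS,
    MARKER_COLUMNS,
    REFERENCE_MARKER_ID,
    Trajectory,
    build_trajectory,
)
from .posture import RIGHT_ELBOW, RIGHT_SHOULDER, LandmarkSeries

__all__ = [
    "CohortSpec",
    "GROUP_SKILL",
    "PLANTED_SIGNS",
    "generate_rr",
    "generate_hand_trajectories",
    "generate_posture",
    "generate_trial",
    "generate_cohort",
]

GROUP_SKILL = {"novice": 0.0, "resident": 0.5, "surgeon": 1.0}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design and planted-effect parameters of the synthetic cohort."""

    # cohort design
    n_per_group: int = 5
    groups: tuple[str, ...] = ("novice", "resident", "surgeon")
    tasks_per_subject: int = 4
    n_trials: int = 58            # two trials lost to incomplete recordings
    duration_s: float = 120.0
    grid_hz: float = 10.0
    seed: int = 1234

    # RR model (ms)
    rr_mean_base: float = 900.0
    rr_mean_slope: float = -150.0
    rr_sd_base: float = 90.0
    rr_sd_shrink: float = 0.7
    rr_floor_ms: float = 300.0

    # hand-trajectory model (m / Hz); right-hand box and the bandwidth law
    # are calibrated so that at s = 0.5 the cohort bounding-box-diagonal
    # ratio is ~6.2 and the dominant/non-dominant path ratio is ~1.7
    left_scale_base: float = 0.05
    left_scale_slope: float = 0.06
    right_scale: float = 0.496
    left_cutoff_hz: float = 1.0
    right_cutoff_base: float = 0.345
    right_cutoff_slope: float = -0.22
    jitter_base_m: float = 0.0005
    jitter_slope_m: float = 0.0010
    jitter_band_hz: tuple[float, float] = (2.5, 4.5)
    # stress-independent per-trial variability of the box sizes; without it
    # the fixed right-hand box would leave the (stress-linked) jitter as the
    # only variance source and fake a stress link in the right-box metrics
    scale_noise_sd: float = 0.05
    left_center: tuple[float, float, float] = (-0.15, 0.0, 0.05)
    right_center: tuple[float, float, float] = (0.15, 0.0, 0.05)

    # synthetic camera (world units = reference-marker frame at identity)
    camera_offset: tuple[float, float, float] = (0.0, 0.1, -1.0)
    wobble_rot_rad: float = 0.03
    wobble_trans_m: float = 0.005
    wobble_cutoff_hz: float = 0.2
    marker_dropout: float = 0.0

    # posture model (normalized image coordinates)
    posture_hz: float = 10.0
    elbow_amp: float = 0.04
    shoulder_amp: float = 0.025
    posture_amp_base: float = 0.2   # amplitude factor = base + slope * s
    posture_amp_slope: float = 0.8
    posture_cutoff_hz: float = 0.8
    posture_noise: float = 0.002
    posture_drift: float = 0.01

    # SURG-TLX links (answers 1..20)
    tlx_slope: float = 12.0
    tlx_noise_sd: float = 2.0

    # manual-score rates at skill 0; linearly reduced by skill
    manual_base_rates: dict = field(
        default_factory=lambda: {
            "collisions_phantom": 3.0,
            "collision_robot_arms": 2.0,
            "ring_drops": 2.5,
            "spike_color_missed": 1.5,
        }
    )
    manual_skill_shrink: float = 0.6
    rings_placed_p_base: float = 0.5
    rings_placed_p_slope: float = 0.45


#: Expected sign of each battery metric's correlation with BSI under the
#: planted structure (+1 / -1 planted link through latent stress, 0 null).
PLANTED_SIGNS: dict[str, int] = {
    "Lefthand_std": +1,
    "Lefthand_range": +1,
    "Lefthand_total_dist": +1,
    "Lefthand_avg_speed": +1,
    "Left_jerk": +1,
    # the bandwidth law concentrates the slower (stressed) right hand near
    # its box edges, so spatial std rises with stress although the box is
    # unchanged: a mediated planted link, not a null
    "Righthand_std": +1,
    "Righthand_range": 0,
    "Righthand_total_dist": -1,
    "Righthand_avg_speed": -1,
    "Right_jerk": +1,
    "Total_dist_rate": -1,
    "Range_rate": -1,
    "Elbow_vy": +1,
    "Shoulder_vy": +1,
    "Mental_fatigue": 0,
    "Physical_fatigue": +1,
    "Temporal_demands": 0,
    "Complexity": 0,
    "Situational_stress": 0,
    "Distractions": +1,
    "Collisions_phantom": 0,
    "Collision_robot_arms": 0,
    "Rings_placed": 0,
    "Ring_drops": 0,
    "Spike_color_missed": 0,
}
assert set(PLANTED_SIGNS) == set(TABLE_METRICS)


def _lowpass_noise(n: int, fs: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """White noise low-passed at ``cutoff`` Hz via FFT truncation."""
    if cutoff <= 0 or n < 2:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[freqs > cutoff] = 0.0
    return np.fft.irfft(spec, n)


def _bandpass_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    return np.fft.irfft(spec, n)


def _rescale(x: np.ndarray, half_extent: float, center: float) -> np.ndarray:
    """Affinely map a signal onto [center - half_extent, center + half_extent]."""
    span = np.ptp(x)
    if span == 0 or half_extent == 0:
        return np.full_like(x, center)
    return (x - x.min()) / span * (2 * half_extent) - half_extent + center


def generate_rr(
    duration_s: float,
    spec: CohortSpec,
    s: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> RRSeries:
    """Truncated-Gaussian RR series covering [t0, t0 + duration_s]."""
    if duration_s <= 10:
        raise ValueError("duration must exceed 10 s")
    mean = spec.rr_mean_base + spec.rr_mean_slope * s
    sd = spec.rr_sd_base * (1.0 - spec.rr_sd_shrink * s)
    n_draw = int(duration_s / (mean / 1000.0) * 1.5) + 20
    rr = np.maximum(rng.normal(mean, sd, n_draw), spec.rr_floor_ms)
    t = t0 + np.cumsum(rr) / 1000.0
    keep = t <= t0 + duration_s + mean / 1000.0
    return RRSeries(t[keep], rr[keep])


def _hand_signal(
    n: int,
    fs: float,
    half_extent: float,
    cutoff: float,
    center: np.ndarray,
    jitter_amp: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    pos = np.empty((n, 3))
    for k in range(3):
        smooth = _rescale(_lowpass_noise(n, fs, cutoff, rng), half_extent, center[k])
        if jitter_amp > 0:
            j = _bandpass_noise(n, fs, band, rng)
            jr = np.sqrt(np.mean(j**2))
            if jr > 0:
                j *= jitter_amp / jr
            smooth = smooth + j
        pos[:, k] = smooth
    return pos


def generate_hand_trajectories(
    duration_s: float,
    spec: CohortSpec,
    s: float,
    skill: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> tuple[Trajectory, Trajectory, pd.DataFrame]:
    """Planted left/right trajectories plus camera-frame marker observations.

    Returns ``(left, right, observations)`` where the trajectories are in
    the reference-marker frame and ``observations`` is the raw marker CSV
    table (reference + both hand markers) as seen through a wobbling
    camera.  Rebasing the observations must reproduce the planted
    trajectories to machine precision.
    """
    fs = spec.grid_hz
    n = int(round(duration_s * fs)) + 1
    t = t0 + np.arange(n) / fs

    jitter_amp = spec.jitter_base_m + spec.jitter_slope_m * s
    left_half = (spec.left_scale_base + spec.left_scale_slope * s) / 2.0
    right_half = spec.right_scale / 2.0
    if spec.scale_noise_sd > 0:
        left_half *= float(np.exp(rng.normal(0.0, spec.scale_noise_sd)))
        right_half *= float(np.exp(rng.normal(0.0, spec.scale_noise_sd)))
    right_cutoff = max(spec.right_cutoff_base + spec.right_cutoff_slope * s, 0.05)

    left_pos = _hand_signal(
        n, fs, left_half, spec.left_cutoff_hz, np.asarray(spec.left_center),
        jitter_amp, spec.jitter_band_hz, rng,
    )
    right_pos = _hand_signal(
        n, fs, right_half, right_cutoff, np.asarray(spec.right_center),
        jitter_amp, spec.jitter_band_hz, rng,
    )
    left = Trajectory(t, left_pos, hand="left")
    right = Trajectory(t, right_pos, hand="right")

    # reference marker pose in world (fixed, mildly rotated)
    r_ref = Rotation.from_rotvec([0.15, -0.1, 0.05])
    p_ref = np.array([0.0, -0.3, 0.0])

    # wobbling camera: slow low-passed pose noise around a base offset
    wob_r = np.column_stack(
        [_lowpass_noise(n, fs, spec.wobble_cutoff_hz, rng) for _ in range(3)]
    )
    wob_p = np.column_stack(
        [_lowpass_noise(n, fs, spec.wobble_cutoff_hz, rng) for _ in range(3)]
    )

    def _norm(w: np.ndarray, amp: float) -> np.ndarray:
        r = np.sqrt(np.mean(w**2))
        return w * (amp / r) if r > 0 else w

    r_cam = Rotation.from_rotvec(_norm(wob_r, spec.wobble_rot_rad))
    p_cam = np.asarray(spec.camera_offset) + p_ref + _norm(wob_p, spec.wobble_trans_m)

    frames = []
    r_cam_inv = r_cam.inv()
    for marker_id, world_pos, world_rot in (
        (REFERENCE_MARKER_ID, np.tile(p_ref, (n, 1)), r_ref),
        (HAND_MARKER_IDS["left"], p_ref + r_ref.apply(left_pos), r_ref),
        (HAND_MARKER_IDS["right"], p_ref + r_ref.apply(right_pos), r_ref),
    ):
        rvec = (r_cam_inv * world_rot).as_rotvec()
        tvec = r_cam_inv.apply(world_pos - p_cam)
        if rvec.ndim == 1:
            rvec = np.tile(rvec, (n, 1))
        keep = np.ones(n, dtype=bool)
        if spec.marker_dropout > 0:
            keep = rng.random(n) >= spec.marker_dropout
        frames.append(
            pd.DataFrame(
                {
                    "t_unix": t[keep],
                    "marker_id": marker_id,
                    "rx": rvec[keep, 0],
                    "ry": rvec[keep, 1],
                    "rz": rvec[keep, 2],
                    "tx": tvec[keep, 0],
                    "ty": tvec[keep, 1],
                    "tz": tvec[keep, 2],
                    "depth_m": tvec[keep, 2],
                }
            )
        )
    observations = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["t_unix", "marker_id"], kind="stable")
        .reset_index(drop=True)[MARKER_COLUMNS]
    )
    return left, right, observations


def generate_posture(
    duration_s: float,
    spec: CohortSpec,
    s: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> LandmarkSeries:
    """Shoulder/elbow landmark series: baseline + drift + stress-scaled sway."""
    fs = spec.posture_hz
    n = int(round(duration_s * fs)) + 1
    t = t0 + np.arange(n) / fs
    amp_factor = spec.posture_amp_base + spec.posture_amp_slope * s

    def channel(baseline: float, amp: float) -> np.ndarray:
        osc = _lowpass_noise(n, fs, spec.posture_cutoff_hz, rng)
        r = np.sqrt(np.mean(osc**2))
        if r > 0:
            osc *= amp / r
        drift = _lowpass_noise(n, fs, 0.05, rng)
        rd = np.sqrt(np.mean(drift**2))
        if rd > 0:
            drift *= spec.posture_drift / rd
        return baseline + drift + osc + spec.posture_noise * rng.standard_normal(n)

    sh_y = channel(0.35, spec.shoulder_amp * amp_factor)
    el_y = channel(0.55, spec.elbow_amp * amp_factor)
    sh_x = channel(0.60, 0.01)
    el_x = channel(0.62, 0.015)
    return LandmarkSeries(
        t=np.concatenate([t, t]),
        landmark_id=np.concatenate(
            [np.full(n, RIGHT_SHOULDER), np.full(n, RIGHT_ELBOW)]
        ),
        x=np.concatenate([sh_x, el_x]),
        y=np.concatenate([sh_y, el_y]),
    )


def _tlx_answer(linked: bool, s: float, spec: CohortSpec, rng: np.random.Generator,
                noise_mean: float = 10.0, noise_sd: float = 4.0) -> int:
    if linked:
        raw = 1.0 + spec.tlx_slope * s + rng.normal(0.0, spec.tlx_noise_sd)
    else:
        raw = rng.normal(noise_mean, noise_sd)
    return int(np.clip(np.round(raw), 1, 20))


def generate_trial(
    subject_id: str,
    group: str,
    task_id: int,
    spec: CohortSpec,
    s: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> TrialRecord:
    """One full synthetic trial (all streams, questionnaire, manual scores)."""
    skill = GROUP_SKILL[group]
    duration = spec.duration_s
    rr = generate_rr(duration + 4.0, spec, s, rng, t0=t0 - 2.0)
    left, right, _obs = generate_hand_trajectories(duration, spec, s, skill, rng, t0=t0)
    # trajectories are rebuilt from the camera-frame observations so that
    # the rebasing stage is part of every downstream computation
    left = build_trajectory(_obs, "left")
    right = build_trajectory(_obs, "right")
    posture = generate_posture(duration, spec, s, rng, t0=t0)

    tlx = SurgTLX(
        mental=_tlx_answer(False, s, spec, rng, 12.0, 4.0),
        physical=_tlx_answer(True, s, spec, rng),
        temporal=_tlx_answer(False, s, spec, rng, 10.0, 4.0),
        complexity=_tlx_answer(False, s, spec, rng, 10.0, 4.0),
        situational_stress=_tlx_answer(False, s, spec, rng, 8.0, 4.0),
        distractions=_tlx_answer(True, s, spec, rng),
    )
    shrink = 1.0 - spec.manual_skill_shrink * skill
    manual = ManualScores(
        collisions_phantom=int(rng.poisson(spec.manual_base_rates["collisions_phantom"] * shrink)),
        collision_robot_arms=int(rng.poisson(spec.manual_base_rates["collision_robot_arms"] * shrink)),
        rings_placed=int(rng.binomial(10, min(spec.rings_placed_p_base + spec.rings_placed_p_slope * skill, 1.0))),
        ring_drops=int(rng.poisson(spec.manual_base_rates["ring_drops"] * shrink)),
        spike_color_missed=int(rng.poisson(spec.manual_base_rates["spike_color_missed"] * shrink)),
    )
    return TrialRecord(
        subject_id=subject_id,
        group=group,
        task_id=task_id,
        task_window=(t0, t0 + duration),
        rr=rr,
        left=left,
        right=right,
        posture=posture,
        tlx=tlx,
        manual=manual,
    )


def generate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[TrialRecord], pd.DataFrame, dict[str, int]]:
    """Generate the full synthetic cohort.

    Subjects are enumerated per group, four tasks each; trials beyond
    ``spec.n_trials`` (the last two of the nominal 60) are dropped,
    emulating incomplete recordings.  Returns ``(trials, ground_truth,
    planted_signs)`` where ``ground_truth`` holds one row per trial with
    the planted latent stress and skill.
    """
    spec = spec or CohortSpec()
    ss = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(ss)
    combos = [
        (f"{group[:3]}{i + 1:02d}", group, task + 1)
        for group in spec.groups
        for i in range(spec.n_per_group)
        for task in range(spec.tasks_per_subject)
    ]
    combos = combos[: spec.n_trials]
    child_seeds = ss.spawn(len(combos))
    trials = []
    truth_rows = []
    for j, ((subject, group, task), child) in enumerate(zip(combos, child_seeds)):
        rng = np.random.default_rng(child)
        s = float(master.uniform(0.0, 1.0))
        t0 = 1_700_000_000.0 + j * (spec.duration_s + 300.0)
        trial = generate_trial(subject, group, task, spec, s, rng, t0=t0)
        trials.append(trial)
        truth_rows.append(
            {
                "subject_id": subject,
                "group": group,
                "task_id": task,
                "stress_s": s,
                "skill": GROUP_SKILL[group],
                "t_start": t0,
                "t_end": t0 + spec.duration_s,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return trials, truth, dict(PLANTED_SIGNS)
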