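"""Synthetic multi-view pathological-gait simulator.

Generates labelled 33-landmark pose videos with the statistical structure the
classification pipeline assumes: subjects walk a 10 m straight path recorded
from a frontal and a sagittal camera, performing one of seven gait patterns —
normal (NOR) plus six impairments (circumduction CIR, Trendelenburg TRE,
antalgic ANT, crouch CRO, Parkinsonian PAR, vaulting VAU) — with asymmetric
impairments affecting the right side by default.

The walker is a sinusoidal joint-trajectory model: the pelvis advances one
stride per gait cycle, each foot alternates a ground-fixed stance phase with a
smooth swing arc, knees are placed by two-link inverse kinematics, and arms
swing antiphase to the ipsilateral leg. Impairments enter as parametric
modifiers of this base cycle, all scaled by an ``impairment_magnitude`` in
[0, 1]; at magnitude 0 every class collapses onto the same normal walker.

Per-class stride-length modifiers are calibrated so the mean number of gait
cycles per 10 m walk matches clinically observed per-class means
(ANT 7.6, CIR 5.8, CRO 7.2, NOR 4.6, PAR 10.4, TRE 6.4, VAU 5.4).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .containers import DIRECTIONS, GAIT_CLASSES, VIEWS, PoseSequence
from .skeleton import LANDMARK_INDEX as LM
from .skeleton import N_LANDMARKS

# calibrated so 10 m / (base stride * factor) reproduces per-class cycle means
_STRIDE_FACTORS = {
    "NOR": 1.0,
    "ANT": 4.6 / 7.6,
    "CIR": 4.6 / 5.8,
    "CRO": 4.6 / 7.2,
    "PAR": 4.6 / 10.4,
    "TRE": 4.6 / 6.4,
    "VAU": 4.6 / 5.4,
}
_CADENCE_FACTORS = {c: 1.0 for c in GAIT_CLASSES}
_CADENCE_FACTORS["PAR"] = 1.30  # shuffling: shorter, quicker strides


@dataclass(frozen=True)
class Anthropometry:
    """Subject body scale. Segment lengths are standard fractions of stature."""

    height: float = 1.70

    @property
    def leg_length(self) -> float:
        return 0.53 * self.height

    @property
    def thigh(self) -> float:
        return 0.245 * self.height

    @property
    def shank(self) -> float:
        return 0.246 * self.height

    @property
    def foot_length(self) -> float:
        return 0.152 * self.height

    @property
    def hip_width(self) -> float:
        return 0.191 * self.height

    @property
    def shoulder_width(self) -> float:
        return 0.259 * self.height

    @property
    def trunk_length(self) -> float:
        return 0.288 * self.height

    @property
    def upper_arm(self) -> float:
        return 0.186 * self.height

    @property
    def forearm(self) -> float:
        return 0.146 * self.height

    @property
    def hand(self) -> float:
        return 0.108 * self.height


@dataclass(frozen=True)
class GaitParams:
    """Per-class kinematic modifiers, expressed at full impairment magnitude.

    All additive amplitudes are metres; scales are dimensionless factors
    applied to the normal walker. Every modifier is multiplied by the
    impairment magnitude, so magnitude 0 reproduces normal gait exactly.
    """

    circumduction_amp: float = 0.18      # CIR: lateral swing arc of affected leg
    pelvic_drop_amp: float = 0.055       # TRE: contralateral pelvic drop in stance
    stance_asymmetry: float = 0.30       # ANT: fractional cut of affected stance time
    knee_hip_flexion_offset: float = 0.12  # CRO: pelvis lowering via constant flexion
    arm_swing_scale: float = 0.15        # PAR: arm swing reduced to this fraction
    trunk_pitch: float = 0.35            # PAR: forward trunk pitch, radians
    vault_rise: float = 0.07             # VAU: body lift on unaffected stance
    stride_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(_STRIDE_FACTORS))
    cadence_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(_CADENCE_FACTORS))


@dataclass(frozen=True)
class WalkerControls:
    """Resolved control curve parameters consumed by the kinematic walker."""

    stride_factor: float = 1.0
    cadence_factor: float = 1.0
    duty_left: float = 0.60        # stance fraction of the gait cycle
    duty_right: float = 0.60
    circumduction: float = 0.0     # m, lateral arc of affected swing foot
    pelvic_drop: float = 0.0       # m, contralateral hip drop during affected stance
    crouch_drop: float = 0.0       # m, constant pelvis lowering
    arm_swing: float = 1.0         # fraction of normal arm swing amplitude
    trunk_pitch: float = 0.0       # rad, forward lean
    vault_rise: float = 0.0        # m, body lift during affected swing
    affected_side: str = "right"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic recording protocol.

    Defaults emulate the recording protocol the pipeline targets: a 10 m
    outdoor walk filmed at 60 fps (so the 30 fps resampling path is
    exercised) by a sagittal camera 4 m from the walking line and a frontal
    camera on the path axis, with right-side-affected asymmetric gaits.
    ``stride_length`` and ``cadence_hz`` are the normal-gait subject ranges;
    per-class values derive from them through ``GaitParams`` stride/cadence
    scales interpolated by ``impairment_magnitude``.
    """

    n_subjects: int = 10
    walk_distance: float = 10.0
    raw_fps: float = 60.0
    stride_length: tuple[float, float] = (2.05, 2.30)   # m per cycle, NOR
    cadence_hz: tuple[float, float] = (0.85, 1.05)      # cycles/s, NOR
    impairment_magnitude: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in GAIT_CLASSES})
    gait_params: GaitParams = field(default_factory=GaitParams)
    affected_side: str = "right"
    keypoint_jitter_sd: float = 2.0      # px, on x/y channels
    depth_noise_sd: float = 6.0          # relative-depth units, z channel
    occlusion_prob: float = 0.03         # per landmark-frame
    camera_distance: float = 4.0         # m, both cameras
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.walk_distance <= 0:
            raise ValueError("walk_distance must be positive")
        for name, rng_ in (("stride_length", self.stride_length),
                           ("cadence_hz", self.cadence_hz)):
            lo, hi = rng_
            if not (0 < lo < hi):
                raise ValueError(f"{name} range must be positive and non-degenerate")
        if not 0 <= self.occlusion_prob < 1:
            raise ValueError("occlusion_prob must be in [0, 1)")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        for cls, m in self.impairment_magnitude.items():
            if cls not in GAIT_CLASSES:
                raise ValueError(f"unknown gait class {cls!r}")
            if not 0 <= m <= 1:
                raise ValueError("impairment magnitudes must lie in [0, 1]")

    def class_stride_range(self, label: str) -> tuple[float, float]:
        """Effective stride range for a class at its configured magnitude."""
        m = self.impairment_magnitude.get(label, 1.0)
        f = 1.0 + m * (self.gait_params.stride_scale[label] - 1.0)
        lo, hi = self.stride_length
        return lo * f, hi * f


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    anthropometry: Anthropometry
    stride_base: float     # NOR stride, m/cycle
    cadence_base: float    # NOR cadence, cycles/s


def apply_impairment(base: WalkerControls, label: str, params: GaitParams,
                     magnitude: float) -> WalkerControls:
    """Modify base-gait controls for one gait class at a given magnitude.

    Magnitude 0 (or label NOR) returns the input unchanged. Each class alters
    a distinct subset of controls; stride and cadence are interpolated between
    the normal value and the class target.
    """
    if label not in GAIT_CLASSES:
        raise ValueError(f"unknown gait class {label!r}")
    if not 0 <= magnitude <= 1:
        raise ValueError("magnitude must lie in [0, 1]")
    if label == "NOR" or magnitude == 0:
        return base

    m = magnitude
    stride_f = base.stride_factor * (1 + m * (params.stride_scale[label] - 1))
    cadence_f = base.cadence_factor * (1 + m * (params.cadence_scale[label] - 1))
    mods: dict[str, float] = {}
    if label == "CIR":
        mods["circumduction"] = m * params.circumduction_amp
    elif label == "TRE":
        mods["pelvic_drop"] = m * params.pelvic_drop_amp
    elif label == "ANT":
        duty = base.duty_right if base.affected_side == "right" else base.duty_left
        shortened = duty * (1 - m * params.stance_asymmetry)
        key = "duty_right" if base.affected_side == "right" else "duty_left"
        mods[key] = shortened
    elif label == "CRO":
        mods["crouch_drop"] = m * params.knee_hip_flexion_offset
    elif label == "PAR":
        mods["arm_swing"] = base.arm_swing * (1 + m * (params.arm_swing_scale - 1))
        mods["trunk_pitch"] = base.trunk_pitch + m * params.trunk_pitch
    elif label == "VAU":
        mods["vault_rise"] = m * params.vault_rise
    return replace(base, stride_factor=stride_f, cadence_factor=cadence_f, **mods)


def _swing_profile(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 swing advance with zero end velocity."""
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _leg_trajectory(phase: np.ndarray, offset: float, duty: float, stride: float,
                    side_z: float, swing_height: float,
                    circumduction: float, circ_sign: float):
    """World-frame heel trajectory and swing progress for one leg.

    ``phase`` is the global gait phase in cycles; the leg's own phase is
    shifted by ``offset``. During stance the heel stays at the contact point;
    during swing it advances one stride along x with a single vertical arc,
    so heel height has exactly one maximum per cycle.
    """
    leg_phase = phase - offset
    n = np.floor(leg_phase)
    psi = leg_phase - n
    in_swing = psi >= duty
    u = np.where(in_swing, (psi - duty) / (1 - duty), 0.0)

    contact_x = stride * (n + offset + duty / 2)
    x = contact_x + stride * _swing_profile(u)
    y = swing_height * np.sin(np.pi * u)
    z = np.full_like(x, side_z) + circ_sign * circumduction * np.sin(np.pi * u)
    return np.stack([x, y, z], axis=-1), u, in_swing


def _two_link_ik(hip: np.ndarray, ankle: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Knee position between hip and ankle (two-link IK, knee anterior).

    Solved in the vertical plane spanned by the hip-to-ankle axis and the
    forward direction, so thigh and shank lengths are exact in 3D.
    Over-extension beyond l1 + l2 is clipped toward a straight leg.
    """
    d = ankle - hip
    dist_true = np.linalg.norm(d, axis=-1)
    dist = np.clip(dist_true, abs(l1 - l2) + 1e-9, l1 + l2 - 1e-9)
    u = d / dist_true[..., None]
    a = (l1 ** 2 - l2 ** 2 + dist ** 2) / (2 * dist)
    h = np.sqrt(np.maximum(l1 ** 2 - a ** 2, 0.0))
    forward = np.zeros_like(u)
    forward[..., 0] = 1.0
    perp = forward - (u[..., 0])[..., None] * u   # forward, orthogonal to u
    norm = np.linalg.norm(perp, axis=-1, keepdims=True)
    perp = perp / np.where(norm > 1e-12, norm, 1.0)
    return hip + a[..., None] * u + h[..., None] * perp


def walker_poses(phase: np.ndarray, anthro: Anthropometry, stride: float,
                 controls: WalkerControls = WalkerControls(),
                 reach_stride: float | None = None) -> np.ndarray:
    """Body-frame 3D poses of the parametric walker at the given gait phases.

    Returns a (T, 33, 3) array in metres with axes (x forward, y up,
    z to the walker's left); the pelvis advances ``stride`` metres per cycle
    along x. Continuous and 1-periodic in phase up to that forward advance.

    ``reach_stride`` is the stride the leg segments are sized for (the
    subject's normal stride); thigh and shank are lengthened, in fixed
    proportion, just enough that the leg spans the step at heel contact, so
    bone lengths stay constant within a subject across all gait classes.
    """
    phase = np.atleast_1d(np.asarray(phase, dtype=float))
    T = phase.shape[0]
    a = anthro
    c = controls
    stride = stride * c.stride_factor
    if reach_stride is None:
        reach_stride = stride
    right_affected = c.affected_side == "right"

    pose = np.zeros((T, N_LANDMARKS, 3))

    swing_height = 0.07
    bob = 0.018
    sway = 0.025
    standing_hip = a.leg_length * 0.98  # slight habitual knee bend

    ankle_up = 0.050 * a.height
    ankle_fwd = 0.020 * a.height
    # leg reach needed in late swing, where the smooth swing profile leads
    # the pelvis by up to 0.34 stride
    required = np.hypot(standing_hip + bob - ankle_up,
                        reach_stride * 0.34 + ankle_fwd)
    leg_scale = max(1.0, 1.02 * required / (a.thigh + a.shank))
    thigh, shank = a.thigh * leg_scale, a.shank * leg_scale

    # feet ---------------------------------------------------------------
    heel_l, u_l, swing_l = _leg_trajectory(
        phase, 0.5, c.duty_left, stride, +a.hip_width / 2, swing_height,
        c.circumduction if not right_affected else 0.0, +1.0)
    heel_r, u_r, swing_r = _leg_trajectory(
        phase, 0.0, c.duty_right, stride, -a.hip_width / 2, swing_height,
        c.circumduction if right_affected else 0.0, -1.0)

    # vaulting: the body (and the unaffected stance foot, via plantarflexion)
    # rises while the affected leg swings
    u_aff = u_r if right_affected else u_l
    lift = c.vault_rise * np.sin(np.pi * u_aff)
    if right_affected:
        heel_l[:, 1] += lift
    else:
        heel_r[:, 1] += lift

    # pelvis -------------------------------------------------------------
    pelvis = np.zeros((T, 3))
    pelvis[:, 0] = stride * phase
    pelvis[:, 1] = (standing_hip - c.crouch_drop + bob * np.cos(4 * np.pi * phase)
                    + lift)
    pelvis[:, 2] = sway * np.sin(2 * np.pi * phase)

    # Trendelenburg: hip contralateral to the affected stance leg drops
    psi_aff = np.mod(phase - (0.0 if right_affected else 0.5), 1.0)
    duty_aff = c.duty_right if right_affected else c.duty_left
    in_stance_aff = psi_aff < duty_aff
    drop = np.where(in_stance_aff,
                    c.pelvic_drop * np.sin(np.pi * psi_aff / duty_aff), 0.0)

    hip_l = pelvis + np.array([0.0, 0.0, a.hip_width / 2])
    hip_r = pelvis + np.array([0.0, 0.0, -a.hip_width / 2])
    if right_affected:
        hip_l[:, 1] -= drop
    else:
        hip_r[:, 1] -= drop
    pose[:, LM["left_hip"]] = hip_l
    pose[:, LM["right_hip"]] = hip_r

    # legs ---------------------------------------------------------------
    for side, heel, hip in (("left", heel_l, hip_l), ("right", heel_r, hip_r)):
        ankle = heel + np.array([ankle_fwd, ankle_up, 0.0])
        toe = heel + np.array([a.foot_length, 0.012, 0.0])
        knee = _two_link_ik(hip, ankle, thigh, shank)
        pose[:, LM[f"{side}_heel"]] = heel
        pose[:, LM[f"{side}_ankle"]] = ankle
        pose[:, LM[f"{side}_foot_index"]] = toe
        pose[:, LM[f"{side}_knee"]] = knee

    # trunk, head --------------------------------------------------------
    pitch = c.trunk_pitch
    trunk_dir = np.array([np.sin(pitch), np.cos(pitch), 0.0])
    shoulder_c = pelvis + a.trunk_length * trunk_dir
    neck = shoulder_c + 0.065 * a.height * trunk_dir
    h = a.height
    face_offsets = {
        "nose": (0.055 * h, 0.020 * h, 0.0),
        "left_eye_inner": (0.050 * h, 0.033 * h, 0.012 * h),
        "left_eye": (0.047 * h, 0.034 * h, 0.020 * h),
        "left_eye_outer": (0.043 * h, 0.034 * h, 0.028 * h),
        "right_eye_inner": (0.050 * h, 0.033 * h, -0.012 * h),
        "right_eye": (0.047 * h, 0.034 * h, -0.020 * h),
        "right_eye_outer": (0.043 * h, 0.034 * h, -0.028 * h),
        "left_ear": (0.010 * h, 0.028 * h, 0.040 * h),
        "right_ear": (0.010 * h, 0.028 * h, -0.040 * h),
        "mouth_left": (0.048 * h, 0.005 * h, 0.013 * h),
        "mouth_right": (0.048 * h, 0.005 * h, -0.013 * h),
    }
    for name, off in face_offsets.items():
        pose[:, LM[name]] = neck + np.asarray(off)

    # arms: antiphase with the ipsilateral leg ---------------------------
    arm_amp = 0.35 * c.arm_swing
    elbow_flex = 0.35
    for side, sign, arm_offset in (("left", +1.0, 0.0), ("right", -1.0, 0.5)):
        shoulder = shoulder_c + np.array([0.0, 0.0, sign * a.shoulder_width / 2])
        alpha = arm_amp * np.cos(2 * np.pi * (phase + arm_offset)) + pitch
        ua_dir = np.stack([np.sin(alpha), -np.cos(alpha),
                           np.zeros_like(alpha)], axis=-1)
        beta = alpha + elbow_flex
        fa_dir = np.stack([np.sin(beta), -np.cos(beta),
                           np.zeros_like(beta)], axis=-1)
        elbow = shoulder + a.upper_arm * ua_dir
        wrist = elbow + a.forearm * fa_dir
        pose[:, LM[f"{side}_shoulder"]] = shoulder
        pose[:, LM[f"{side}_elbow"]] = elbow
        pose[:, LM[f"{side}_wrist"]] = wrist
        pose[:, LM[f"{side}_pinky"]] = wrist + a.hand * fa_dir \
            + np.array([0.0, 0.0, sign * 0.015])
        pose[:, LM[f"{side}_index"]] = wrist + a.hand * fa_dir \
            + np.array([0.0, 0.0, -sign * 0.010])
        pose[:, LM[f"{side}_thumb"]] = wrist + 0.5 * a.hand * fa_dir \
            + np.array([0.0, 0.0, -sign * 0.020])

    return pose


def base_gait_cycle(phase: float | np.ndarray,
                    anthropometry: Anthropometry = Anthropometry(),
                    stride: float | None = None) -> np.ndarray:
    """Normal-gait pose(s) at the given phase(s) of the cycle.

    ``stride`` defaults to the stature-scaled normal stride. For a scalar
    phase a (33, 3) body-frame pose is returned; for an array of phases the
    leading axis is time.
    """
    if stride is None:
        stride = 1.28 * anthropometry.height
    scalar = np.isscalar(phase)
    out = walker_poses(np.atleast_1d(phase), anthropometry, stride)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# cameras
# ---------------------------------------------------------------------------

_SAGITTAL_F = 400.0   # focal length, px
_FRONTAL_F = 900.0
_IMG_CX, _IMG_CY = 960.0, 540.0
_CAM_HEIGHT = 1.2


def _project(world: np.ndarray, view: str, camera_distance: float,
             walk_distance: float) -> np.ndarray:
    """Pinhole projection of world poses to (x px, y px, z relative depth).

    Sagittal camera: perpendicular to the path at its midpoint, so the
    subject's distance — and hence pixel scale — is near-constant. Frontal
    camera: on the path axis behind the start, so the subject's distance
    changes by the walked length and the projected size changes with it.
    The z channel is the landmark's camera depth relative to the hip centre,
    scaled like the pixel channels.
    """
    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    if view == "sagittal":
        depth = camera_distance - z          # camera on the walker's left
        u = _SAGITTAL_F * (x - walk_distance / 2) / depth + _IMG_CX
        f = _SAGITTAL_F
    elif view == "frontal":
        depth = camera_distance + x          # camera behind the start line
        u = _FRONTAL_F * (-z) / depth + _IMG_CX
        f = _FRONTAL_F
    else:
        raise ValueError(f"unknown view {view!r}")
    v = _IMG_CY - f * (y - _CAM_HEIGHT) / depth

    hip_depth = 0.5 * (depth[:, LM["left_hip"]] + depth[:, LM["right_hip"]])
    z_rel = f * (depth - hip_depth[:, None]) / hip_depth[:, None]
    return np.stack([u, v, z_rel], axis=-1)


def render_sequence(subject: SubjectProfile, label: str, view: str,
                    direction: str, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> PoseSequence:
    """Simulate one video: walk the path, project to the camera, add noise.

    The walker covers ``config.walk_distance`` at the subject's class-specific
    stride and cadence. Keypoint jitter is added to the pixel channels, a
    larger noise to the relative-depth channel, and each landmark-frame is
    occluded (set missing) independently with ``config.occlusion_prob``.
    """
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if config.walk_distance <= 0:
        raise ValueError("walk distance must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    magnitude = config.impairment_magnitude.get(label, 1.0)
    controls = apply_impairment(
        WalkerControls(affected_side=config.affected_side), label,
        config.gait_params, magnitude)

    stride = subject.stride_base * controls.stride_factor
    cadence = subject.cadence_base * controls.cadence_factor
    n_cycles = config.walk_distance / stride
    duration = n_cycles / cadence
    n_frames = max(int(round(duration * config.raw_fps)), 2)
    t = np.arange(n_frames) / config.raw_fps
    phase = cadence * t

    world = walker_poses(phase, subject.anthropometry, stride,
                         replace(controls, stride_factor=1.0),
                         reach_stride=subject.stride_base)
    if direction == "left":
        # walk the path the other way: rotate 180 deg about the path midpoint
        world = world.copy()
        world[..., 0] = config.walk_distance - world[..., 0]
        world[..., 2] = -world[..., 2]

    values = _project(world, view, config.camera_distance, config.walk_distance)
    values[..., :2] += rng.normal(0.0, config.keypoint_jitter_sd,
                                  size=values.shape[:2] + (2,))
    values[..., 2] += rng.normal(0.0, config.depth_noise_sd,
                                 size=values.shape[:2])

    missing = rng.random(values.shape[:2]) < config.occlusion_prob
    values[missing] = np.nan

    video_id = f"{subject.subject_id}_{label}_{view}_{direction}"
    return PoseSequence(values=values, fps=config.raw_fps, video_id=video_id,
                        subject_id=subject.subject_id, view=view,
                        direction=direction, label=label, missing=missing)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class GaitDataset:
    """A simulated study: manifest plus one pose sequence per video."""

    manifest: pd.DataFrame
    sequences: dict[str, PoseSequence]


def make_subjects(config: SimulationConfig) -> list[SubjectProfile]:
    """Draw per-subject anthropometry and normal-gait parameters (seeded)."""
    rng = np.random.default_rng([config.seed, 0xA11CE])
    subjects = []
    for i in range(config.n_subjects):
        height = float(rng.uniform(1.55, 1.90))
        u = float(rng.random())
        s_lo, s_hi = config.stride_length
        c_lo, c_hi = config.cadence_hz
        subjects.append(SubjectProfile(
            subject_id=f"S{i:02d}",
            anthropometry=Anthropometry(height=height),
            stride_base=s_lo + u * (s_hi - s_lo),
            cadence_base=c_lo + float(rng.random()) * (c_hi - c_lo),
        ))
    return subjects


def simulate_dataset(config: SimulationConfig) -> GaitDataset:
    """Simulate the full study: every subject x 7 classes x 2 views x 2 directions.

    Deterministic in ``config.seed``: each video gets its own child generator
    keyed by (seed, subject, class, view, direction).
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects for a subject-wise analysis")
    subjects = make_subjects(config)
    rows = []
    sequences: dict[str, PoseSequence] = {}
    for si, subject in enumerate(subjects):
        for ci, label in enumerate(GAIT_CLASSES):
            for vi, view in enumerate(VIEWS):
                for di, direction in enumerate(DIRECTIONS):
                    rng = np.random.default_rng([config.seed, si, ci, vi, di])
                    seq = render_sequence(subject, label, view, direction,
                                          config, rng)
                    sequences[seq.video_id] = seq
                    rows.append({
                        "video_id": seq.video_id,
                        "subject_id": subject.subject_id,
                        "view": view,
                        "direction": direction,
                        "label": label,
                        "fps": config.raw_fps,
                        "n_frames": seq.n_frames,
                    })
    manifest = pd.DataFrame(rows)
    return GaitDataset(manifest=manifest, sequences=sequences)


def count_gait_cycles(seq: PoseSequence, side: str = "right") -> float:
    """Count gait cycles from peaks of one heel's vertical pixel channel.

    Swing raises the heel once per cycle; in pixel coordinates (y grows
    downward) those are minima, so peaks are found on the negated channel
    after removing its rolling median. Used only to calibrate the simulator.
    """
    if seq.duration_s < 2.0:
        raise ValueError("need at least 2 s of frames to count cycles")
    def _fill(v: np.ndarray) -> np.ndarray:
        return pd.Series(v).interpolate(limit_direction="both").to_numpy()

    y = _fill(seq.values[:, LM[f"{side}_heel"], 1])
    if np.ptp(y) < 1e-9:
        raise ValueError("no cycles detectable: heel channel is constant")
    # divide out apparent body size so perspective (frontal view) does not
    # swamp the swing bumps
    ankle_mid = 0.5 * (_fill(seq.values[:, LM["left_ankle"], 1])
                       + _fill(seq.values[:, LM["right_ankle"], 1]))
    extent = np.abs(_fill(seq.values[:, LM["nose"], 1]) - ankle_mid)
    scale = pd.Series(extent).rolling(int(seq.fps), center=True,
                                      min_periods=1).median().to_numpy()
    if np.all(scale > 0):
        y = y / scale
    # suppress keypoint jitter, then remove the slow trend over ~1 s
    smooth = (pd.Series(y).rolling(max(int(0.15 * seq.fps), 1), center=True,
                                   min_periods=1).mean().to_numpy())
    trend = pd.Series(smooth).rolling(int(seq.fps), center=True,
                                      min_periods=1).median().to_numpy()
    signal = -(smooth - trend)
    cut = int(0.25 * seq.fps)  # camera-entry/exit frames are unreliable
    if len(signal) > 2 * cut + 2:
        signal = signal[cut:-cut]
    prominence = 0.5 * (np.quantile(signal, 0.95) - np.quantile(signal, 0.05))
    if prominence <= 0:
        raise ValueError("no cycles detectable: heel channel is constant")
    peaks, _ = find_peaks(signal, prominence=prominence,
                          distance=max(int(0.45 * seq.fps), 1))
    if len(peaks) == 0:
        raise ValueError("no cycles detectable")
    return float(len(peaks))


def dataset_fingerprint(dataset: GaitDataset) -> str:
    """SHA-256 over all sequence bytes and the manifest; determinism checks."""
    h = hashlib.sha256()
    for vid in sorted(dataset.sequences):
        h.update(vid.encode())
        h.update(np.ascontiguousarray(dataset.sequences[vid].values).tobytes())
    h.update(dataset.manifest.to_csv(index=False).encode())
    return h.hexdigest()
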