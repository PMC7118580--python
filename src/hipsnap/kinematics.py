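"""Hip circumduction kinematics.

The hip is a spherical joint: every pose is a rotation about the femoral
head center. Clinical semantics use three angles - abduction, flexion,
external rotation - composed intrinsically as

    R = R_abduction(anterior axis) . R_flexion(mediolateral axis)
        . R_external_rotation(longitudinal axis)

in the instance frame (+x anterior, +y medial, +z superior, right hip).
With flexion as the middle angle the decomposition is unique and exact for
|flexion| < 90 deg, which keeps the provocative apex (90 deg abduction,
60 deg flexion, 30 deg external rotation) gimbal-safe and lets the apex
frame decompose back to its nominal angles exactly.

Sign conventions (right hip): positive abduction moves the thigh laterally,
positive flexion anteriorly, positive external rotation turns the anterior
femur laterally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .anatomy import FEMUR_LABELS, AnatomyInstance, LandmarkSet


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class JointPose:
    rotation: np.ndarray  # 3x3, det = +1
    clinical: tuple[float, float, float]  # (abduction, flexion, external_rotation) deg
    time: float  # s


@dataclass
class MotionSequence:
    frames: list[JointPose]
    angular_speed: float  # deg/s
    apex_index: int

    def __len__(self):
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def duration(self) -> float:
        return float(self.frames[-1].time)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "frame,time_s,abduction_deg,flexion_deg,external_rotation_deg,"
                + ",".join(f"r{i}{j}" for i in range(3) for j in range(3))
                + "\n"
            )
            for k, f in enumerate(self.frames):
                rot = ",".join(f"{v:.12g}" for v in f.rotation.ravel())
                a, fl, e = f.clinical
                fh.write(f"{k},{f.time:.9f},{a:.9f},{fl:.9f},{e:.9f},{rot}\n")


def compose_rotation(abduction: float, flexion: float, external_rotation: float) -> np.ndarray:
    """Rotation matrix from clinical angles (degrees)."""
    return Rotation.from_euler(
        "XYZ", [-abduction, -flexion, -external_rotation], degrees=True
    ).as_matrix()


def decompose_rotation(rotation: np.ndarray) -> tuple[float, float, float]:
    """Clinical angles (degrees) from a rotation matrix; exact round trip.

    Raises for non-orthonormal input; unique for |flexion| < 90 deg.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation matrix")
    ax, ay, az = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
    return (-ax, -ay, -az)


def build_circumduction_sequence(
    peak_abduction: float = 90.0,
    peak_flexion: float = 60.0,
    peak_rotation: float = 30.0,
    speed: float = 25.0,
    n_steps: int = 120,
) -> MotionSequence:
    """Provocative circumduction: neutral -> apex -> neutral.

    The three clinical angles ramp linearly and simultaneously from zero to
    their peaks over the first half of the sequence and back over the second
    half; frame times follow from the per-step geodesic rotation angle at
    the given constant angular speed. ``n_steps`` is the total frame count
    (first and last frame neutral, apex at index n_steps // 2).
    """
    if n_steps < 2 or n_steps % 2 != 0:
        raise ConfigurationError("n_steps must be an even integer >= 2")
    if speed <= 0:
        raise ConfigurationError("speed must be > 0")
    m = n_steps // 2
    peaks = np.array([peak_abduction, peak_flexion, peak_rotation], dtype=float)

    frames: list[JointPose] = []
    prev_R = None
    t = 0.0
    for k in range(n_steps):
        frac = k / m if k <= m else (n_steps - 1 - k) / (n_steps - 1 - m)
        clin = tuple(float(v) for v in frac * peaks)
        R = compose_rotation(*clin)
        if prev_R is not None:
            step_deg = geodesic_angle(prev_R, R)
            t += step_deg / speed
        frames.append(JointPose(rotation=R, clinical=clin, time=t))
        prev_R = R
    return MotionSequence(frames=frames, angular_speed=speed, apex_index=m)


def geodesic_angle(R0: np.ndarray, R1: np.ndarray) -> float:
    """Rotation angle (degrees) of the relative rotation R0 -> R1."""
    rel = Rotation.from_matrix(R0.T @ np.asarray(R1))
    return float(np.degrees(np.linalg.norm(rel.as_rotvec())))


def apply_pose(anatomy: AnatomyInstance, pose: JointPose):
    """Rigidly rotate the femur about the head center; the pelvis is fixed.

    Returns (posed femur landmarks, posed femur components, posed insertion).
    """
    R = pose.rotation
    c = anatomy.head_center
    mask = np.array([l in FEMUR_LABELS for l in anatomy.landmarks.labels])
    pts = anatomy.landmarks.points.copy()
    pts[mask] = (pts[mask] - c) @ R.T + c
    labels = [l for l, m in zip(anatomy.landmarks.labels, mask) if m]
    femur_lms = LandmarkSet(points=pts[mask], labels=labels)
    components = {k: cap.transformed(R, c) for k, cap in anatomy.femur_components.items()}
    insertion = c + R @ (anatomy.psoas_insertion - c)
    return femur_lms, components, insertion
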