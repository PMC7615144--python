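"""Rigid head-motion representation and motion-score metrics.

Conventions
-----------
All poses live in one scanner frame: ``x`` runs right-to-left (left
positive), ``y`` down-to-up (up positive), ``z`` foot-to-head (head
positive).  Rotations are stored in degrees, translations in millimetres.
A pose materialises as the 3x3 matrix ``R = Rz(theta_z) @ Ry(theta_y) @
Rx(theta_x)`` (rotations about the fixed scanner axes, applied x-first).
This order is chosen deliberately: the closed-form combined-angle
expression used by the motion score is *exact* for it (the sign of its
sin-product term singles out this composition), so the formula and the
matrix-trace angle agree to rounding error.  A point ``p`` in the
reference head position appears at ``R @ p + t`` after the motion.

The motion score of a frame-to-frame pose increment is the largest
displacement of any point on a sphere of 64 mm radius under the net
rotation, plus the Euclidean norm of the translation.  It is the standard
single-number summary for rigid head motion in motion-correction work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "MotionTrace",
    "MotionScoreParams",
    "combined_rotation_angle",
    "rotation_angle_from_matrix",
    "sphere_displacement",
    "motion_score_frame",
    "mean_motion_score",
    "expected_deflection",
    "lowpass_filter_trace",
    "rebase_trace",
    "identity_transform",
]

TRACE_COLUMNS = [
    "time_s",
    "theta_x_deg",
    "theta_y_deg",
    "theta_z_deg",
    "t_x_mm",
    "t_y_mm",
    "t_z_mm",
]


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid-body pose: rotations in degrees, translations in mm."""

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0
    t_x: float = 0.0
    t_y: float = 0.0
    t_z: float = 0.0

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.theta_x, self.theta_y, self.theta_z], float)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.t_x, self.t_y, self.t_z], float)

    @property
    def params(self) -> np.ndarray:
        """The six parameters as ``[theta_x, theta_y, theta_z, t_x, t_y, t_z]``."""
        return np.concatenate([self.angles, self.translation])

    def rotation_matrix(self) -> np.ndarray:
        """3x3 rotation ``Rz @ Ry @ Rx`` (orthonormal, det +1)."""
        return Rotation.from_euler("xyz", self.angles, degrees=True).as_matrix()

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        p = np.asarray(params, float)
        return cls(*p.tolist())

    @classmethod
    def from_matrix(cls, rot: np.ndarray, trans: np.ndarray) -> "RigidTransform":
        ang = Rotation.from_matrix(rot).as_euler("xyz", degrees=True)
        return cls(*ang.tolist(), *np.asarray(trans, float).tolist())

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform ``(..., 3)`` points: ``R @ p + t``."""
        pts = np.asarray(points, float)
        return pts @ self.rotation_matrix().T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self o other``: apply ``other`` first, then ``self``."""
        ra, rb = self.rotation_matrix(), other.rotation_matrix()
        return RigidTransform.from_matrix(
            ra @ rb, ra @ other.translation + self.translation
        )

    def inverse(self) -> "RigidTransform":
        r = self.rotation_matrix()
        return RigidTransform.from_matrix(r.T, -r.T @ self.translation)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.params) <= tol))


def identity_transform() -> RigidTransform:
    return RigidTransform()


@dataclass(frozen=True)
class MotionScoreParams:
    """Radius (mm) of the sphere whose worst-case point displacement enters
    the motion score; 64 mm approximates the head."""

    sphere_radius: float = 64.0

    def __post_init__(self):
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")


@dataclass
class MotionTrace:
    """Time-stamped pose sequence with a declared zero-motion reference time.

    ``poses`` is an ``(N, 6)`` array of ``[theta_x, theta_y, theta_z, t_x,
    t_y, t_z]`` rows; ``times`` are seconds from scan start, strictly
    increasing.  ``sampling_label`` tags the provenance of the trace
    (prescribed / navigator / tracker / tracker_filtered).
    """

    times: np.ndarray
    poses: np.ndarray
    reference_time: float = 0.0
    sampling_label: str = "prescribed"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.poses = np.asarray(self.poses, float)
        if self.poses.ndim != 2 or self.poses.shape[1] != 6:
            raise ValueError("poses must be (N, 6)")
        if len(self.times) != len(self.poses):
            raise ValueError("times and poses length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def pose(self, i: int) -> RigidTransform:
        return RigidTransform.from_params(self.poses[i])

    def nearest_index(self, t: float) -> int:
        """Index of the sample nearest ``t``; ties break to the earlier sample."""
        d = np.abs(self.times - t)
        return int(np.argmin(d))  # argmin returns first minimum => earlier sample

    def sample_at(self, t) -> np.ndarray:
        """Linear interpolation of the six parameters at times ``t``
        (clamped at the trace ends); returns ``(len(t), 6)``."""
        t = np.atleast_1d(np.asarray(t, float))
        out = np.empty((len(t), 6))
        for j in range(6):
            out[:, j] = np.interp(t, self.times, self.poses[:, j])
        return out

    def pose_at(self, t: float) -> RigidTransform:
        return RigidTransform.from_params(self.sample_at(t)[0])

    def copy(self, **kw) -> "MotionTrace":
        base = dict(
            times=self.times.copy(),
            poses=self.poses.copy(),
            reference_time=self.reference_time,
            sampling_label=self.sampling_label,
        )
        base.update(kw)
        return MotionTrace(**base)

    # ---- I/O: CSV + JSON sidecar -------------------------------------
    def to_csv(self, path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            np.column_stack([self.times, self.poses]), columns=TRACE_COLUMNS
        )
        df.to_csv(path, index=False, float_format="%.9g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "reference_time": self.reference_time,
                    "sampling_label": self.sampling_label,
                },
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, path) -> "MotionTrace":
        path = Path(path)
        df = pd.read_csv(path)
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace CSV missing columns: {missing}")
        meta = {"reference_time": 0.0, "sampling_label": "prescribed"}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta.update(json.loads(sidecar.read_text()))
        return cls(
            times=df["time_s"].to_numpy(),
            poses=df[TRACE_COLUMNS[1:]].to_numpy(),
            reference_time=float(meta["reference_time"]),
            sampling_label=str(meta["sampling_label"]),
        )


# ---------------------------------------------------------------------------
# Motion-score metrics
# ---------------------------------------------------------------------------

def combined_rotation_angle(theta_x: float, theta_y: float, theta_z: float) -> float:
    """Combined rotation angle |theta| (degrees) from three axis rotations.

    Evaluates ``|theta| = arccos(0.5 * (-1 + cos tx cos ty + cos tx cos tz
    + cos ty cos tz + sin tx sin ty sin tz))``, the closed form used with
    the motion score.  For the package's pose convention
    (``R = Rz @ Ry @ Rx``) this equals the matrix-trace rotation angle
    exactly — ``arccos((trace(R) - 1)/2)`` — to rounding error; see
    :func:`rotation_angle_from_matrix` for the matrix route.  The arccos
    argument is clamped to [-1, 1].
    """
    tx, ty, tz = np.deg2rad([theta_x, theta_y, theta_z])
    arg = 0.5 * (
        -1.0
        + np.cos(tx) * np.cos(ty)
        + np.cos(tx) * np.cos(tz)
        + np.cos(ty) * np.cos(tz)
        + np.sin(tx) * np.sin(ty) * np.sin(tz)
    )
    return float(np.rad2deg(np.arccos(np.clip(arg, -1.0, 1.0))))


def rotation_angle_from_matrix(transform: RigidTransform) -> float:
    """Exact rotation angle (degrees) via ``arccos((trace(R) - 1)/2)``."""
    r = transform.rotation_matrix()
    arg = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.rad2deg(np.arccos(arg)))


def sphere_displacement(theta_deg: float, params: MotionScoreParams | None = None) -> float:
    """Largest displacement (mm) of any point on the scoring sphere under a
    rotation by ``theta_deg``: ``r * sqrt((1-cos)^2 + sin^2) = 2 r sin(theta/2)``."""
    params = params or MotionScoreParams()
    th = np.deg2rad(theta_deg)
    return float(
        params.sphere_radius * np.sqrt((1.0 - np.cos(th)) ** 2 + np.sin(th) ** 2)
    )


def motion_score_frame(delta: RigidTransform, params: MotionScoreParams | None = None) -> float:
    """Motion score (mm) of one frame-to-frame pose increment:
    worst-case sphere displacement under the net rotation plus the
    Euclidean translation norm."""
    params = params or MotionScoreParams()
    theta = combined_rotation_angle(delta.theta_x, delta.theta_y, delta.theta_z)
    return sphere_displacement(theta, params) + float(
        np.linalg.norm(delta.translation)
    )


def mean_motion_score(trace: MotionTrace, params: MotionScoreParams | None = None) -> float:
    """Mean frame-to-frame motion score (mm) over consecutive sample pairs.

    Uses the differential pose ``pose_i^-1 o pose_{i+1}``, so the value is
    invariant to rebasing the whole trace.
    """
    if len(trace) < 2:
        raise ValueError("mean_motion_score needs at least 2 samples")
    params = params or MotionScoreParams()
    scores = []
    prev = trace.pose(0)
    for i in range(1, len(trace)):
        cur = trace.pose(i)
        delta = prev.inverse().compose(cur)
        scores.append(motion_score_frame(delta, params))
        prev = cur
    return float(np.mean(scores))


def expected_deflection(dot_displacement_cm: float, eye_screen_distance_cm: float = 76.0) -> float:
    """Predicted head rotation (degrees) for a fixation dot displaced by
    ``dot_displacement_cm`` on a screen viewed at ``eye_screen_distance_cm``.

    Uses the small-angle ratio d/L in radians converted to degrees (the
    convention that reproduces the printed protocol values at 76 cm:
    2.5 cm -> 1.9, 3.5 -> 2.6, 5 -> 3.8, 7.5 -> 5.7).
    """
    if eye_screen_distance_cm <= 0:
        raise ValueError("eye-screen distance must be positive")
    if dot_displacement_cm < 0:
        raise ValueError("dot displacement must be non-negative")
    return float(np.rad2deg(dot_displacement_cm / eye_screen_distance_cm))


# ---------------------------------------------------------------------------
# Trace processing
# ---------------------------------------------------------------------------

def lowpass_filter_trace(
    trace: MotionTrace,
    cutoff_hz: float = 1.0,
    sample_rate_hz: float | None = None,
    order: int = 4,
) -> MotionTrace:
    """Zero-phase low-pass filtering of each of the six parameter series.

    A Butterworth filter of the given order is applied forward and backward
    (``filtfilt``), doubling the effective order and cancelling phase
    delay.  The trace must be uniformly sampled.
    """
    if len(trace) < 2:
        raise ValueError("cannot filter a trace with fewer than 2 samples")
    dt = np.diff(trace.times)
    if np.max(np.abs(dt - dt[0])) > 1e-6 * max(dt[0], 1e-12):
        raise ValueError("trace must be uniformly sampled; resample first")
    fs = sample_rate_hz if sample_rate_hz is not None else 1.0 / dt[0]
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie in (0, sample_rate/2)")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    filtered = np.empty_like(trace.poses)
    for j in range(6):
        filtered[:, j] = filtfilt(b, a, trace.poses[:, j])
    label = trace.sampling_label
    if label == "tracker":
        label = "tracker_filtered"
    return trace.copy(poses=filtered, sampling_label=label)


def rebase_trace(trace: MotionTrace, reference_time: float) -> MotionTrace:
    """Re-express the trace relative to the pose at ``reference_time``.

    Every pose is left-composed with the inverse of the pose at the sample
    nearest ``reference_time`` (ties toward the earlier sample), so the
    reference sample becomes the identity.  Frame-to-frame differentials,
    and hence the mean motion score, are unchanged.
    """
    idx = trace.nearest_index(reference_time)
    ref_inv = trace.pose(idx).inverse()
    out = np.empty_like(trace.poses)
    for i in range(len(trace)):
        out[i] = ref_inv.compose(trace.pose(i)).params
    return trace.copy(poses=out, reference_time=reference_time)
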