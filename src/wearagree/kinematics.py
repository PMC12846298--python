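"""Shoulder kinematics: orientation harmonization and range-of-motion extraction.

The wearable reports segment orientation as Euler angles from its on-board
fusion; the optical reference reports per-frame segment→laboratory rotation
matrices. The two are made comparable by

1. converting the Euler stream to rotation matrices (one fixed convention,
   intrinsic yaw–pitch–roll z-y'-x'', applied identically to both systems so
   the choice cancels in the comparison),
2. estimating the fixed mounting rotation between the sensor frame and the
   optically defined segment frame (orthogonal Procrustes on SO(3)),
3. referencing both trajectories to the mean orientation over an initial
   0.3 s window, so analysis concerns relative angular variation,
4. re-expressing as Euler angles, unwrapping ±180° discontinuities,
   zero-phase 4th-order Butterworth low-pass smoothing (default 6 Hz),
5. resampling each task cycle to 1700 points and taking max − min per axis
   as the per-cycle range of motion (ROM), averaged over the five cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .errors import (
    AlignmentError,
    ConfigurationError,
    ProcessingError,
    RangeError,
    SchemaError,
)
from .recordings import RotationTrajectory, TimeSeriesRecording
from .segmentation import CycleAnnotation, split_cycles

__all__ = [
    "KinematicsConfig",
    "ROMRecord",
    "euler_to_matrix",
    "matrix_to_euler",
    "euler_stream_to_trajectory",
    "estimate_rigid_alignment",
    "mean_rotation",
    "reference_to_initial",
    "unwrap_degrees",
    "butterworth_lowpass",
    "resample_linear",
    "rom",
    "geodesic_angle_deg",
    "run_kinematics_pipeline",
]

AXES = ("axis1", "axis2", "axis3")
GIMBAL_PITCH_DEG = 89.9

#: Euler channel feeding each reported rotation axis. Axis 1 is glossed
#: anatomically as abduction/adduction, axis 2 flexion/extension, axis 3
#: lateral/medial rotation; the pipeline itself reports by axis index.
DEFAULT_AXIS_CHANNELS = {"axis1": "roll", "axis2": "pitch", "axis3": "yaw"}


@dataclass
class KinematicsConfig:
    cutoff_hz: float = 6.0
    filter_order: int = 4
    ref_window_s: float = 0.3
    target_len: int = 1700
    axis_channels: dict = field(default_factory=lambda: dict(DEFAULT_AXIS_CHANNELS))


@dataclass
class ROMRecord:
    """Per-cycle and mean ROM for one participant/side/axis, both systems."""

    participant: str
    side: str
    axis: str
    per_cycle_device: np.ndarray
    per_cycle_reference: np.ndarray
    rom_device_deg: float
    rom_reference_deg: float


def euler_to_matrix(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Rotation matrix for intrinsic yaw–pitch–roll: R = Rz(yaw)·Ry(pitch)·Rx(roll)."""
    return Rotation.from_euler("ZYX", [yaw, pitch, roll], degrees=True).as_matrix()


def _eulers_to_matrices(roll, pitch, yaw) -> np.ndarray:
    ang = np.column_stack([yaw, pitch, roll])
    return Rotation.from_euler("ZYX", ang, degrees=True).as_matrix()


def matrix_to_euler(R: np.ndarray, tol: float = 1e-6):
    """Invert :func:`euler_to_matrix`; returns ``(roll, pitch, yaw, gimbal_flag)``.

    Near gimbal lock (|pitch| > 89.9°) the decomposition is degenerate: roll
    is set to 0, the remaining freedom folds into yaw, and the flag is set.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > tol:
        raise SchemaError("input is not an orthonormal 3x3 rotation within tolerance")
    roll, pitch, yaw, flag = _matrices_to_eulers(R[None])
    return float(roll[0]), float(pitch[0]), float(yaw[0]), bool(flag[0])


def _matrices_to_eulers(mats: np.ndarray):
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*[Gg]imbal lock.*")
        ang = Rotation.from_matrix(mats).as_euler("ZYX", degrees=True)
    ang = np.atleast_2d(ang)
    yaw, pitch, roll = ang[:, 0], ang[:, 1], ang[:, 2]
    flags = np.abs(pitch) > GIMBAL_PITCH_DEG
    if np.any(flags):
        # at |pitch| -> 90 the matrix depends only on yaw -/+ roll: fold the
        # degenerate freedom into yaw and zero roll (scipy already reports
        # roll = 0 at exact lock; enforce the same convention near lock)
        yaw = np.where(flags, yaw - np.sign(pitch) * roll, yaw)
        roll = np.where(flags, 0.0, roll)
    return roll, pitch, yaw, flags


def euler_stream_to_trajectory(stream: TimeSeriesRecording, system: str = "imu") -> RotationTrajectory:
    """Convert a (roll, pitch, yaw) degree stream to a rotation trajectory."""
    for ch in ("roll", "pitch", "yaw"):
        if ch not in stream.channels:
            raise SchemaError(f"Euler stream missing channel {ch!r}")
    mats = _eulers_to_matrices(
        stream.channel("roll"), stream.channel("pitch"), stream.channel("yaw")
    )
    return RotationTrajectory(
        times=stream.times,
        matrices=mats,
        rate_hz=stream.rate_hz,
        side=stream.side,
        system=system,
    )


def _project_so3(M: np.ndarray, min_sv: float = 1e-12) -> np.ndarray:
    U, S, Vt = np.linalg.svd(M)
    if S[-1] < min_sv * max(S[0], 1.0):
        raise AlignmentError("degenerate (rank-deficient) rotation accumulation")
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def estimate_rigid_alignment(
    imu: RotationTrajectory, cam: RotationTrajectory
) -> np.ndarray:
    """Fixed rotation A minimizing Σₜ ‖R_cam(t) − R_imu(t)·A‖²_F.

    Frames are paired by nearest-neighbor timestamp matching within half the
    coarser sample period; the solution is the orthogonal-Procrustes rotation
    from the SVD of Σₜ R_imu(t)ᵀ·R_cam(t), with the determinant corrected
    to +1.
    """
    tol = 0.5 * max(imu.dt, cam.dt)
    idx = np.searchsorted(cam.times, imu.times)
    idx = np.clip(idx, 1, cam.times.size - 1)
    left, right = cam.times[idx - 1], cam.times[idx]
    nearest = np.where(imu.times - left < right - imu.times, idx - 1, idx)
    matched = np.abs(cam.times[nearest] - imu.times) <= tol
    if matched.sum() < 3:
        raise AlignmentError(
            f"only {int(matched.sum())} time-matched frame pairs; need >= 3"
        )
    Ri = imu.matrices[matched]
    Rc = cam.matrices[nearest[matched]]
    M = np.einsum("nji,njk->ik", Ri, Rc)  # Σ Ri^T Rc
    return _project_so3(M)


def mean_rotation(matrices: np.ndarray) -> np.ndarray:
    """Chordal mean: arithmetic average projected back onto SO(3) via SVD."""
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.shape[0] == 0:
        raise ProcessingError("cannot average zero rotations")
    M = mats.mean(axis=0)
    try:
        return _project_so3(M, min_sv=1e-8)
    except AlignmentError as exc:
        raise ProcessingError(f"degenerate rotation mean: {exc}") from exc


def reference_to_initial(
    traj: RotationTrajectory, ref_window_s: float = 0.3
) -> TimeSeriesRecording:
    """Express the trajectory relative to its initial pose.

    The reference pose R̄₀ is the mean rotation over the first
    ``ref_window_s`` of the trajectory; relative rotations are
    R_rel(t) = R̄₀ᵀ·R(t) (so the initial pose maps to the identity) and are
    returned as an Euler-angle stream with gimbal flags in ``meta``.
    """
    t0 = traj.times[0]
    in_win = traj.times < t0 + ref_window_s
    if not np.any(in_win):
        raise RangeError(f"reference window {ref_window_s} s holds no frames")
    if ref_window_s > traj.span[1] - traj.span[0]:
        raise RangeError("reference window longer than trajectory")
    R0 = mean_rotation(traj.matrices[in_win])
    rel = np.einsum("ji,njk->nik", R0, traj.matrices)
    roll, pitch, yaw, flags = _matrices_to_eulers(rel)
    return TimeSeriesRecording(
        times=traj.times,
        data=pd.DataFrame({"roll": roll, "pitch": pitch, "yaw": yaw}),
        rate_hz=traj.rate_hz,
        side=traj.side,
        meta={"system": traj.system, "gimbal_flags": flags},
    )


def unwrap_degrees(angles) -> np.ndarray:
    """Add ±360° multiples so consecutive differences lie in (−180°, 180°].

    The first sample is unchanged.
    """
    x = np.asarray(angles, dtype=float)
    if x.size < 2:
        return x.copy()
    d = np.diff(x)
    dw = (d + 180.0) % 360.0 - 180.0
    dw[dw == -180.0] = 180.0  # half-open tie convention
    return np.concatenate([[x[0]], x[0] + np.cumsum(dw)])


def butterworth_lowpass(
    x, order: int = 4, cutoff_hz: float = 6.0, rate_hz: float = 100.0
) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth low-pass with DC gain 1."""
    if not 0 < cutoff_hz < rate_hz / 2:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must be in (0, Nyquist={rate_hz / 2} Hz)"
        )
    x = np.asarray(x, dtype=float)
    b, a = butter(order, cutoff_hz, btype="low", fs=rate_hz)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        raise ProcessingError(
            f"signal of {x.size} samples too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return filtfilt(b, a, x)


def resample_linear(x, times, target_len: int = 1700) -> np.ndarray:
    """Linear interpolation onto ``target_len`` evenly spaced points.

    The output spans ``[times[0], times[-1]]`` with the endpoints preserved
    exactly.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    if x.size != times.size:
        raise SchemaError("values and times differ in length")
    if x.size < 2:
        raise ProcessingError("need at least 2 samples to resample")
    if not np.all(np.diff(times) > 0):
        raise SchemaError("times must be strictly increasing")
    grid = np.linspace(times[0], times[-1], target_len)
    out = np.interp(grid, times, x)
    out[0], out[-1] = x[0], x[-1]
    return out


def rom(angles) -> float:
    """Range of motion: max − min of the relative angle series, degrees."""
    x = np.asarray(angles, dtype=float)
    if x.size == 0:
        raise ProcessingError("cannot take ROM of an empty series")
    return float(x.max() - x.min())


def geodesic_angle_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Rotation angle of R1ᵀ·R2 in degrees (distance on SO(3))."""
    c = (np.trace(R1.T @ R2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _per_cycle_rom(
    stream: TimeSeriesRecording,
    annotation: CycleAnnotation,
    cfg: KinematicsConfig,
) -> dict[str, np.ndarray]:
    out = {axis: [] for axis in cfg.axis_channels}
    for seg in split_cycles(stream, annotation):
        for axis, ch in cfg.axis_channels.items():
            ang = unwrap_degrees(seg.channel(ch))
            ang = butterworth_lowpass(
                ang, cfg.filter_order, cfg.cutoff_hz, stream.rate_hz
            )
            ang = resample_linear(ang, seg.times, cfg.target_len)
            out[axis].append(rom(ang))
    return {axis: np.asarray(v) for axis, v in out.items()}


def run_kinematics_pipeline(
    imu_euler: TimeSeriesRecording,
    cam: RotationTrajectory,
    annotation: CycleAnnotation,
    config: KinematicsConfig | None = None,
    participant: str = "",
) -> list[ROMRecord]:
    """Full chain: align → reference → split → unwrap → filter → resample → ROM.

    The rigid mounting rotation is estimated per trial from the overlapping
    frames and applied on the sensor side (post-multiplication); both systems
    are then referenced to their own initial pose and processed identically.
    """
    cfg = config or KinematicsConfig()
    imu_traj = euler_stream_to_trajectory(imu_euler, system="imu")
    A = estimate_rigid_alignment(imu_traj, cam)
    imu_aligned = imu_traj.with_matrices(imu_traj.matrices @ A)
    rel_imu = reference_to_initial(imu_aligned, cfg.ref_window_s)
    rel_cam = reference_to_initial(cam, cfg.ref_window_s)
    rom_imu = _per_cycle_rom(rel_imu, annotation, cfg)
    rom_cam = _per_cycle_rom(rel_cam, annotation, cfg)
    side = imu_euler.side or cam.side
    return [
        ROMRecord(
            participant=participant,
            side=side,
            axis=axis,
            per_cycle_device=rom_imu[axis],
            per_cycle_reference=rom_cam[axis],
            rom_device_deg=float(rom_imu[axis].mean()),
            rom_reference_deg=float(rom_cam[axis].mean()),
        )
        for axis in cfg.axis_channels
    ]
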