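"""Seeded paired-sensor simulator with known ground truth.

The study the pipeline targets recorded 11 participants performing five
repetitions of a bilateral tooth-brushing task (5 s rests), with six shoulder
muscles per limb observed by two EMG systems (1000 Hz) and the arm-segment
orientation observed by an IMU (100 Hz Euler angles, through an unknown fixed
mounting rotation) and by an optical system (100 Hz rotation matrices). The
raw recordings are not public, so this module emulates the acquisition with
a fully seeded generator whose latent truth every downstream stage can be
checked against.

EMG model
---------
Each muscle's activation is a smooth per-cycle burst (Hann window with
participant- and cycle-level width/center variation). Both systems observe a
mixture of a *shared* latent envelope and a system-specific envelope, weighted
by the per-muscle shared-latent fraction f — f = 1 makes the systems measure
the same activation, f = 0 makes them independent. The raw signal is the
envelope amplitude-modulating a zero-mean Gaussian wideband carrier (the
standard phenomenological surface-EMG model), scaled into ADC counts with
system-specific gain, baseline offset and additive white noise. An optional
biphasic spike train at 72 beats/min emulates cardiac contamination of the
left pectoralis major, with an independent phase per system (the two EMG
systems record in separate sessions).

Because the pipeline min–max normalizes every cycle, a pure gain or offset
difference between systems cannot bias the final RMS; the generator's
``device_envelope_exponent`` knob instead distorts the device envelope
*shape* (env**p), producing a controlled, truth-computable inter-device RMS
bias used by the recovery checks.

Kinematics model
----------------
A ground-truth segment trajectory is built from per-axis Hann-profile
excursions whose per-cycle peak-to-peak amplitude equals the configured ROM
target (with participant- and cycle-level variation). The camera observes the
true rotation perturbed by small random rotations; the IMU observes
R_true(t)·R_mount (body-fixed mounting misalignment) as Euler angles plus
angular noise. Truth records the mounting rotation and per-cycle true ROM.

Determinism: every output is a pure function of (config, seed); sub-streams
are keyed by (purpose, participant, side) through ``SeedSequence`` spawn keys
so regenerating one participant never shifts another's data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RangeError, SchemaError
from .kinematics import euler_to_matrix
from .recordings import RotationTrajectory, TimeSeriesRecording
from .segmentation import CycleAnnotation

__all__ = [
    "MUSCLES",
    "AXES",
    "SimulationConfig",
    "GroundTruth",
    "generate_timeline",
    "generate_emg_pair",
    "generate_kinematics_pair",
    "inject_sync_tap",
]

MUSCLES = ("PM", "AD", "MD", "PD", "UT", "LT")
AXES = ("axis1", "axis2", "axis3")

# stream purposes (first spawn-key element)
_P_TIMELINE, _P_EMG, _P_KIN = 1, 2, 3
_SHARED, _DEVICE, _REFERENCE = 0, 1, 2

HEART_RATE_HZ = 1.2  # 72 beats/min cardiac artifact

#: Per-muscle mean burst-width fraction of the cycle. Distinct widths give
#: each muscle a distinct normalized-waveform RMS, so rank order is a
#: recoverable truth.
_BURST_WIDTH = {"PM": 0.45, "AD": 0.62, "MD": 0.55, "PD": 0.40, "UT": 0.70, "LT": 0.50}


def _default_shared_fraction() -> dict:
    # high concordance for the superficial PM/AD/MD, low for PD/UT/LT —
    # emulating muscle-dependent between-system agreement
    return {"PM": 0.90, "AD": 0.95, "MD": 0.90, "PD": 0.50, "UT": 0.55, "LT": 0.55}


def _default_rom_targets() -> dict:
    return {"axis1": 45.0, "axis2": 30.0, "axis3": 60.0}


@dataclass
class SimulationConfig:
    """Study-design constants and generator noise model.

    Cohort/protocol defaults follow the emulated study: 11 participants,
    5 task cycles with 5 s rests, EMG at 1000 Hz, orientation streams at
    100 Hz, six muscles and three rotation axes per limb. Cycle duration
    (self-selected pace in the study) defaults to 10 ± 1 s.
    """

    n_participants: int = 11
    n_cycles: int = 5
    cycle_duration_mean_s: float = 10.0
    cycle_duration_sd_s: float = 1.0
    rest_s: float = 5.0
    emg_rate_hz: float = 1000.0
    imu_rate_hz: float = 100.0
    cam_rate_hz: float = 100.0
    video_fps: float = 30.0
    muscles: tuple = MUSCLES
    axes: tuple = AXES

    # EMG observation model
    shared_fraction: dict = field(default_factory=_default_shared_fraction)
    device_gain: float = 1.0
    reference_gain: float = 1.2
    device_offset: float = 0.02
    reference_offset: float = -0.03
    device_noise_sd: float = 0.04
    reference_noise_sd: float = 0.03
    ecg_artifact_amplitude: float = 0.15
    device_envelope_exponent: float = 1.0
    burst_width_participant_sd: float = 0.10
    burst_width_cycle_sd: float = 0.04
    burst_center_sd: float = 0.06
    adc_midscale: float = 2047.5
    counts_scale: float = 300.0

    # kinematics observation model
    rom_targets_deg: dict = field(default_factory=_default_rom_targets)
    rom_participant_cv: float = 0.15
    rom_cycle_cv: float = 0.08
    misalignment_euler_deg: tuple = (15.0, 8.0, -10.0)  # roll, pitch, yaw
    orientation_noise_deg: float = 1.0
    #: validation knob: additive per-cycle excursion miscalibration of the
    #: device trajectory (degrees, every axis); the camera still observes the
    #: true trajectory, so the induced inter-device ROM bias equals this value
    device_rom_bias_deg: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_cycles < 1:
            raise ConfigurationError("n_participants and n_cycles must be >= 1")
        for name in ("emg_rate_hz", "imu_rate_hz", "cam_rate_hz", "video_fps"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.cycle_duration_mean_s <= 0 or self.cycle_duration_sd_s < 0:
            raise ConfigurationError("cycle duration mean must be > 0 and SD >= 0")
        if self.rest_s < 0:
            raise ConfigurationError("rest_s must be >= 0")
        if isinstance(self.shared_fraction, (int, float)):
            self.shared_fraction = {m: float(self.shared_fraction) for m in self.muscles}
        for m in self.muscles:
            f = self.shared_fraction.get(m)
            if f is None or not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"shared-latent fraction for {m} must be in [0, 1], got {f}"
                )
        for ax in self.axes:
            t = self.rom_targets_deg.get(ax)
            if t is None or t < 0:
                raise ConfigurationError(f"ROM target for {ax} must be >= 0, got {t}")
            if t >= 180.0:
                raise ConfigurationError(
                    f"ROM target for {ax} is {t}° >= 180°: unwrap becomes ambiguous"
                )
        if not np.all(np.isfinite(self.misalignment_euler_deg)):
            raise ConfigurationError("misalignment angles must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["muscles"] = list(self.muscles)
        d["axes"] = list(self.axes)
        d["misalignment_euler_deg"] = list(self.misalignment_euler_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("muscles", "axes", "misalignment_euler_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Recoverable truth behind one generated participant/side.

    ``true_alignment`` is the fixed mounting rotation R_mount with
    IMU(t) = R_true(t)·R_mount; the Procrustes alignment estimated by the
    pipeline recovers its inverse (transpose). ``true_rom_deg`` maps axis →
    per-cycle peak-to-peak excursion. ``latent_envelopes`` maps muscle → a
    cycles × 1700 matrix of the shared latent activation sampled on the
    fixed-length grid, and ``latent_rms`` the RMS of each muscle's mean
    normalized latent cycle.
    """

    true_alignment: np.ndarray | None = None
    true_rom_deg: dict | None = None
    latent_envelopes: dict | None = None
    latent_rms: dict | None = None
    sync_time_s: float | None = None

    def to_json(self, path: str | Path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x

        payload = {
            "true_alignment": conv(self.true_alignment),
            "true_rom_deg": conv(self.true_rom_deg),
            "latent_rms": conv(self.latent_rms),
            "sync_time_s": self.sync_time_s,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator keyed by integers/labels."""
    ints = tuple(
        k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in keys
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=ints))


def _side_key(side: str) -> int:
    if side not in ("left", "right"):
        raise SchemaError(f"side must be 'left' or 'right', got {side!r}")
    return 0 if side == "left" else 1


def generate_timeline(config: SimulationConfig, seed: int | None = None) -> CycleAnnotation:
    """Draw the five task-cycle intervals, separated by the configured rest.

    Durations are normal (mean ± SD) truncated at > 0; the first cycle starts
    at t = 0.
    """
    if config.cycle_duration_mean_s <= 0:
        raise ConfigurationError("cycle duration mean must be > 0")
    rng = _substream(config.seed if seed is None else seed, _P_TIMELINE)
    cycles = []
    t = 0.0
    for _ in range(config.n_cycles):
        dur = rng.normal(config.cycle_duration_mean_s, config.cycle_duration_sd_s)
        while dur <= 0:  # truncate at > 0 by redrawing
            dur = rng.normal(config.cycle_duration_mean_s, config.cycle_duration_sd_s)
        cycles.append((t, t + dur))
        t += dur + config.rest_s
    return CycleAnnotation(cycles=cycles, fps=config.video_fps, source="synthetic")


def _hann_burst(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """Hann window of given width/center on the unit cycle coordinate."""
    v = (u - (center - width / 2.0)) / width
    inside = (v >= 0.0) & (v <= 1.0)
    out = np.zeros_like(u)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * v[inside]))
    return out


def _burst_params(rng: np.random.Generator, config: SimulationConfig, muscle: str):
    """Participant-level burst width/center for one muscle from one stream."""
    w = float(
        np.clip(
            rng.normal(_BURST_WIDTH.get(muscle, 0.55), config.burst_width_participant_sd),
            0.15,
            0.90,
        )
    )
    c_lo, c_hi = w / 2.0 + 0.02, 1.0 - w / 2.0 - 0.02
    c = float(np.clip(rng.normal(0.5, config.burst_center_sd), c_lo, c_hi))
    return w, c


def _cycle_params(
    rng: np.random.Generator, config: SimulationConfig, base_w: float, base_c: float
) -> tuple[float, float]:
    """Cycle-level jitter of the participant-level burst parameters."""
    w = float(np.clip(rng.normal(base_w, config.burst_width_cycle_sd), 0.10, 0.95))
    c = float(np.clip(base_c, w / 2.0 + 0.01, 1.0 - w / 2.0 - 0.01))
    return w, c


def _ecg_train(times: np.ndarray, amplitude: float, phase_s: float) -> np.ndarray:
    """Biphasic (one full sine period) spike train at the cardiac rate."""
    width = 0.03  # s, R-wave-like transient
    period = 1.0 / HEART_RATE_HZ
    tt = np.mod(times - phase_s, period)
    out = np.zeros_like(times)
    inside = tt < width
    out[inside] = amplitude * np.sin(2.0 * np.pi * tt[inside] / width)
    return out


def _latent_summary(env_rows: np.ndarray):
    """RMS of the mean normalized latent cycle (independent of the pipeline path)."""
    norm = []
    for row in env_rows:
        lo, hi = row.min(), row.max()
        norm.append(np.zeros_like(row) if hi == lo else (row - lo) / (hi - lo))
    return float(np.sqrt(np.mean(np.mean(norm, axis=0) ** 2)))


def generate_emg_pair(
    annotation: CycleAnnotation,
    config: SimulationConfig,
    seed: int | None = None,
    participant: int = 0,
    side: str = "right",
):
    """Simulate one limb's paired EMG session.

    Returns ``(device, reference, truth)``: two 6-channel recordings at
    ``emg_rate_hz`` in ADC counts, and the latent ground truth (per-cycle
    shared envelopes on the 1700-point grid and their normalized-mean RMS).
    """
    seed = config.seed if seed is None else seed
    s_idx = _side_key(side)
    span = annotation.task_span[1]
    rate = config.emg_rate_hz
    n = int(np.ceil(span * rate - 1e-9))
    times = np.arange(n) / rate

    rng_sh = _substream(seed, _P_EMG, participant, s_idx, _SHARED)
    rng_dev = _substream(seed, _P_EMG, participant, s_idx, _DEVICE)
    rng_ref = _substream(seed, _P_EMG, participant, s_idx, _REFERENCE)

    grid = (np.arange(1700) + 0.5) / 1700.0  # latent-truth cycle grid
    data_d, data_r = {}, {}
    latent_env, latent_rms = {}, {}

    for muscle in config.muscles:
        f = config.shared_fraction[muscle]
        w_sh, c_sh = _burst_params(rng_sh, config, muscle)
        w_d, c_d = _burst_params(rng_dev, config, muscle)
        w_r, c_r = _burst_params(rng_ref, config, muscle)

        env_d = np.zeros(n)
        env_r = np.zeros(n)
        truth_rows = []
        for a, b in annotation.cycles:
            mask = (times >= a) & (times < b)
            u = (times[mask] - a) / (b - a)
            ws, cs = _cycle_params(rng_sh, config, w_sh, c_sh)
            wd, cd = _cycle_params(rng_dev, config, w_d, c_d)
            wr, cr = _cycle_params(rng_ref, config, w_r, c_r)
            sh = _hann_burst(u, cs, ws)
            env_d[mask] = f * sh + (1.0 - f) * _hann_burst(u, cd, wd)
            env_r[mask] = f * sh + (1.0 - f) * _hann_burst(u, cr, wr)
            truth_rows.append(_hann_burst(grid, cs, ws))
        env_d = env_d**config.device_envelope_exponent

        carrier = rng_sh.standard_normal(n)
        sig_d = config.device_gain * env_d * carrier + config.device_offset
        sig_r = config.reference_gain * env_r * carrier + config.reference_offset
        sig_d = sig_d + config.device_noise_sd * rng_dev.standard_normal(n)
        sig_r = sig_r + config.reference_noise_sd * rng_ref.standard_normal(n)

        if side == "left" and muscle == "PM" and config.ecg_artifact_amplitude > 0:
            period = 1.0 / HEART_RATE_HZ
            sig_d = sig_d + _ecg_train(
                times, config.ecg_artifact_amplitude, rng_dev.uniform(0, period)
            )
            sig_r = sig_r + _ecg_train(
                times, config.ecg_artifact_amplitude, rng_ref.uniform(0, period)
            )

        data_d[muscle] = config.adc_midscale + config.counts_scale * sig_d
        data_r[muscle] = config.adc_midscale + config.counts_scale * sig_r
        truth_rows = np.vstack(truth_rows)
        latent_env[muscle] = truth_rows
        latent_rms[muscle] = _latent_summary(truth_rows)

    device = TimeSeriesRecording(
        times=times, data=pd.DataFrame(data_d), rate_hz=rate, side=side,
        meta={"system": "device", "participant": participant},
    )
    reference = TimeSeriesRecording(
        times=times.copy(), data=pd.DataFrame(data_r), rate_hz=rate, side=side,
        meta={"system": "reference", "participant": participant},
    )
    truth = GroundTruth(latent_envelopes=latent_env, latent_rms=latent_rms)
    return device, reference, truth


def generate_kinematics_pair(
    annotation: CycleAnnotation,
    config: SimulationConfig,
    seed: int | None = None,
    participant: int = 0,
    side: str = "right",
):
    """Simulate one limb's simultaneous IMU/camera session.

    Returns ``(imu_euler, cam, truth)``: a (roll, pitch, yaw) degree stream at
    ``imu_rate_hz`` observed through the fixed mounting rotation plus angular
    noise; the camera rotation trajectory at ``cam_rate_hz`` perturbed by
    small random rotations; and the ground truth (mounting rotation,
    per-axis per-cycle true ROM).
    """
    from scipy.spatial.transform import Rotation  # local: keep module import light

    seed = config.seed if seed is None else seed
    s_idx = _side_key(side)
    span = annotation.task_span[1]

    rng_traj = _substream(seed, _P_KIN, participant, s_idx, _SHARED)
    rng_dev = _substream(seed, _P_KIN, participant, s_idx, _DEVICE)
    rng_cam = _substream(seed, _P_KIN, participant, s_idx, _REFERENCE)

    # per-axis per-cycle true peak-to-peak excursions
    rom_cycles: dict[str, np.ndarray] = {}
    for ax in config.axes:
        part = float(np.exp(rng_traj.normal(0.0, config.rom_participant_cv)))
        cyc = np.maximum(0.2, rng_traj.normal(1.0, config.rom_cycle_cv, len(annotation)))
        rom_cycles[ax] = config.rom_targets_deg[ax] * part * cyc
        if np.any(rom_cycles[ax] >= 180.0):
            raise ConfigurationError(
                f"drawn per-cycle ROM for {ax} reaches 180°; lower the target or CV"
            )

    def angles_at(t: np.ndarray, excursion_bias: float = 0.0) -> dict[str, np.ndarray]:
        out = {ax: np.zeros_like(t) for ax in config.axes}
        for i, (a, b) in enumerate(annotation.cycles):
            mask = (t >= a) & (t < b)
            u = (t[mask] - a) / (b - a)
            hann = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
            for ax in config.axes:
                out[ax][mask] = (rom_cycles[ax][i] + excursion_bias) * hann
        return out

    t_imu = np.arange(int(np.ceil(span * config.imu_rate_hz - 1e-9))) / config.imu_rate_hz
    t_cam = np.arange(int(np.ceil(span * config.cam_rate_hz - 1e-9))) / config.cam_rate_hz

    # axis -> euler channel mapping (axis1=roll, axis2=pitch, axis3=yaw)
    def true_matrices(t: np.ndarray, excursion_bias: float = 0.0) -> np.ndarray:
        ang = angles_at(t, excursion_bias)
        ypr = np.column_stack([ang["axis3"], ang["axis2"], ang["axis1"]])
        return Rotation.from_euler("ZYX", ypr, degrees=True).as_matrix()

    r_mis, p_mis, y_mis = config.misalignment_euler_deg
    R_mount = euler_to_matrix(r_mis, p_mis, y_mis)

    # orientation_noise_deg is the RMS *total* orientation perturbation; an
    # isotropic perturbation splits it as noise/sqrt(3) per component
    comp_sd = config.orientation_noise_deg / np.sqrt(3.0)

    # IMU: R_true(t) · R_mount, read out as Euler angles plus angular noise
    imu_mats = true_matrices(t_imu, config.device_rom_bias_deg) @ R_mount
    ypr = Rotation.from_matrix(imu_mats).as_euler("ZYX", degrees=True)
    noise = rng_dev.normal(0.0, comp_sd, ypr.shape)
    imu_euler = TimeSeriesRecording(
        times=t_imu,
        data=pd.DataFrame(
            {
                "roll": ypr[:, 2] + noise[:, 2],
                "pitch": ypr[:, 1] + noise[:, 1],
                "yaw": ypr[:, 0] + noise[:, 0],
            }
        ),
        rate_hz=config.imu_rate_hz,
        side=side,
        meta={"system": "imu", "participant": participant},
    )

    # camera: R_true(t) perturbed by small random rotations
    cam_mats = true_matrices(t_cam)
    if config.orientation_noise_deg > 0:
        rv = rng_cam.normal(0.0, np.radians(comp_sd), (t_cam.size, 3))
        cam_mats = cam_mats @ Rotation.from_rotvec(rv).as_matrix()
    cam = RotationTrajectory(
        times=t_cam,
        matrices=cam_mats,
        rate_hz=config.cam_rate_hz,
        side=side,
        system="camera",
        meta={"participant": participant},
    )
    truth = GroundTruth(true_alignment=R_mount, true_rom_deg=rom_cycles)
    return imu_euler, cam, truth


def inject_sync_tap(
    recording: TimeSeriesRecording,
    time_s: float,
    amplitude: float,
    width_s: float = 0.05,
    channel: str | None = None,
) -> TimeSeriesRecording:
    """Add a half-sine tap transient to one channel; all other samples unchanged."""
    lo, hi = recording.span
    if not lo <= time_s < hi:
        raise RangeError(f"tap time {time_s} s outside recording span [{lo}, {hi})")
    if width_s <= 0:
        raise ConfigurationError("tap width must be > 0")
    channel = channel or recording.channels[0]
    x = recording.channel(channel).copy()
    mask = (recording.times >= time_s) & (recording.times < time_s + width_s)
    x[mask] = x[mask] + amplitude * np.sin(
        np.pi * (recording.times[mask] - time_s) / width_s
    )
    data = recording.data.copy()
    data[channel] = x
    out = recording.with_values(data)
    out.meta["sync_time_s"] = float(time_s)
    return out
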