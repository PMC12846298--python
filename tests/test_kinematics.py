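"""Rotation conversions, rigid alignment, angle processing and ROM extraction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wearagree import (
    SimulationConfig,
    estimate_rigid_alignment,
    generate_kinematics_pair,
    generate_timeline,
    run_kinematics_pipeline,
)
from wearagree.errors import (
    AlignmentError,
    ConfigurationError,
    ProcessingError,
    SchemaError,
)
from wearagree.kinematics import (
    butterworth_lowpass,
    euler_stream_to_trajectory,
    euler_to_matrix,
    matrix_to_euler,
    mean_rotation,
    reference_to_initial,
    resample_linear,
    rom,
    unwrap_degrees,
)
from wearagree.recordings import RotationTrajectory


def _random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng)).as_matrix()


class TestEulerConversions:
    def test_zero_angles_give_identity(self):
        np.testing.assert_allclose(euler_to_matrix(0, 0, 0), np.eye(3), atol=1e-15)

    def test_pure_yaw_maps_x_to_y(self):
        R = euler_to_matrix(0, 0, 90)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_round_trip_away_from_gimbal_lock(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            roll, yaw = rng.uniform(-179, 179, 2)
            pitch = rng.uniform(-88.9, 88.9)
            r2, p2, y2, flag = matrix_to_euler(euler_to_matrix(roll, pitch, yaw))
            assert not flag
            assert abs(r2 - roll) < 1e-9
            assert abs(p2 - pitch) < 1e-9
            assert abs(y2 - yaw) < 1e-9

    def test_gimbal_lock_is_flagged_with_zero_roll(self):
        R = euler_to_matrix(25.0, 90.0, 10.0)
        roll, pitch, yaw, flag = matrix_to_euler(R)
        assert flag
        assert roll == 0.0
        assert pitch == pytest.approx(90.0, abs=1e-6)
        # the folded decomposition still reproduces the matrix
        np.testing.assert_allclose(euler_to_matrix(roll, pitch, yaw), R, atol=1e-9)

    def test_non_orthonormal_input_rejected(self):
        with pytest.raises(SchemaError):
            matrix_to_euler(np.eye(3) * 1.5)


class TestRigidAlignment:
    def _trajectories(self, n=200, seed=0, A=None, noise_deg=0.0):
        rng = np.random.default_rng(seed)
        times = np.arange(n) / 100.0
        mats = Rotation.random(n, random_state=np.random.RandomState(seed)).as_matrix()
        imu = RotationTrajectory(times=times, matrices=mats, rate_hz=100.0, system="imu")
        cam_m = mats if A is None else mats @ A
        if noise_deg > 0:
            rv = rng.normal(0, np.radians(noise_deg) / np.sqrt(3), (n, 3))
            cam_m = cam_m @ Rotation.from_rotvec(rv).as_matrix()
        cam = RotationTrajectory(times=times.copy(), matrices=cam_m, rate_hz=100.0, system="camera")
        return imu, cam

    def test_identical_streams_give_identity(self):
        imu, cam = self._trajectories()
        np.testing.assert_allclose(estimate_rigid_alignment(imu, cam), np.eye(3), atol=1e-12)

    def test_noiseless_recovery_of_random_rotation(self):
        for seed in range(5):
            A0 = Rotation.random(random_state=np.random.RandomState(100 + seed)).as_matrix()
            imu, cam = self._trajectories(seed=seed, A=A0)
            A = estimate_rigid_alignment(imu, cam)
            assert np.linalg.norm(A - A0) < 1e-8

    def test_result_is_a_proper_rotation_under_noise(self):
        A0 = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        imu, cam = self._trajectories(seed=3, A=A0, noise_deg=5.0)
        A = estimate_rigid_alignment(imu, cam)
        np.testing.assert_allclose(A @ A.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(A) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_matched_pairs_is_an_error(self):
        imu, cam = self._trajectories(n=2)
        with pytest.raises(AlignmentError):
            estimate_rigid_alignment(imu, cam)


class TestMeanRotation:
    def test_single_and_repeated_matrix(self):
        R = Rotation.from_euler("ZYX", [30, 20, 10], degrees=True).as_matrix()
        np.testing.assert_allclose(mean_rotation(R), R, atol=1e-12)
        np.testing.assert_allclose(mean_rotation(np.stack([R, R])), R, atol=1e-12)

    def test_symmetric_pair_averages_to_identity(self):
        for theta in (10.0, 45.0, 80.0):
            Rp = Rotation.from_euler("x", theta, degrees=True).as_matrix()
            Rm = Rotation.from_euler("x", -theta, degrees=True).as_matrix()
            np.testing.assert_allclose(mean_rotation(np.stack([Rp, Rm])), np.eye(3), atol=1e-10)

    def test_stays_on_so3(self):
        mats = Rotation.random(20, random_state=np.random.RandomState(1)).as_matrix()
        M = mean_rotation(mats)
        np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-10)


class TestReferenceToInitial:
    def test_static_trajectory_gives_zero_angles(self):
        R = Rotation.from_euler("ZYX", [40, 10, -25], degrees=True).as_matrix()
        traj = RotationTrajectory(
            times=np.arange(100) / 100.0,
            matrices=np.repeat(R[None], 100, axis=0),
            rate_hz=100.0,
        )
        rel = reference_to_initial(traj, 0.3)
        for ch in ("roll", "pitch", "yaw"):
            np.testing.assert_allclose(rel.channel(ch), 0.0, atol=1e-9)

    def test_invariance_under_global_lab_rotation(self):
        """Relative angles do not depend on any fixed pre-rotation of the
        laboratory frame."""
        mats = Rotation.random(150, random_state=np.random.RandomState(9)).as_matrix()
        times = np.arange(150) / 100.0
        traj = RotationTrajectory(times=times, matrices=mats, rate_hz=100.0)
        G = Rotation.random(random_state=np.random.RandomState(10)).as_matrix()
        rotated = RotationTrajectory(times=times.copy(), matrices=G @ mats, rate_hz=100.0)
        a = reference_to_initial(traj, 0.3)
        b = reference_to_initial(rotated, 0.3)
        for ch in ("roll", "pitch", "yaw"):
            np.testing.assert_allclose(a.channel(ch), b.channel(ch), atol=1e-8)

    def test_window_uses_expected_frame_count(self):
        mats = Rotation.random(100, random_state=np.random.RandomState(2)).as_matrix()
        traj = RotationTrajectory(times=np.arange(100) / 100.0, matrices=mats, rate_hz=100.0)
        in_win = traj.times < traj.times[0] + 0.3
        assert in_win.sum() == 30


class TestUnwrap:
    def test_wraparound_example(self):
        np.testing.assert_allclose(unwrap_degrees([179.0, -179.0]), [179.0, 181.0])

    def test_smooth_series_unchanged(self):
        x = np.linspace(-170, 170, 300)
        np.testing.assert_allclose(unwrap_degrees(x), x)

    def test_matches_cumulative_wrapped_difference_oracle(self):
        rng = np.random.default_rng(12)
        x = np.cumsum(rng.uniform(-200, 200, 500))
        wrapped = (x + 180.0) % 360.0 - 180.0
        # oracle: rebuild by accumulating wrapped-to-(−180,180] differences
        out = [wrapped[0]]
        for d in np.diff(wrapped):
            dw = (d + 180.0) % 360.0 - 180.0
            if dw == -180.0:
                dw = 180.0
            out.append(out[-1] + dw)
        np.testing.assert_allclose(unwrap_degrees(wrapped), out, atol=1e-9)


class TestButterworth:
    def test_dc_gain_is_one(self):
        np.testing.assert_allclose(
            butterworth_lowpass(np.full(1000, 3.3), rate_hz=100.0), 3.3, atol=1e-9
        )

    @pytest.mark.parametrize(
        "freq,band",
        [(0.5, "pass"), (40.0, "stop")],
    )
    def test_frequency_response(self, freq, band):
        t = np.arange(3000) / 100.0
        x = np.sin(2 * np.pi * freq * t)
        y = butterworth_lowpass(x, order=4, cutoff_hz=6.0, rate_hz=100.0)
        amp = np.abs(y[500:-500]).max()
        if band == "pass":
            assert amp > 0.99
        else:
            assert amp < 0.01

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            butterworth_lowpass(np.ones(100), cutoff_hz=50.0, rate_hz=100.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ProcessingError):
            butterworth_lowpass(np.ones(10), rate_hz=100.0)


class TestResampleLinear:
    def test_ramp_preserves_endpoints_exactly(self):
        t = np.linspace(0.0, 2.0, 313)
        x = 5.0 * t - 1.0
        y = resample_linear(x, t)
        assert y.size == 1700
        assert y[0] == x[0] and y[-1] == x[-1]
        np.testing.assert_allclose(y, np.linspace(x[0], x[-1], 1700), atol=1e-9)

    def test_native_uniform_1700_is_identity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=1700)
        t = np.arange(1700) / 100.0
        np.testing.assert_allclose(resample_linear(x, t), x, atol=1e-9)

    def test_unordered_times_rejected(self):
        with pytest.raises(SchemaError):
            resample_linear([1.0, 2.0, 3.0], [0.0, 2.0, 1.0])


def test_rom_closed_forms():
    assert rom(np.full(50, 12.0)) == 0.0
    t = np.linspace(0, 1, 2001)
    assert rom(20.0 * np.sin(2 * np.pi * t)) == pytest.approx(40.0, abs=1e-3)
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    assert rom(x) == rom(rng.permutation(x))


class TestFullPipeline:
    def _noiseless_cfg(self, **kw):
        base = dict(
            seed=5,
            cycle_duration_mean_s=4.0,
            cycle_duration_sd_s=0.3,
            rest_s=1.0,
            orientation_noise_deg=0.0,
            rom_participant_cv=0.0,
            rom_cycle_cv=0.0,
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_noiseless_identity_misalignment_systems_agree(self):
        cfg = self._noiseless_cfg(misalignment_euler_deg=(0.0, 0.0, 0.0))
        ann = generate_timeline(cfg)
        imu, cam, _ = generate_kinematics_pair(ann, cfg, participant=0, side="right")
        for rec in run_kinematics_pipeline(imu, cam, ann):
            assert rec.rom_device_deg == pytest.approx(rec.rom_reference_deg, abs=0.1)
            assert rec.per_cycle_device.size == 5
            assert rec.per_cycle_reference.size == 5

    def test_noiseless_random_misalignment_agrees_after_alignment(self):
        cfg = self._noiseless_cfg(misalignment_euler_deg=(37.0, -21.0, 64.0))
        ann = generate_timeline(cfg)
        imu, cam, truth = generate_kinematics_pair(ann, cfg, participant=0, side="left")
        A = estimate_rigid_alignment(euler_stream_to_trajectory(imu), cam)
        assert np.linalg.norm(A - truth.true_alignment.T) < 1e-7
        for rec in run_kinematics_pipeline(imu, cam, ann):
            assert rec.rom_device_deg == pytest.approx(rec.rom_reference_deg, abs=0.1)

    def test_noiseless_rom_target_recovered(self):
        # protocol-scale cycle durations: the 0.3 s reference window then
        # covers a negligible fraction of the cycle, so per-axis peak-to-peak
        # excursions match the configured targets closely
        cfg = self._noiseless_cfg(
            cycle_duration_mean_s=10.0,
            cycle_duration_sd_s=1.0,
            rest_s=5.0,
            rom_targets_deg={"axis1": 25.0, "axis2": 40.0, "axis3": 55.0},
        )
        ann = generate_timeline(cfg)
        imu, cam, _ = generate_kinematics_pair(ann, cfg, participant=0, side="right")
        expected = {"axis1": 25.0, "axis2": 40.0, "axis3": 55.0}
        for rec in run_kinematics_pipeline(imu, cam, ann):
            assert rec.rom_device_deg == pytest.approx(expected[rec.axis], abs=0.5)
            assert rec.rom_reference_deg == pytest.approx(expected[rec.axis], abs=0.5)

    def test_intermediate_matrices_stay_on_so3(self):
        cfg = SimulationConfig(
            seed=2, cycle_duration_mean_s=3.0, cycle_duration_sd_s=0.2, rest_s=0.5
        )
        ann = generate_timeline(cfg)
        imu, cam, _ = generate_kinematics_pair(ann, cfg, participant=0, side="right")
        traj = euler_stream_to_trajectory(imu)
        A = estimate_rigid_alignment(traj, cam)
        aligned = traj.with_matrices(traj.matrices @ A)
        aligned.validate(tol=1e-6)
        cam.validate(tol=1e-6)

    def test_sagittal_mirror_negates_axis1_but_preserves_rom(self):
        """Conjugating the trajectory by the sagittal-plane reflection negates
        the signed axis-1 (and axis-3) angles while every axis ROM is
        unchanged."""
        cfg = self._noiseless_cfg()
        ann = generate_timeline(cfg)
        _, cam, _ = generate_kinematics_pair(ann, cfg, participant=0, side="right")
        S = np.diag([1.0, -1.0, 1.0])
        mirrored = cam.with_matrices(S @ cam.matrices @ S)
        rel = reference_to_initial(cam, 0.3)
        rel_m = reference_to_initial(mirrored, 0.3)
        np.testing.assert_allclose(rel_m.channel("roll"), -rel.channel("roll"), atol=1e-8)
        np.testing.assert_allclose(rel_m.channel("pitch"), rel.channel("pitch"), atol=1e-8)
        for ch in ("roll", "pitch", "yaw"):
            assert rom(rel_m.channel(ch)) == pytest.approx(rom(rel.channel(ch)), abs=1e-8)
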