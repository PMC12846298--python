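# Methods

This note documents the models behind `wearagree`: the processing chains,
the synthetic-data generator that stands in for raw cohort recordings, the
parameters that matter, and the numerical choices made where the design was
genuinely open.

## Study design emulated by the generator

The pipeline targets a validation study design in which participants perform
five repetitions of a bilateral tooth-brushing task with 5 s rests, while six
shoulder muscles per limb (pectoralis major PM, anterior/middle/posterior
deltoid AD/MD/PD, upper/lower trapezius UT/LT) are recorded at 1000 Hz by a
wearable prototype and by a reference EMG system, and the arm-segment
orientation is recorded at 100 Hz by the wearable's IMU and by an optical
motion-capture system. Task cycles are annotated from 30 frames/s video.
Raw recordings of this kind are generally not deposited, so the
`synthetic` module generates seeded cohorts with a known latent truth;
defaults are fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| participants | 11 | cohort size of the emulated design |
| cycles × duration | 5 × 10 ± 1 s | self-selected brushing pace; duration is not prescribed by the protocol, 10 s is a realistic choice |
| rest between cycles | 5 s | protocol constant |
| EMG rate | 1000 Hz | device constant |
| IMU / camera rate | 100 Hz | device constant (shared timestamps by default) |
| shared-latent fraction | PM 0.90, AD 0.95, MD 0.90, PD 0.50, UT 0.55, LT 0.55 | emulates muscle-dependent between-system concordance (superficial muscles agree well; PD/UT/LT are placement- and crosstalk-sensitive) |
| EMG noise SD (device/reference) | 0.04 / 0.03 of burst amplitude | prototype slightly noisier than the laboratory system |
| ECG artifact | 0.15 amplitude, 72 beats/min, left PM only | cardiac proximity of the left pectoralis major |
| ROM targets (axis 1/2/3) | 45° / 30° / 60° | plausible shoulder excursions for the task; axis 2 is the Euler mid-angle and is kept well below gimbal lock |
| ROM variability | 15% between participants, 8% between cycles | typical functional-task repeatability |
| mounting misalignment | (15°, 8°, −10°) roll/pitch/yaw | a deliberately non-trivial fixed sensor mounting |
| orientation noise | 1° RMS total rotation | typical consumer-IMU orientation error at rest |

## EMG model

Each muscle's latent activation is a per-cycle Hann burst with a per-muscle
mean width (fraction of the cycle), participant-level and cycle-level width
jitter, and center jitter. Hann bursts are smooth, compactly supported inside
the cycle, and have an analytically known normalized shape, which makes the
per-cycle min–max normalization and the RMS of the mean waveform exactly
recoverable truths. Both systems observe a convex mixture of a shared latent
envelope and a system-specific envelope weighted by the shared-latent
fraction f; f = 1 makes the two systems measure the same activation, f = 0
makes them independent — downstream between-system correlation of the RMS
across participants is then ≈ 0 and increases monotonically with f.

The raw signal is the envelope amplitude-modulating a zero-mean Gaussian
wideband carrier (the standard phenomenological surface-EMG model), scaled
into ADC counts with system-specific gain, offset and additive white noise.
The carrier is shared between the systems so that the fully noiseless,
equal-gain configuration produces bitwise-identical channels up to a constant
offset — a degenerate case the tests rely on. Because every cycle is min–max
normalized by the pipeline, gain and offset differences cannot bias the
final RMS; two dedicated knobs exist for validation experiments:

* `device_envelope_exponent` distorts the device envelope *shape*
  (env → env^p), producing a persistent inter-device RMS difference;
* `device_rom_bias_deg` (kinematics) adds a fixed excursion miscalibration
  to the device-observed trajectory; with single-axis motion the induced
  inter-device ROM bias equals this value exactly, which is what the
  bias-recovery check uses.

## Kinematics model

The ground-truth segment orientation is built in Euler space (intrinsic
z-y′-x″, i.e. R = Rz(yaw)·Ry(pitch)·Rx(roll)): each axis follows a Hann
profile per cycle whose peak-to-peak amplitude is the per-cycle true ROM.
The camera observes R_true(t) post-multiplied by small random rotations; the
IMU observes R_true(t)·R_mount (a body-fixed mounting rotation) read out as
Euler angles with additive angular noise. `orientation_noise_deg` is defined
as the RMS *total* orientation perturbation; since the perturbation is
isotropic, each rotation-vector / Euler component receives SD = value/√3.
The same convention is applied to both systems.

Ground truth records the mounting rotation (whose inverse the Procrustes
alignment estimates) and the per-axis per-cycle ROM.

## Pipeline numerical choices

* **ADC transfer** `v = ((raw/(2^bits − 1)) − 0.5)·vref/gain` with defaults
  12 bits / 3.3 V / gain 1000. Normalization makes the choice immaterial to
  results; out-of-range samples are clipped with a warning.
* **Envelope edges**: the 1 s moving average uses reflection padding.
  Zero padding would droop the envelope at cycle boundaries and bias the
  per-cycle min used by normalization.
* **Fixed-length resampling** uses the mirror construction
  `[reverse(x), x, reverse(x)]`, linear resampling to 3×1700 points, and the
  central block. This realization is exactly the identity when the cycle
  already has 1700 samples.
* **Windows** are half-open `[start, end)` everywhere, so no sample belongs
  to two cycles and trimming is idempotent.
* **Sync-tap detection** uses deviation from a 0.5 s baseline with a default
  threshold of 8 baseline SDs; with taps ≥ 20× the noise SD the detection
  error is below two sample periods in ≥ 99% of seeded trials.
* **Euler convention** is fixed to intrinsic yaw–pitch–roll for both
  systems; any single convention applied identically to both cancels in the
  ROM comparison. Near gimbal lock (|pitch| > 89.9°) the decomposition sets
  roll = 0, folds the freedom into yaw, and flags the sample.
* **Alignment** is one-sided (post-multiplication on the IMU side): a single
  rigidly mounted sensor has one unknown mounting rotation. Frames are
  paired by nearest-neighbor timestamps within half the coarser sample
  period; the accumulation Σ R_imuᵀR_cam is projected to SO(3) by SVD with
  determinant correction, and rank-deficient accumulations raise an error.
  The transform is estimated per trial (the most conservative choice; a
  per-participant calibration could reuse it).
* **Initial-pose referencing** uses the chordal mean (SVD projection of the
  arithmetic matrix mean) over the first 0.3 s and composes as R̄₀ᵀ·R(t), so
  the initial pose maps to the identity; the alternative right-composition
  changes the Euler decomposition and was fixed out by this choice for both
  systems.
* **Unwrapping** adds ±360° multiples so consecutive differences lie in
  (−180°, 180°]; the half-open tie convention is pinned (a difference of
  exactly −180° unwraps to +180°), which is why the three-line modular
  implementation is used rather than a library unwrap with a different tie
  rule.
* **Butterworth cutoff** defaults to 6 Hz (4th order, zero-phase
  forward–backward): volitional upper-limb movement lives well below 6 Hz,
  and zero-phase filtering avoids lag that would bias per-cycle extrema. The
  cutoff is configurable; it is not prescribed by the emulated protocol.
* **Agreement conventions**: differences are device − reference; the LOA
  multiplier is the normal 1.96 (printed LOA are symmetric about the bias by
  construction); sample SDs use n−1 throughout; between-device ICC pools
  participants within each limb (n = 11, k = 2); CV is aggregated across
  subjects by arithmetic mean; per-repetition RMS (the cycle-level analogue
  of the headline RMS) feeds intra-device ICC and CV. Rounding to two
  decimals happens only at report rendering.

## What the generator does and does not emulate

The generator reproduces the *structure* of the validation data — shared
latent activation with device-specific observation, a rigid mounting
misalignment, simultaneous IMU/camera observation of one trajectory, cycle
timing from an annotated protocol — with all randomness derived from one
seed and sub-streams keyed by participant and side.

It deliberately does not model: soft-tissue artifact (the dominant source of
real IMU–camera disagreement during functional movement), marker occlusion
or labeling errors, electrode–skin impedance drift, Bluetooth packet loss,
non-stationary muscle recruitment, or sensor-fusion dynamics inside the IMU.
Consequently the synthetic kinematics agreement is near-perfect (ICC ≈ 1,
LOA within ±1°) — far tighter than any real-device validation — and passing
tests demonstrate the correctness of the *analysis*, not the performance of
any physical device. The EMG branch, with its separate-session observation
model, produces the muscle-dependent moderate agreement pattern by
construction of the shared-latent fractions.

## Problem sizes used by the checks

The stochastic suites use: 500 seeded trials for mounting-rotation recovery
(median geodesic error), 200 seeded participant-side simulations for ROM
recovery (each a full generator + pipeline run at 1° noise with a random
mounting rotation), 40 trials for inter-device bias recovery, 1000 simulated
pairs for LOA coverage, and a 5-point orientation-noise grid with replicated
11-participant cohorts for the ICC monotonicity check. Property tests that
do not depend on protocol-scale durations run on shortened timelines
(2.5–4 s cycles) to keep the suite fast; checks that are sensitive to the
envelope-window-to-cycle ratio or the reference-window fraction (latent rank
preservation, ROM target recovery) run at the 10 s protocol scale.

## Known limitations

* The per-cycle 0–1 normalization makes absolute amplitude unrecoverable by
  design; only waveform-shape information survives into the RMS.
* Euler-space ROM of simultaneous multi-axis motion is subject to
  cross-coupling: per-axis peak-to-peak values are exactly the configured
  targets only for single-axis motion, and within a fraction of a degree at
  protocol scale otherwise.
* The orientation-noise inflation of per-cycle extrema biases ROM upward for
  both systems (≈ 0.5–1° at 1° noise); it largely cancels in device − reference
  comparisons but not against the noise-free truth.
* Gimbal-locked samples are flagged, not excluded; trajectories approaching
  |pitch| = 90° should use a different axis assignment.
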