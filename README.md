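# wearagree

Method-agreement validation for paired wearable sEMG/IMU recordings against
gold-standard reference systems.

## The problem

Low-cost wearable devices that record surface electromyography (sEMG) and
inertial orientation (IMU) promise quantitative monitoring of upper-limb
function during activities of daily living — for example, bilateral tooth
brushing performed in five repetitions by a cohort of participants. Before
such a device can be used clinically, its measurements must be shown to agree
with established references: a laboratory EMG acquisition system for muscle
activation amplitude, and an optical motion-capture system for shoulder range
of motion (ROM). `wearagree` implements that validation analysis as a tested,
reusable pipeline, together with a fully seeded synthetic cohort generator
with known ground truth, so every stage can be verified without access to raw
recordings.

It is aimed at biomechanics and rehabilitation researchers who need a
reproducible implementation of the processing chains and the
method-comparison statistics, and at anyone who wants to study how those
statistics behave under controlled, known conditions.

## What it computes

**EMG amplitude chain** (identical for device and reference, per
participant/side/muscle): ADC counts → volts → mean-offset removal →
full-wave rectification → 1 s moving-average envelope → split into the five
annotated task cycles → mirror-padded resampling of each cycle to 1700
points → per-cycle min–max normalization to [0, 1] → pointwise mean of the
five normalized cycles → RMS of the mean waveform. Per-repetition RMS values
feed intra-device reliability and the coefficient of variation.

**Kinematics chain** (per participant/side/axis): the IMU Euler stream
(roll, pitch, yaw; intrinsic z-y′-x″ convention) is converted to rotation
matrices; the fixed sensor-mounting rotation A is estimated against the
camera's segment→laboratory matrices by orthogonal Procrustes on SO(3),

    A = argmin_{A ∈ SO(3)} Σ_t ‖R_cam(t) − R_imu(t)·A‖²_F ,

solved from the SVD of Σ_t R_imuᵀ(t)·R_cam(t) with determinant correction.
Both trajectories are referenced to the chordal-mean rotation over the first
0.3 s (R_rel(t) = R̄₀ᵀ·R(t)), re-expressed as Euler angles, unwrapped,
low-pass filtered (zero-phase 4th-order Butterworth, 6 Hz), resampled to
1700 points per cycle, and summarized as per-cycle ROM = max − min, averaged
over the five cycles.

**Agreement battery** per target (muscle or axis) × limb, with differences
oriented device − reference:

* Bland–Altman bias `d̄` and 95% limits of agreement `d̄ ± 1.96·SD(d)`;
* Pearson correlation r;
* between-device ICC(2,1) — two-way random effects, absolute agreement,
  single measures: `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))`;
* intra-device ICC(2,1) across the five repetitions, per system;
* CV% = mean over subjects of `100·SD(5 reps)/mean(5 reps)`.

## Worked example

```python
from wearagree import (SimulationConfig, generate_timeline, generate_emg_pair,
                       generate_kinematics_pair, emg_rms_table,
                       run_kinematics_pipeline)

cfg = SimulationConfig(seed=1)          # 11 participants, 5 cycles of ~10 s
timeline = generate_timeline(cfg)
device, reference, truth = generate_emg_pair(timeline, cfg,
                                             participant=0, side="right")
for rec in emg_rms_table(device, reference, timeline,
                         participant="P01", side="right")[:3]:
    print(f"{rec.muscle}: device RMS {rec.rms_device:.3f}  "
          f"reference RMS {rec.rms_reference:.3f}  "
          f"latent RMS {truth.latent_rms[rec.muscle]:.3f}")

imu, cam, kin_truth = generate_kinematics_pair(timeline, cfg,
                                               participant=0, side="right")
for rec in run_kinematics_pipeline(imu, cam, timeline, participant="P01"):
    print(f"{rec.axis}: IMU ROM {rec.rom_device_deg:.1f} deg  "
          f"camera ROM {rec.rom_reference_deg:.1f} deg  "
          f"true ROM {kin_truth.true_rom_deg[rec.axis].mean():.1f} deg")
```

prints

```
PM: device RMS 0.398  reference RMS 0.404  latent RMS 0.394
AD: device RMS 0.531  reference RMS 0.537  latent RMS 0.553
MD: device RMS 0.506  reference RMS 0.516  latent RMS 0.522
axis1: IMU ROM 53.6 deg  camera ROM 53.6 deg  true ROM 53.0 deg
axis2: IMU ROM 35.2 deg  camera ROM 35.2 deg  true ROM 34.2 deg
axis3: IMU ROM 61.1 deg  camera ROM 61.5 deg  true ROM 60.8 deg
```

The RMS values are unitless (RMS of the mean 0–1-normalized cycle waveform):
both systems track the latent activation truth closely for these
high-concordance muscles. The ROM rows show the IMU, after mounting-rotation
alignment, agreeing with the camera to a fraction of a degree, with the
residual offset from truth caused by orientation noise inflating per-cycle
extrema.

The same analysis end-to-end, from a shell:

```sh
wearagree full --seed 1 --outdir results/
```

writes `agreement_emg.csv` (12 muscle × limb rows), `agreement_rom.csv`
(6 axis × limb rows), Bland–Altman point tables, a run manifest with SHA-256
digests, and a markdown report, e.g.:

```
| Target | Limb | Bias | LOA (Lower–Upper) | Pearson r | ICC (between) | ... |
| PM | left  | -0.00 | -0.02 to 0.01 | 0.99 | 0.98 | ... |
| PM | right | -0.01 | -0.01 to 0.00 | 0.99 | 0.97 | ... |
```

Other subcommands (`simulate`, `segment`, `emg`, `kin`, `agree`, `report`)
expose each stage separately; see `wearagree --help`.

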