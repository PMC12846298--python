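"""Surface-EMG amplitude chain: counts → volts → envelope → normalized RMS.

The chain is applied identically to the wearable prototype and the reference
acquisition so that the final per-muscle statistic is comparable:

1. convert ADC counts to volts (midscale-referenced transfer function),
2. remove the mean offset,
3. full-wave rectify,
4. 1 s moving-average envelope (reflection-padded, centered),
5. split into the five annotated task cycles,
6. resample each cycle to a fixed 1700-point grid (mirror padding, central
   window),
7. normalize each cycle to [0, 1],
8. average the five normalized cycles pointwise,
9. take the RMS of the mean waveform.

Because of step 7 the final RMS is invariant to any positive affine rescaling
of the raw signal — the ADC constants are therefore configuration, not
results-relevant calibration. Per-repetition RMS values (RMS of each
normalized resampled cycle) are kept for intra-device reliability (ICC across
repetitions) and the coefficient of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ProcessingError, SchemaError
from .recordings import TimeSeriesRecording
from .segmentation import CycleAnnotation, split_cycles

__all__ = [
    "EMGConfig",
    "NormalizedCycleMatrix",
    "MuscleRMSRecord",
    "counts_to_volts",
    "remove_offset",
    "full_wave_rectify",
    "moving_average_envelope",
    "resample_mirror_central",
    "normalize_01",
    "mean_cycle",
    "rms",
    "run_emg_pipeline",
    "emg_rms_table",
]

TARGET_LEN = 1700


@dataclass
class EMGConfig:
    """ADC transfer function and envelope parameters.

    The defaults (12-bit converter, 3.3 V reference, amplifier gain 1000)
    describe a typical low-cost acquisition front end; per-cycle 0–1
    normalization makes the downstream RMS independent of these choices.
    """

    adc_bits: int = 12
    vref_volts: float = 3.3
    gain: float = 1000.0
    envelope_window_s: float = 1.0
    target_len: int = TARGET_LEN


@dataclass
class NormalizedCycleMatrix:
    """Per-cycle normalized waveforms on the fixed-length grid.

    ``values`` is cycles × target_len with every value in [0, 1]; each
    non-degenerate row attains both 0 and 1 by construction of the min–max
    normalization. ``degenerate`` flags constant cycles that were mapped to
    all-zeros.
    """

    values: np.ndarray
    muscle: str = ""
    side: str = ""
    system: str = ""
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("cycle matrix must be 2-D (cycles x points)")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape[0], dtype=bool)


@dataclass
class MuscleRMSRecord:
    """Headline and per-repetition RMS for one participant/side/muscle pair."""

    participant: str
    side: str
    muscle: str
    rms_device: float
    rms_reference: float
    per_repetition_device: np.ndarray
    per_repetition_reference: np.ndarray


def counts_to_volts(raw, adc_bits: int = 12, vref_volts: float = 3.3, gain: float = 1000.0):
    """Midscale-referenced ADC transfer: ``((raw/(2^bits−1)) − 0.5) · vref / gain``.

    Values outside the converter range raise a clipping warning and are
    clamped before conversion.
    """
    if adc_bits < 1:
        raise ProcessingError(f"adc_bits must be >= 1, got {adc_bits}")
    if vref_volts <= 0 or gain <= 0:
        raise ProcessingError("vref_volts and gain must be > 0")
    raw = np.asarray(raw, dtype=float)
    full_scale = 2**adc_bits - 1
    if np.any(raw < 0) or np.any(raw > full_scale):
        warnings.warn(
            f"{int(((raw < 0) | (raw > full_scale)).sum())} samples outside "
            f"[0, {full_scale}]: clipped",
            stacklevel=2,
        )
        raw = np.clip(raw, 0, full_scale)
    return (raw / full_scale - 0.5) * vref_volts / gain


def remove_offset(x):
    """Subtract the signal mean (output mean is 0 to numerical tolerance)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ProcessingError("cannot remove offset from an empty signal")
    return x - x.mean()


def full_wave_rectify(x):
    """Elementwise absolute value."""
    return np.abs(np.asarray(x, dtype=float))


def moving_average_envelope(x, window_s: float = 1.0, rate_hz: float = 1000.0):
    """Centered moving mean over ``round(window_s · rate_hz)`` samples.

    Edges are handled by reflecting the signal about its endpoints, which
    avoids the edge droop a zero-padded average would introduce into the
    per-cycle min/max used later for normalization. Output length equals
    input length.
    """
    x = np.asarray(x, dtype=float)
    win = round(window_s * rate_hz)
    if win < 1:
        raise ProcessingError(f"window of {window_s} s at {rate_hz} Hz spans < 1 sample")
    if win > x.size:
        raise ProcessingError(f"window ({win} samples) longer than signal ({x.size})")
    return uniform_filter1d(x, size=win, mode="reflect")


def resample_mirror_central(x, target_len: int = TARGET_LEN):
    """Resample a cycle to ``target_len`` points via mirror padding.

    The cycle is extended to ``[reverse(x), x, reverse(x)]``, linearly
    resampled to ``3 · target_len`` points, and the central block is
    returned. When ``len(x) == target_len`` this is exactly the identity.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ProcessingError(f"cycle of {x.size} samples cannot be resampled")
    xm = np.concatenate([x[::-1], x, x[::-1]])
    grid = np.linspace(0.0, xm.size - 1.0, 3 * target_len)
    ym = np.interp(grid, np.arange(xm.size), xm)
    return ym[target_len : 2 * target_len]


def normalize_01(cycle):
    """Min–max normalize to [0, 1]; returns ``(normalized, degenerate_flag)``.

    A constant cycle (max == min) is mapped to all zeros with the degenerate
    flag set.
    """
    x = np.asarray(cycle, dtype=float)
    if x.size == 0:
        raise ProcessingError("cannot normalize an empty cycle")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def mean_cycle(matrix):
    """Pointwise arithmetic mean of the normalized repetitions (rows)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise SchemaError("expected a 2-D cycles x points matrix")
    return m.mean(axis=0)


def rms(waveform) -> float:
    """Root mean square, ``sqrt(mean(x**2))``."""
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ProcessingError("cannot take RMS of an empty waveform")
    return float(np.sqrt(np.mean(x**2)))


def process_emg_channel(
    x,
    rate_hz: float,
    annotation: CycleAnnotation,
    config: EMGConfig | None = None,
    muscle: str = "",
    side: str = "",
    system: str = "",
    times: np.ndarray | None = None,
) -> NormalizedCycleMatrix:
    """Run the full per-channel chain and return the normalized cycle matrix."""
    cfg = config or EMGConfig()
    volts = counts_to_volts(x, cfg.adc_bits, cfg.vref_volts, cfg.gain)
    env = moving_average_envelope(
        full_wave_rectify(remove_offset(volts)), cfg.envelope_window_s, rate_hz
    )
    if times is None:
        times = np.arange(env.size) / rate_hz
    rec = TimeSeriesRecording(times=times, data={"env": env}, rate_hz=rate_hz)
    rows, flags = [], []
    for seg in split_cycles(rec, annotation):
        y, degenerate = normalize_01(
            resample_mirror_central(seg.channel("env"), cfg.target_len)
        )
        rows.append(y)
        flags.append(degenerate)
    return NormalizedCycleMatrix(
        values=np.vstack(rows),
        muscle=muscle,
        side=side,
        system=system,
        degenerate=np.array(flags),
    )


def run_emg_pipeline(
    recording: TimeSeriesRecording,
    annotation: CycleAnnotation,
    config: EMGConfig | None = None,
) -> dict[str, dict]:
    """Per-muscle headline RMS and per-repetition RMS for one recording.

    Returns ``{muscle: {"rms": float, "per_repetition": ndarray,
    "degenerate": ndarray, "matrix": NormalizedCycleMatrix}}``.
    """
    results: dict[str, dict] = {}
    for muscle in recording.channels:
        mat = process_emg_channel(
            recording.channel(muscle),
            recording.rate_hz,
            annotation,
            config,
            muscle=muscle,
            side=recording.side,
            times=recording.times,
        )
        results[muscle] = {
            "rms": rms(mean_cycle(mat.values)),
            "per_repetition": np.array([rms(row) for row in mat.values]),
            "degenerate": mat.degenerate,
            "matrix": mat,
        }
    return results


def emg_rms_table(
    device: TimeSeriesRecording,
    reference: TimeSeriesRecording,
    annotation: CycleAnnotation,
    config: EMGConfig | None = None,
    participant: str = "",
    side: str = "",
) -> list[MuscleRMSRecord]:
    """Run the chain on both systems and pair the results per muscle."""
    if device.channels != reference.channels:
        raise SchemaError(
            f"channel mismatch: device {device.channels} vs reference {reference.channels}"
        )
    side = side or device.side
    res_d = run_emg_pipeline(device, annotation, config)
    res_r = run_emg_pipeline(reference, annotation, config)
    return [
        MuscleRMSRecord(
            participant=participant,
            side=side,
            muscle=m,
            rms_device=res_d[m]["rms"],
            rms_reference=res_r[m]["rms"],
            per_repetition_device=res_d[m]["per_repetition"],
            per_repetition_reference=res_r[m]["per_repetition"],
        )
        for m in device.channels
    ]
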