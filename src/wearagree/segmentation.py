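"""Video-frame timing, synchronization-tap detection, trimming and cycle splits.

The experimental protocol is segmented from video recorded at 30 frames/s:
an operator notes the start and end frame of each task repetition, frames are
converted to seconds, and all streams (EMG at 1000 Hz, orientation at 100 Hz)
are trimmed and split on the shared time axis. A sharp tap on the sensor at
the start of each acquisition produces a transient used to co-register the
clocks of the different systems.

All windows are half-open ``[start, end)`` so that no sample is assigned to
two cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DetectionError, InsufficientDataError, RangeError, SchemaError
from .recordings import RotationTrajectory, TimeSeriesRecording

__all__ = [
    "CycleAnnotation",
    "frames_to_seconds",
    "detect_sync_event",
    "trim_to_task",
    "split_cycles",
    "cycle_duration_stats",
]


@dataclass
class CycleAnnotation:
    """Ordered, non-overlapping task-cycle intervals in seconds.

    ``fps`` records the video frame rate the times were derived from and
    ``source`` a free-form provenance label (file name, "synthetic", ...).
    """

    cycles: list[tuple[float, float]]
    fps: float = 30.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise SchemaError("fps must be > 0")
        cycles = [(float(a), float(b)) for a, b in self.cycles]
        for i, (a, b) in enumerate(cycles):
            if not a < b:
                raise SchemaError(f"cycle {i}: start {a} must be < end {b}")
        for i in range(1, len(cycles)):
            if cycles[i][0] < cycles[i - 1][1]:
                raise SchemaError(f"cycles {i - 1} and {i} overlap or are unsorted")
        self.cycles = cycles

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def task_span(self) -> tuple[float, float]:
        """Outer window from first cycle start to last cycle end."""
        if not self.cycles:
            raise InsufficientDataError("annotation has no cycles")
        return self.cycles[0][0], self.cycles[-1][1]

    def shifted(self, offset_s: float) -> "CycleAnnotation":
        return CycleAnnotation(
            cycles=[(a + offset_s, b + offset_s) for a, b in self.cycles],
            fps=self.fps,
            source=self.source,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "cycle": np.arange(1, len(self.cycles) + 1),
                "start_s": [a for a, _ in self.cycles],
                "end_s": [b for _, b in self.cycles],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float = 30.0, source: str = "") -> "CycleAnnotation":
        """Read an annotation CSV.

        Accepts either second-based columns (``start_s``, ``end_s``) or
        frame-based ones (``start_frame``, ``end_frame``) converted at ``fps``.
        """
        df = pd.read_csv(path)
        if {"start_s", "end_s"} <= set(df.columns):
            cycles = list(zip(df["start_s"].astype(float), df["end_s"].astype(float)))
        elif {"start_frame", "end_frame"} <= set(df.columns):
            cycles = [
                (frames_to_seconds(int(a), fps), frames_to_seconds(int(b), fps))
                for a, b in zip(df["start_frame"], df["end_frame"])
            ]
        else:
            raise SchemaError(f"{path}: need start_s/end_s or start_frame/end_frame")
        return cls(cycles=cycles, fps=fps, source=source or str(path))


def frames_to_seconds(frame_index: int, fps: float) -> float:
    """Convert a video frame index to seconds (``frame_index / fps``)."""
    if frame_index < 0:
        raise RangeError(f"frame index must be >= 0, got {frame_index}")
    if fps <= 0:
        raise SchemaError(f"fps must be > 0, got {fps}")
    return frame_index / fps


def detect_sync_event(
    recording: TimeSeriesRecording,
    channel: str,
    threshold_sd: float = 8.0,
    baseline_s: float = 0.5,
) -> float:
    """Locate the synchronization tap in ``channel``.

    The first ``baseline_s`` of the channel define a quiet baseline; the tap
    is the first post-baseline sample whose absolute deviation from the
    baseline mean exceeds ``threshold_sd`` baseline standard deviations. The
    returned time becomes t=0 for cross-system alignment.

    Raises
    ------
    DetectionError
        If no sample exceeds the threshold (missing tap).
    """
    x = recording.channel(channel)
    t0 = recording.times[0]
    base = x[recording.times < t0 + baseline_s]
    if base.size < 2:
        raise InsufficientDataError(
            f"baseline window {baseline_s} s holds {base.size} samples; need >= 2"
        )
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    post = recording.times >= t0 + baseline_s
    if not np.any(post):
        raise DetectionError("recording ends inside the baseline window")
    if threshold_sd == 0:
        return float(recording.times[post][0])
    dev = np.abs(x[post] - mu)
    hits = np.flatnonzero(dev > threshold_sd * sd)
    if hits.size == 0:
        raise DetectionError(
            f"no sample on {channel!r} exceeds {threshold_sd} baseline SDs: sync tap not found"
        )
    return float(recording.times[post][hits[0]])


def _window_mask(times: np.ndarray, dt: float, start_s: float, end_s: float):
    if not start_s < end_s:
        raise RangeError(f"window start {start_s} must be < end {end_s}")
    span_lo, span_hi = float(times[0]), float(times[-1]) + dt
    eps = 1e-9
    if start_s < span_lo - eps or end_s > span_hi + eps:
        raise RangeError(
            f"window [{start_s}, {end_s}) outside recording span [{span_lo}, {span_hi})"
        )
    return (times >= start_s - eps) & (times < end_s - eps)


def trim_to_task(rec, start_s: float, end_s: float):
    """Keep samples with ``start_s <= t < end_s`` and rebase time to zero.

    Works for both :class:`TimeSeriesRecording` and
    :class:`RotationTrajectory`. Trimming an already-trimmed object with its
    own span is the identity.
    """
    mask = _window_mask(rec.times, rec.dt, start_s, end_s)
    times = rec.times[mask] - start_s
    if isinstance(rec, RotationTrajectory):
        return rec.with_matrices(rec.matrices[mask], times=times)
    if isinstance(rec, TimeSeriesRecording):
        return rec.with_values(rec.data.loc[mask].reset_index(drop=True), times=times)
    raise SchemaError(f"cannot trim object of type {type(rec).__name__}")


def split_cycles(rec, annotation: CycleAnnotation) -> list:
    """One sub-recording per annotated cycle (half-open windows, time rebased).

    Raises :class:`RangeError` naming the offending cycle index if a cycle
    extends beyond the recording span.
    """
    out = []
    for i, (a, b) in enumerate(annotation.cycles):
        try:
            out.append(trim_to_task(rec, a, b))
        except RangeError as exc:
            raise RangeError(f"cycle {i}: {exc}") from exc
    return out


def cycle_duration_stats(annotation: CycleAnnotation) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n−1) of the cycle durations in seconds.

    A single cycle yields SD 0 with a warning; an empty annotation is an error.
    """
    if len(annotation) == 0:
        raise InsufficientDataError("annotation has no cycles")
    durations = np.array([b - a for a, b in annotation.cycles])
    if durations.size == 1:
        warnings.warn("single cycle: SD reported as 0", stacklevel=2)
        return float(durations[0]), 0.0
    return float(durations.mean()), float(durations.std(ddof=1))
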