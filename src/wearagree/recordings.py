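"""In-memory containers for multichannel time series and rotation trajectories.

Time, in seconds, is the interchange currency between the heterogeneous
streams (30 fps video annotations, 100 Hz orientation streams, 1000 Hz EMG).
A recording's span is the half-open interval ``[times[0], times[-1] + dt)``
where ``dt = 1 / rate_hz``; every windowing operation in the package uses
half-open ``[start, end)`` windows so no sample belongs to two segments.

CSV layouts (all plain text, header row first):

* time series — ``t`` column in seconds plus one column per channel;
* rotation trajectory — ``t`` plus ``r11..r33`` (row-major 3x3 per frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["TimeSeriesRecording", "RotationTrajectory"]

_MATRIX_COLS = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise SchemaError("times must be a non-empty 1-D array")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise SchemaError("times must be strictly increasing")
    return times


@dataclass
class TimeSeriesRecording:
    """Labeled multichannel samples at a fixed sampling rate.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    data
        One column per channel; row count must match ``times``.
    rate_hz
        Nominal sampling rate (samples/s), > 0.
    side
        Limb label (``"left"``/``"right"``) or empty.
    meta
        Free-form annotations (flags, provenance).
    """

    times: np.ndarray
    data: pd.DataFrame
    rate_hz: float
    side: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if len(self.data) != self.times.size:
            raise SchemaError(
                f"data has {len(self.data)} rows but times has {self.times.size}"
            )
        if self.rate_hz <= 0:
            raise SchemaError("rate_hz must be > 0")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def span(self) -> tuple[float, float]:
        """Half-open time span ``[t0, t_last + dt)`` covered by the samples."""
        return float(self.times[0]), float(self.times[-1]) + self.dt

    def channel(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise SchemaError(f"no channel {name!r}; have {self.channels}")
        return self.data[name].to_numpy()

    def with_values(self, data: pd.DataFrame, times: np.ndarray | None = None) -> "TimeSeriesRecording":
        return TimeSeriesRecording(
            times=self.times if times is None else times,
            data=data,
            rate_hz=self.rate_hz,
            side=self.side,
            meta=dict(self.meta),
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "t", self.times)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float | None = None, side: str = "") -> "TimeSeriesRecording":
        df = pd.read_csv(path)
        if "t" not in df.columns:
            raise SchemaError(f"{path}: missing required time column 't'")
        times = df.pop("t").to_numpy(dtype=float)
        if rate_hz is None:
            if times.size < 2:
                raise SchemaError(f"{path}: cannot infer rate from a single sample")
            rate_hz = 1.0 / float(np.median(np.diff(times)))
        return cls(times=times, data=df, rate_hz=rate_hz, side=side)


@dataclass
class RotationTrajectory:
    """Per-frame segment→laboratory rotation matrices.

    Every matrix must be orthonormal with determinant +1 (a proper rotation);
    ``validate`` enforces this within a tolerance.
    """

    times: np.ndarray
    matrices: np.ndarray
    rate_hz: float
    side: str = ""
    system: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.shape != (self.times.size, 3, 3):
            raise SchemaError(
                f"matrices shape {self.matrices.shape} != ({self.times.size}, 3, 3)"
            )
        if self.rate_hz <= 0:
            raise SchemaError("rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1]) + self.dt

    def validate(self, tol: float = 1e-6) -> None:
        """Raise :class:`SchemaError` if any frame is not a proper rotation."""
        eye = np.eye(3)
        gram = np.einsum("nij,nik->njk", self.matrices, self.matrices)
        err = np.abs(gram - eye).max()
        if err > tol:
            raise SchemaError(f"matrices deviate from orthonormality by {err:.2e}")
        dets = np.linalg.det(self.matrices)
        if np.any(dets < 0):
            raise SchemaError("improper rotation (negative determinant) in trajectory")

    def with_matrices(self, matrices: np.ndarray, times: np.ndarray | None = None) -> "RotationTrajectory":
        return RotationTrajectory(
            times=self.times if times is None else times,
            matrices=matrices,
            rate_hz=self.rate_hz,
            side=self.side,
            system=self.system,
            meta=dict(self.meta),
        )

    def to_csv(self, path: str | Path) -> None:
        flat = self.matrices.reshape(self.n_frames, 9)
        out = pd.DataFrame(flat, columns=_MATRIX_COLS)
        out.insert(0, "t", self.times)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float | None = None, side: str = "", system: str = "") -> "RotationTrajectory":
        df = pd.read_csv(path)
        missing = [c for c in ["t", *_MATRIX_COLS] if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        times = df["t"].to_numpy(dtype=float)
        mats = df[_MATRIX_COLS].to_numpy(dtype=float).reshape(-1, 3, 3)
        if rate_hz is None:
            if times.size < 2:
                raise SchemaError(f"{path}: cannot infer rate from a single frame")
            rate_hz = 1.0 / float(np.median(np.diff(times)))
        return cls(times=times, matrices=mats, rate_hz=rate_hz, side=side, system=system)
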