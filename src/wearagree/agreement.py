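"""Method-comparison statistics: Bland–Altman, Pearson, ICC(2,1), CV.

Conventions, fixed once for the whole package:

* differences are ``device − reference`` (prototype minus gold standard), so
  a positive bias means the prototype overestimates;
* 95% limits of agreement use the 1.96 normal multiplier and are therefore
  exactly symmetric about the bias;
* every sample standard deviation uses the n−1 denominator;
* ICC(2,1) is the two-way random-effects, absolute-agreement, single-measures
  intraclass correlation:

      ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

  with MSR/MSC/MSE the row (subject), column (rater) and residual mean
  squares of the two-way ANOVA decomposition;
* the coefficient of variation is computed per subject over its repetitions
  (100·SD/mean) and aggregated across subjects by arithmetic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError, SchemaError

__all__ = [
    "BlandAltman",
    "PairedMeasureTable",
    "bland_altman",
    "pearson_r",
    "icc_2_1",
    "intra_device_icc",
    "cv_percent",
    "build_agreement_table",
    "bland_altman_plot_data",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float


@dataclass
class PairedMeasureTable:
    """Paired per-target values from the device and the reference system.

    ``summary`` has one row per participant × side × target with columns
    ``participant, side, target, device, reference`` (the headline value:
    RMS of the mean normalized cycle, or mean-of-cycles ROM).
    ``repetitions`` is long-format with columns
    ``participant, side, target, system, repetition, value`` and exactly five
    repetitions per system. ``kind`` labels the measure ("emg_rms" or
    "rom_deg").
    """

    summary: pd.DataFrame
    repetitions: pd.DataFrame
    kind: str = ""

    def __post_init__(self) -> None:
        need = {"participant", "side", "target", "device", "reference"}
        if not need <= set(self.summary.columns):
            raise SchemaError(f"summary missing columns {need - set(self.summary.columns)}")
        need = {"participant", "side", "target", "system", "repetition", "value"}
        if not need <= set(self.repetitions.columns):
            raise SchemaError(
                f"repetitions missing columns {need - set(self.repetitions.columns)}"
            )
        if self.summary[["device", "reference"]].isna().any().any():
            raise SchemaError("half-missing pairs may not enter the statistics")


def bland_altman(device, reference) -> BlandAltman:
    """Bias and 95% limits of agreement of ``device − reference``."""
    d = np.asarray(device, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape:
        raise SchemaError(f"length mismatch: {d.shape} vs {r.shape}")
    if d.size < 2:
        raise InsufficientDataError("Bland–Altman needs at least 2 pairs")
    diff = d - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(bias, sd, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd)


def pearson_r(x, y) -> float:
    """Product-moment correlation; undefined when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SchemaError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InsufficientDataError("Pearson correlation needs at least 3 pairs")
    xd, yd = x - x.mean(), y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0 or sy == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    return float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))


def icc_2_1(matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``matrix`` is subjects × raters (complete, no missing cells).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise SchemaError("ICC input must be a 2-D subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(f"ICC needs >= 2 subjects and >= 2 raters, got {n}x{k}")
    if np.isnan(m).any():
        raise SchemaError("ICC input must be complete (no missing cells)")
    grand = m.mean()
    if np.allclose(m, grand):
        raise DegenerateDataError("ICC undefined: zero total variance")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def intra_device_icc(per_repetition) -> float:
    """ICC(2,1) with task repetitions as the rater dimension."""
    return icc_2_1(per_repetition)


def cv_percent(per_repetition) -> float:
    """Mean across subjects of the per-subject CV, in percent.

    Each subject's CV is ``100 · SD(repetitions, n−1) / mean(repetitions)``;
    subjects with zero mean are excluded with a warning.
    """
    m = np.asarray(per_repetition, dtype=float)
    if m.ndim != 2:
        raise SchemaError("CV input must be a 2-D subjects x repetitions matrix")
    means = m.mean(axis=1)
    keep = means != 0
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} subject(s) with zero mean excluded from CV",
            stacklevel=2,
        )
    if not np.any(keep):
        raise DegenerateDataError("all subjects have zero mean: CV undefined")
    cvs = 100.0 * m[keep].std(axis=1, ddof=1) / means[keep]
    return float(np.abs(cvs).mean())


def _rep_matrix(reps: pd.DataFrame, system: str) -> np.ndarray:
    sub = reps[reps["system"] == system]
    pivot = sub.pivot_table(
        index="participant", columns="repetition", values="value", sort=True
    )
    return pivot.to_numpy()


def build_agreement_table(paired: PairedMeasureTable) -> pd.DataFrame:
    """One agreement row per target × limb (the report-table schema).

    Columns: target, limb, n, bias, loa_lower, loa_upper, pearson_r,
    icc_between, icc_intra_device, icc_intra_reference, cv_device_pct,
    cv_reference_pct. Values are unrounded; rounding happens only at report
    rendering. Targets with fewer than 3 complete pairs are skipped with a
    warning.
    """
    rows = []
    targets = paired.summary["target"].unique()
    for side in paired.summary["side"].unique():
        for target in targets:
            cell = paired.summary[
                (paired.summary["side"] == side) & (paired.summary["target"] == target)
            ].sort_values("participant")
            if len(cell) < 3:
                warnings.warn(
                    f"target {target}/{side}: only {len(cell)} pairs, skipped",
                    stacklevel=2,
                )
                continue
            dev = cell["device"].to_numpy()
            ref = cell["reference"].to_numpy()
            ba = bland_altman(dev, ref)
            reps = paired.repetitions[
                (paired.repetitions["side"] == side)
                & (paired.repetitions["target"] == target)
            ]
            rep_d = _rep_matrix(reps, "device")
            rep_r = _rep_matrix(reps, "reference")
            rows.append(
                {
                    "target": target,
                    "limb": side,
                    "n": len(cell),
                    "bias": ba.bias,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                    "pearson_r": pearson_r(dev, ref),
                    "icc_between": icc_2_1(np.column_stack([dev, ref])),
                    "icc_intra_device": intra_device_icc(rep_d),
                    "icc_intra_reference": intra_device_icc(rep_r),
                    "cv_device_pct": cv_percent(rep_d),
                    "cv_reference_pct": cv_percent(rep_r),
                }
            )
    return pd.DataFrame(rows)


def bland_altman_plot_data(device, reference):
    """Per-pair (mean, difference) points plus the bias/LOA reference lines.

    Returns ``(points, lines)`` where ``points`` is a DataFrame with columns
    ``mean`` and ``difference`` and ``lines`` is a dict with keys ``bias``,
    ``loa_lower``, ``loa_upper`` — a table any plotting layer can consume.
    """
    d = np.asarray(device, dtype=float)
    r = np.asarray(reference, dtype=float)
    ba = bland_altman(d, r)
    points = pd.DataFrame({"mean": (d + r) / 2.0, "difference": d - r})
    lines = {"bias": ba.bias, "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper}
    return points, lines
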