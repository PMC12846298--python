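"""End-to-end orchestration: simulate a cohort, run both pipelines, report.

``run_full_validation`` reproduces the whole validation study on synthetic
data: per participant it draws one EMG-session timeline and one
kinematics-session timeline, simulates both limbs, runs the EMG amplitude
chain and the kinematics ROM chain, and assembles the two agreement tables
(muscle × limb for EMG, axis × limb for ROM) plus Bland–Altman plot points.
A run manifest (config snapshot, seed, package version, SHA-256 digests of
every output, warnings) makes runs reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agreement import PairedMeasureTable, bland_altman_plot_data, build_agreement_table
from .emg import EMGConfig, emg_rms_table
from .kinematics import KinematicsConfig, run_kinematics_pipeline
from .synthetic import (
    SimulationConfig,
    generate_emg_pair,
    generate_kinematics_pair,
    generate_timeline,
)

__all__ = [
    "simulate_cohort_tables",
    "run_full_validation",
    "render_report",
    "load_config",
    "save_config",
]

SIDES = ("left", "right")


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML/JSON simulation config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return SimulationConfig.from_dict(data or {})


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def simulate_cohort_tables(
    config: SimulationConfig,
    seed: int | None = None,
    emg_config: EMGConfig | None = None,
    kin_config: KinematicsConfig | None = None,
) -> tuple[PairedMeasureTable, PairedMeasureTable, dict]:
    """Simulate the cohort and run both pipelines per participant/side.

    Returns the EMG and ROM paired tables plus a truth dict keyed by
    ``(participant, side)`` with the generator's ground truth for each
    modality.
    """
    seed = config.seed if seed is None else seed
    emg_sum, emg_rep, rom_sum, rom_rep = [], [], [], []
    truths: dict = {}
    for p in range(config.n_participants):
        # the two protocol repetitions (EMG session, kinematics session) get
        # distinct timelines, like the study's two acquisition passes
        tl_emg = generate_timeline(config, seed=seed * 1000 + 2 * p)
        tl_kin = generate_timeline(config, seed=seed * 1000 + 2 * p + 1)
        pid = f"P{p + 1:02d}"
        for side in SIDES:
            dev, ref, t_emg = generate_emg_pair(tl_emg, config, seed=seed, participant=p, side=side)
            for rec in emg_rms_table(dev, ref, tl_emg, emg_config, participant=pid, side=side):
                emg_sum.append(
                    {
                        "participant": pid,
                        "side": side,
                        "target": rec.muscle,
                        "device": rec.rms_device,
                        "reference": rec.rms_reference,
                    }
                )
                for sysname, reps in (
                    ("device", rec.per_repetition_device),
                    ("reference", rec.per_repetition_reference),
                ):
                    for j, v in enumerate(reps, start=1):
                        emg_rep.append(
                            {
                                "participant": pid,
                                "side": side,
                                "target": rec.muscle,
                                "system": sysname,
                                "repetition": j,
                                "value": float(v),
                            }
                        )
            imu, cam, t_kin = generate_kinematics_pair(
                tl_kin, config, seed=seed, participant=p, side=side
            )
            for rec in run_kinematics_pipeline(imu, cam, tl_kin, kin_config, participant=pid):
                rom_sum.append(
                    {
                        "participant": pid,
                        "side": side,
                        "target": rec.axis,
                        "device": rec.rom_device_deg,
                        "reference": rec.rom_reference_deg,
                    }
                )
                for sysname, reps in (
                    ("device", rec.per_cycle_device),
                    ("reference", rec.per_cycle_reference),
                ):
                    for j, v in enumerate(reps, start=1):
                        rom_rep.append(
                            {
                                "participant": pid,
                                "side": side,
                                "target": rec.axis,
                                "system": sysname,
                                "repetition": j,
                                "value": float(v),
                            }
                        )
            truths[(pid, side)] = {"emg": t_emg, "kinematics": t_kin}
    emg_table = PairedMeasureTable(
        summary=pd.DataFrame(emg_sum), repetitions=pd.DataFrame(emg_rep), kind="emg_rms"
    )
    rom_table = PairedMeasureTable(
        summary=pd.DataFrame(rom_sum), repetitions=pd.DataFrame(rom_rep), kind="rom_deg"
    )
    return emg_table, rom_table, truths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_validation(
    config: SimulationConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run the whole synthetic validation and write results + manifest.

    Outputs in ``outdir``: ``agreement_emg.csv``, ``agreement_rom.csv``,
    ``bland_altman_points_emg.csv``, ``bland_altman_points_rom.csv``,
    ``config.yaml`` and ``manifest.json``.
    """
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        emg_table, rom_table, _ = simulate_cohort_tables(config, seed=seed)
        agr_emg = build_agreement_table(emg_table)
        agr_rom = build_agreement_table(rom_table)
        caught = [str(w.message) for w in wlist]

    agr_emg.to_csv(outdir / "agreement_emg.csv", index=False)
    agr_rom.to_csv(outdir / "agreement_rom.csv", index=False)
    for name, table in (("emg", emg_table), ("rom", rom_table)):
        pts = []
        for (side, target), cell in table.summary.groupby(["side", "target"], sort=True):
            p, lines = bland_altman_plot_data(cell["device"], cell["reference"])
            p.insert(0, "target", target)
            p.insert(1, "limb", side)
            for k, v in lines.items():
                p[k] = v
            pts.append(p)
        pd.concat(pts, ignore_index=True).to_csv(
            outdir / f"bland_altman_points_{name}.csv", index=False
        )
    save_config(config, outdir / "config.yaml")

    files = sorted(f for f in outdir.iterdir() if f.suffix in (".csv", ".yaml"))
    manifest = {
        "package": "wearagree",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "outputs": {f.name: _sha256(f) for f in files},
        "warnings": caught,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


_EMG_ORDER = ["PM", "AD", "MD", "PD", "UT", "LT"]


def _format_table(df: pd.DataFrame, title: str) -> str:
    cols = [
        ("target", "Target"),
        ("limb", "Limb"),
        ("bias", "Bias"),
        ("loa", "LOA (Lower–Upper)"),
        ("pearson_r", "Pearson r"),
        ("icc_between", "ICC (between)"),
        ("icc_intra_device", "ICC (device)"),
        ("cv_device_pct", "CV% (device)"),
        ("cv_reference_pct", "CV% (reference)"),
    ]
    df = df.copy()
    df["loa"] = [
        f"{lo:.2f} to {hi:.2f}" for lo, hi in zip(df["loa_lower"], df["loa_upper"])
    ]
    lines = [f"## {title}", ""]
    lines.append("| " + " | ".join(h for _, h in cols) + " |")
    lines.append("|" + "|".join("---" for _ in cols) + "|")
    for _, row in df.iterrows():
        cells = []
        for key, _ in cols:
            v = row[key]
            cells.append(f"{v:.2f}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)


def render_report(results_dir: str | Path) -> Path:
    """Render the two agreement tables as a markdown report (2-decimal rounding).

    Rounding happens only here; the CSVs keep full precision.
    """
    results_dir = Path(results_dir)
    for name in ("agreement_emg.csv", "agreement_rom.csv", "manifest.json"):
        if not (results_dir / name).exists():
            raise FileNotFoundError(f"missing results file: {results_dir / name}")
    manifest = json.loads((results_dir / "manifest.json").read_text())
    emg = pd.read_csv(results_dir / "agreement_emg.csv")
    emg["_ord"] = emg["target"].map({m: i for i, m in enumerate(_EMG_ORDER)})
    emg = emg.sort_values(["_ord", "limb"]).drop(columns="_ord")
    rom = pd.read_csv(results_dir / "agreement_rom.csv").sort_values(["limb", "target"])
    parts = [
        "# Synthetic validation report",
        "",
        f"Seed: {manifest['seed']}  |  wearagree {manifest['version']}",
        "",
        _format_table(emg, "EMG amplitude agreement (normalized RMS, device vs reference)"),
        _format_table(rom, "Shoulder ROM agreement (degrees, IMU vs camera)"),
    ]
    out = results_dir / "report.md"
    out.write_text("\n".join(parts))
    return out
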