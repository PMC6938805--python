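"""CSV and plot emission for a simulation run.

A run writes its tables at the top of the output directory and its figures
into four fixed folders — ``plots_PEC`` and ``plots_ETR`` for per-event
concentration and risk courses, ``plots_All`` for the combined mixture-risk
figure (all events plus the ETRmix line), and ``plots_TER`` for the
TERmix-versus-threshold figure on a logarithmic ordinate with a dotted
threshold line.  CSV values are written at full floating precision (the
shortest round-tripping decimal form), never rounded: the exponential decay
tail is meaningful down to arbitrarily small magnitudes.  Outputs are
deterministic — a rerun with identical inputs overwrites byte-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .data_tables import Dialect  # noqa: E402
from .engine import ConcentrationMatrix  # noqa: E402
from .errors import SprayRiskError  # noqa: E402
from .risk import RiskCourse  # noqa: E402

PLOT_FOLDERS = ("plots_PEC", "plots_ETR", "plots_All", "plots_TER")
_SVG_META = {"Date": None}  # keep SVG output time-independent


@dataclass
class RunOutputs:
    """Paths produced by :func:`write_outputs`."""

    outdir: Path
    pec_table: Path
    etr_tables: dict[str, Path] = field(default_factory=dict)
    ter_tables: dict[str, Path] = field(default_factory=dict)
    plot_files: list[Path] = field(default_factory=list)
    report: Path | None = None
    run_log: Path | None = None


def _fmt(x: float) -> str:
    if np.isinf(x):
        return "inf"
    return repr(float(x))


def _write_csv(path: Path, days: np.ndarray, columns: list[tuple[str, np.ndarray]],
               dialect: Dialect) -> None:
    header = ["days"] + [name for name, _ in columns]
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        fh.write(dialect.delimiter.join(header) + "\n")
        for i, day in enumerate(days):
            row = [str(int(day))] + [_fmt(series[i]) for _, series in columns]
            fh.write(dialect.delimiter.join(row) + "\n")


def _save(fig: plt.Figure, stem: Path, outputs: RunOutputs) -> None:
    for ext in ("png", "svg"):
        target = stem.with_suffix(f".{ext}")
        fig.savefig(target, metadata=_SVG_META if ext == "svg" else None)
        outputs.plot_files.append(target)
    plt.close(fig)


def _check_writable(outdir: Path) -> None:
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise SprayRiskError(f"output directory {outdir} is not writable: {exc}") from exc


def write_outputs(
    matrix: ConcentrationMatrix,
    risks: Mapping[str, RiskCourse],
    outdir: str | Path,
    *,
    description: str = "run",
    dialect: Dialect | None = None,
    make_plots: bool = True,
    run_log: Mapping | None = None,
) -> RunOutputs:
    """Write the PEC/ETR/TER tables, plots, exceedance report and run log.

    ``risks`` maps endpoint kind ("acute"/"chronic") to its risk course; any
    subset may be supplied.  Writability is probed before the first file is
    touched so a failure never leaves a partial run behind.
    """
    dialect = dialect or Dialect()
    outdir = Path(outdir)
    _check_writable(outdir)
    for folder in PLOT_FOLDERS:
        (outdir / folder).mkdir(exist_ok=True)
    safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in description) or "run"

    outputs = RunOutputs(outdir=outdir, pec_table=outdir / "pec_table.csv")
    event_cols = list(zip(matrix.labels, matrix.values.T))
    _write_csv(outputs.pec_table, matrix.days,
               event_cols + [("cumulative", matrix.cumulative)], dialect)

    lines = [f"simulation: {description}", f"days simulated: {len(matrix.days)}",
             f"applications: {len(matrix.events)}"]
    for kind, rc in risks.items():
        etr_path = outdir / f"etr_table_{kind}.csv"
        ter_path = outdir / f"ter_table_{kind}.csv"
        _write_csv(etr_path, rc.days,
                   list(zip(rc.labels, rc.per_event_etr.T)) + [("ETRmix", rc.etr_mix)],
                   dialect)
        _write_csv(ter_path, rc.days,
                   list(zip(rc.labels, rc.per_event_ter.T)) + [("TERmix", rc.ter_mix)],
                   dialect)
        outputs.etr_tables[kind] = etr_path
        outputs.ter_tables[kind] = ter_path
        lines.append(f"[{kind}] TER threshold: {rc.threshold}")
        if rc.exceedance_intervals:
            ivals = ", ".join(f"[{a}, {b}]" for a, b in rc.exceedance_intervals)
            lines.append(
                f"[{kind}] TERmix below threshold from day {rc.first_exceedance_day} "
                f"({rc.days_below} day(s) below; intervals: {ivals})"
            )
        else:
            lines.append(f"[{kind}] no exceedance")

    report = outdir / "exceedance_report.txt"
    report.write_text("\n".join(lines) + "\n", encoding=dialect.encoding)
    outputs.report = report

    if run_log is not None:
        log_path = outdir / "run_log.json"
        log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n",
                            encoding=dialect.encoding)
        outputs.run_log = log_path

    if make_plots:
        _make_plots(matrix, risks, outdir, safe, outputs)
    return outputs


def _make_plots(matrix: ConcentrationMatrix, risks: Mapping[str, RiskCourse],
                outdir: Path, safe: str, outputs: RunOutputs) -> None:
    plt.rcParams["svg.hashsalt"] = safe
    days = matrix.days

    for i, label in enumerate(matrix.labels):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.plot(days, matrix.values[:, i], color="tab:blue")
        ax.set_xlabel("day")
        ax.set_ylabel("PEC [mg a.i./kg dw]")
        ax.set_title(f"{label} (application {i + 1})")
        fig.tight_layout()
        _save(fig, outdir / "plots_PEC" / f"{safe}_PEC_{i + 1}_{label}", outputs)

    for kind, rc in risks.items():
        for i, label in enumerate(rc.labels):
            fig, ax = plt.subplots(figsize=(6, 3.5))
            ax.plot(days, rc.per_event_etr[:, i], color="tab:orange")
            ax.set_xlabel("day")
            ax.set_ylabel(f"ETR ({kind})")
            ax.set_title(f"{label} (application {i + 1})")
            fig.tight_layout()
            _save(fig, outdir / "plots_ETR" / f"{safe}_ETR_{kind}_{i + 1}_{label}", outputs)

        fig, ax = plt.subplots(figsize=(7, 4))
        for i, label in enumerate(rc.labels):
            ax.plot(days, rc.per_event_etr[:, i], lw=0.9, label=f"{label} #{i + 1}")
        ax.plot(days, rc.etr_mix, color="red", lw=1.6, label="ETRmix")
        ax.set_xlabel("day")
        ax.set_ylabel(f"ETR ({kind})")
        ax.legend(fontsize=7)
        fig.tight_layout()
        _save(fig, outdir / "plots_All" / f"{safe}_All_{kind}", outputs)

        fig, ax = plt.subplots(figsize=(7, 4))
        finite = np.where(np.isinf(rc.ter_mix), np.nan, rc.ter_mix)
        ax.plot(days, finite, color="tab:green", label="TERmix")
        ax.axhline(rc.threshold, color="black", linestyle=":", label=f"threshold = {rc.threshold}")
        ax.set_yscale("log")
        ax.set_xlabel("day")
        ax.set_ylabel(f"TERmix ({kind})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        _save(fig, outdir / "plots_TER" / f"{safe}_TER_{kind}", outputs)


def read_result_table(path: str | Path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read an emitted result CSV back (values positional, full precision)."""
    dialect = dialect or Dialect()
    return pd.read_csv(path, sep=dialect.delimiter, encoding=dialect.encoding,
                       float_precision="round_trip")
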