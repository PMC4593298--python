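"""Concentration-sweep studies: control pace, drug paces, summary export.

A study paces the chosen cell model to steady state drug-free (the control),
then for each test concentration converts the compound's potency data into
per-channel block factors, scales the conductances, re-paces to steady
state (warm-started from the control steady state) and reports APD90 and
its percent change from control, together with any abnormality messages.
Results export to CSV: a summary table, one voltage trace per
concentration, and a metadata file echoing every input.
"""

from __future__ import annotations

import argparse
import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from .cellmodels import CellModelDefinition, apply_block, available_models, get_model
from .doseresponse import (
    ChannelBlockSpec,
    ChannelId,
    CompoundSpec,
    BlockFactors,
    block_factors,
)
from .engine import PacingProtocol, SolverFailure, Trace, pace_to_steady

__all__ = [
    "ConcentrationRange",
    "StudyRow",
    "StudyResult",
    "concentration_grid",
    "run_study",
    "export_csv",
    "load_config",
    "main",
]

logger = logging.getLogger("apblock")

# Exported plot/trace files are down-sampled to this step for readability;
# biomarkers are always computed on the full-resolution grid.
TRACE_EXPORT_STEP_MS = 1.0


@dataclass(frozen=True)
class ConcentrationRange:
    """A test-concentration grid in µM; control (0 µM) is always prepended."""

    low: float
    high: float
    count: int
    log_spaced: bool = True

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.high < self.low:
            raise ValueError("high must be >= low")
        if self.log_spaced and self.low <= 0:
            raise ValueError(
                f"log-spaced range requires low > 0 µM, got {self.low}"
            )
        if self.low < 0:
            raise ValueError("concentrations must be >= 0")


def concentration_grid(conc_range: ConcentrationRange) -> np.ndarray:
    """[0] followed by ``count`` values from low to high, log10- or linearly
    spaced; endpoints exact."""
    r = conc_range
    if r.count == 1:
        vals = np.array([r.low])
    elif r.log_spaced:
        vals = np.logspace(np.log10(r.low), np.log10(r.high), r.count)
        vals[0], vals[-1] = r.low, r.high
    else:
        vals = np.linspace(r.low, r.high, r.count)
        vals[0], vals[-1] = r.low, r.high
    return np.concatenate(([0.0], vals))


@dataclass(frozen=True)
class StudyRow:
    """One concentration's outcome."""

    conc: float  # µM
    factors: BlockFactors
    biomarkers: Optional[bm.Biomarkers]
    delta_apd90_pct: Optional[float]
    messages: tuple[bm.AbnormalityMessage, ...]
    converged: bool
    paces_run: int
    trace: Optional[Trace] = None
    error: Optional[str] = None


@dataclass(frozen=True)
class StudyResult:
    """Control row followed by one row per test concentration, ascending."""

    metadata: dict
    rows: tuple[StudyRow, ...]

    @property
    def control(self) -> StudyRow:
        return self.rows[0]


def run_study(
    model_name: str,
    compound: CompoundSpec,
    conc_range: ConcentrationRange,
    protocol: Optional[PacingProtocol] = None,
    frequency: float = 1.0,
) -> StudyResult:
    """Run the full control + concentration-sweep pipeline.

    The control (0 µM) paces to steady state from the model's default
    initial state; each test concentration warm-starts from the control's
    converged state.  A solver failure on one concentration is recorded in
    that row; the remaining concentrations still run.
    """
    model = get_model(model_name)
    if protocol is None:
        protocol = PacingProtocol.for_model(model, frequency=frequency)
    concs = concentration_grid(conc_range)
    logger.info(
        "study: model=%s compound=%s freq=%g Hz, %d concentrations",
        model_name, compound.name, protocol.frequency, len(concs) - 1,
    )

    rows: list[StudyRow] = []
    control_apd90: Optional[float] = None
    control_state = None
    for conc in concs:
        factors = block_factors(compound, float(conc))
        params = apply_block(model, model.default_parameters, factors)
        start = (model.default_initial_state if control_state is None
                 else control_state)
        try:
            ss = pace_to_steady(model, params, protocol, start)
        except SolverFailure as exc:
            logger.warning("solver failure at %g µM: %s", conc, exc)
            rows.append(StudyRow(
                conc=float(conc), factors=factors, biomarkers=None,
                delta_apd90_pct=None, messages=(), converged=False,
                paces_run=exc.pace or 0, trace=None, error=str(exc),
            ))
            continue

        marks = bm.compute_biomarkers(ss.final_trace)
        prev_marks = (bm.compute_biomarkers(ss.previous_trace)
                      if ss.previous_trace is not None else None)
        messages = tuple(bm.detect_abnormalities(marks, prev_marks,
                                                 ss.final_trace))
        if any(m.code is bm.AbnormalityCode.REPOLARISATION_FAILURE
               for m in messages):
            # a failed repolarisation has no meaningful APD90; report the
            # message instead of a number
            marks = dataclasses.replace(marks, apd90=None, apd50=None)
        if conc == 0.0:
            control_apd90 = marks.apd90
            control_state = ss.end_state
            delta: Optional[float] = 0.0 if marks.apd90 is not None else None
        elif control_apd90 is not None and marks.apd90 is not None:
            delta = 100.0 * (marks.apd90 - control_apd90) / control_apd90
        else:
            delta = None
        logger.info(
            "conc %g µM: %d paces, converged=%s, APD90=%s ms, dAPD90=%s%%",
            conc, ss.paces_run, ss.converged,
            f"{marks.apd90:.2f}" if marks.apd90 is not None else "absent",
            f"{delta:.2f}" if delta is not None else "absent",
        )
        rows.append(StudyRow(
            conc=float(conc), factors=factors, biomarkers=marks,
            delta_apd90_pct=delta, messages=messages,
            converged=ss.converged, paces_run=ss.paces_run,
            trace=ss.final_trace,
        ))

    metadata = {
        "model": model_name,
        "compound": {
            "name": compound.name,
            "blocks": [
                {"channel": str(b.channel), "pic50": b.pic50, "hill": b.hill}
                for b in compound.blocks
            ],
        },
        "pacing": {
            "frequency_hz": protocol.frequency,
            "stim_amplitude": protocol.stim_amplitude,
            "stim_duration_ms": protocol.stim_duration,
            "stim_offset_ms": protocol.stim_offset,
            "abs_tol": protocol.abs_tol,
            "rel_tol": protocol.rel_tol,
            "output_step_ms": protocol.output_step,
            "max_paces": protocol.resolved_max_paces,
            "steady_norm_tol": protocol.steady_norm_tol,
        },
        "concentrations_uM": [float(c) for c in concs],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "software_version": _version(),
    }
    return StudyResult(metadata=metadata, rows=tuple(rows))


def _version() -> str:
    from . import __version__

    return __version__


def _fmt(x: Optional[float]) -> Optional[float]:
    return None if x is None else float(x)


def summary_frame(result: StudyResult) -> pd.DataFrame:
    """The summary table as a DataFrame (one row per concentration)."""
    records = []
    for row in result.rows:
        rec: dict = {"conc_uM": row.conc}
        for ch in ChannelId:
            rec[f"factor_{ch.value}"] = row.factors[ch]
        marks = row.biomarkers
        rec.update(
            apd90_ms=_fmt(marks.apd90) if marks else None,
            apd50_ms=_fmt(marks.apd50) if marks else None,
            peak_mV=_fmt(marks.peak_v) if marks else None,
            rest_mV=_fmt(marks.rest_v) if marks else None,
            dvdt_max_mV_per_ms=_fmt(marks.dvdt_max) if marks else None,
            delta_apd90_pct=_fmt(row.delta_apd90_pct),
            converged=row.converged,
            paces_run=row.paces_run,
            messages="; ".join(str(m) for m in row.messages) or (
                row.error or ""),
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def export_csv(result: StudyResult, directory: str | Path) -> list[Path]:
    """Write summary.csv, per-concentration trace CSVs and metadata.json.

    Deterministic given the result.  Fails before any partial writes if the
    directory cannot be created or written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    probe = directory / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {directory} is not writable") from exc

    written: list[Path] = []
    summary = directory / "summary.csv"
    summary_frame(result).to_csv(summary, index=False, float_format="%.6g",
                                 lineterminator="\n")
    written.append(summary)

    for i, row in enumerate(result.rows):
        if row.trace is None:
            continue
        path = directory / f"trace_{i:02d}_{row.conc:g}uM.csv"
        tr = row.trace.downsample(TRACE_EXPORT_STEP_MS)
        pd.DataFrame({"time_ms": tr.times, "V_mV": tr.voltages}).to_csv(
            path, index=False, float_format="%.6g", lineterminator="\n")
        written.append(path)

    meta = directory / "metadata.json"
    meta.write_text(json.dumps(result.metadata, indent=2) + "\n")
    written.append(meta)
    return written


def plot_summary(result: StudyResult, path: str | Path) -> Path:
    """Summary figure: dAPD90% vs concentration plus overlaid steady APs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    test = [r for r in result.rows if r.conc > 0]
    concs = [r.conc for r in test if r.delta_apd90_pct is not None]
    deltas = [r.delta_apd90_pct for r in test if r.delta_apd90_pct is not None]
    ax1.semilogx(concs, deltas, "o-")
    ax1.set_xlabel("concentration (µM)")
    ax1.set_ylabel("ΔAPD90 (%)")
    ax1.axhline(0, color="grey", lw=0.5)
    for r in result.rows:
        if r.trace is not None:
            tr = r.trace.downsample(TRACE_EXPORT_STEP_MS)
            ax2.plot(tr.times, tr.voltages, label=f"{r.conc:g} µM")
    ax2.set_xlabel("time (ms)")
    ax2.set_ylabel("V (mV)")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Config-file and command-line front end
# ---------------------------------------------------------------------------

_CLI_CHANNELS = {
    "herg": ChannelId.IKr,
    "cal": ChannelId.ICaL,
    "na": ChannelId.INa,
    "iks": ChannelId.IKs,
    "ik1": ChannelId.IK1,
    "ito": ChannelId.Ito,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML config file with the same keys as the CLI flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def compound_from_config(cfg: dict) -> CompoundSpec:
    """Build a CompoundSpec from the ``compound:`` section of a config."""
    comp = cfg.get("compound", {}) or {}
    name = comp.get("name", "compound")
    blocks = []
    for channel_name, entry in (comp.get("channels", {}) or {}).items():
        channel = ChannelId.parse(channel_name)
        entry = entry or {}
        hill = float(entry.get("hill", 1.0))
        if "pic50" in entry:
            blocks.append(ChannelBlockSpec(channel, float(entry["pic50"]), hill))
        elif "ic50_uM" in entry:
            blocks.append(ChannelBlockSpec.from_ic50(
                channel, float(entry["ic50_uM"]), hill))
        else:
            raise ValueError(
                f"channel {channel_name}: need 'pic50' or 'ic50_uM'")
    return CompoundSpec(name=name, blocks=tuple(blocks))


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="apblock",
        description="Predict drug-induced action potential changes by "
                    "multi-channel conductance block.",
    )
    p.add_argument("--model", default="sixcurrent_demo",
                   help="cell model name (see --list-models)")
    p.add_argument("--list-models", action="store_true",
                   help="print available cell models and exit")
    p.add_argument("--pacing-freq", type=float, default=1.0, metavar="HZ",
                   help="pacing frequency in Hz (default 1)")
    for key in _CLI_CHANNELS:
        p.add_argument(f"--pic50-{key}", type=float, metavar="PIC50",
                       help=f"pIC50 against {_CLI_CHANNELS[key].value}")
        p.add_argument(f"--ic50-{key}", type=float, metavar="UM",
                       help=f"IC50 in µM against {_CLI_CHANNELS[key].value}")
        p.add_argument(f"--hill-{key}", type=float, metavar="H",
                       help=f"Hill coefficient for {_CLI_CHANNELS[key].value} "
                            "(default 1)")
    p.add_argument("--plasma-conc-low", type=float, default=0.1, metavar="UM",
                   help="lowest test concentration in µM (default 0.1)")
    p.add_argument("--plasma-conc-high", type=float, default=100.0,
                   metavar="UM", help="highest test concentration in µM "
                   "(default 100)")
    p.add_argument("--plasma-conc-count", type=int, default=5, metavar="N",
                   help="number of test concentrations (default 5)")
    p.add_argument("--plasma-conc-spacing", choices=["log", "linear"],
                   default="log", help="grid spacing (default log)")
    p.add_argument("--compound-name", default="compound")
    p.add_argument("--config", metavar="FILE",
                   help="YAML config file; CLI flags override it")
    p.add_argument("--output", default="apblock_output", metavar="DIR",
                   help="output directory for CSV export")
    p.add_argument("--plot", action="store_true",
                   help="also write summary.png")
    p.add_argument("--max-paces", type=int, default=None)
    p.add_argument("-v", "--verbose", action="count", default=0)
    return p


def _compound_from_args(args: argparse.Namespace) -> CompoundSpec:
    blocks = []
    for key, channel in _CLI_CHANNELS.items():
        pic50 = getattr(args, f"pic50_{key}")
        ic50 = getattr(args, f"ic50_{key}")
        hill = getattr(args, f"hill_{key}")
        if pic50 is not None and ic50 is not None:
            raise ValueError(
                f"give either --pic50-{key} or --ic50-{key}, not both")
        if pic50 is None and ic50 is None:
            if hill is not None:
                raise ValueError(
                    f"--hill-{key} given without a potency for {channel}")
            continue
        hill = 1.0 if hill is None else hill
        if pic50 is not None:
            blocks.append(ChannelBlockSpec(channel, pic50, hill))
        else:
            blocks.append(ChannelBlockSpec.from_ic50(channel, ic50, hill))
    return CompoundSpec(name=args.compound_name, blocks=tuple(blocks))


def main(cli_args: Optional[Sequence[str]] = None) -> int:
    """Entry point: parse flags, run the study, export CSVs.

    Returns 0 on success, 2 on usage errors, 1 on runtime failures.
    """
    parser = build_parser()
    try:
        args = parser.parse_args(cli_args)
    except SystemExit as exc:  # argparse exits on --help or bad flags
        return int(exc.code or 0)

    logging.basicConfig(
        level=logging.DEBUG if args.verbose > 1
        else logging.INFO if args.verbose else logging.WARNING,
        format="%(asctime)s %(levelname)s %(message)s",
    )

    if args.list_models:
        for name in available_models():
            print(name)
        return 0

    try:
        cfg = load_config(args.config) if args.config else {}
        compound = _compound_from_args(args)
        if not compound.blocks and cfg:
            compound = compound_from_config(cfg)
        model_name = cfg.get("model", args.model)
        freq = float(cfg.get("pacing_frequency_hz", args.pacing_freq))
        conc_cfg = cfg.get("concentrations", {}) or {}
        conc_range = ConcentrationRange(
            low=float(conc_cfg.get("low_uM", args.plasma_conc_low)),
            high=float(conc_cfg.get("high_uM", args.plasma_conc_high)),
            count=int(conc_cfg.get("count", args.plasma_conc_count)),
            log_spaced=(conc_cfg.get("spacing", args.plasma_conc_spacing)
                        == "log"),
        )
        model = get_model(model_name)
        protocol = PacingProtocol.for_model(model, frequency=freq,
                                            max_paces=args.max_paces)
    except (ValueError, KeyError, OSError) as exc:
        msg = exc.args[0] if isinstance(exc, KeyError) and exc.args else exc
        print(f"error: {msg}", flush=True)
        return 2

    try:
        result = run_study(model_name, compound, conc_range, protocol)
        outdir = Path(cfg.get("output", args.output))
        export_csv(result, outdir)
        if args.plot:
            plot_summary(result, outdir / "summary.png")
    except (SolverFailure, OSError) as exc:
        print(f"error: {exc}", flush=True)
        return 1
    print(f"wrote results to {outdir}")
    return 0
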