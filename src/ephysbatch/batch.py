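"""Folder-level batch analysis: tables, plots, logs, error isolation.

The driver processes every recording in a manifest, in deterministic
(lexicographic) order, and guarantees three isolation contracts:

* a recording that fails to read or analyse is skipped, logged as Error, and
  excluded from every output table — the rest of the batch is unaffected;
* a failure while producing one table or plot blocks only that output;
* a failure affecting every recording yields no outputs at all.

Outputs are XLSX workbooks (one sheet per recording for the firing and
passive tables, a single sheet for the overview) plus a mirrored
CSV-per-sheet export for diff-able downstream use, PNG plots named
``<recording>_<plot-kind>.png``, and a plain-text run log.  Missing values
are written as empty cells, never 0 or a sentinel.  Numeric cells carry full
double precision; rounding is left to the consumer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError
from .io import BatchManifest, read_recording
from .passive import NeuronOverview, SweepPassiveFeatures, neuron_overview, passive_sweep_features
from .recording import (AnalysisConfig, ProtocolWindow, Recording,
                        infer_step_amplitude, steady_membrane_voltage)
from .spikes import WAVEFORM_FEATURES, SweepFiringFeatures, detect_spikes, firing_features

__all__ = [
    "FIRING_PROPERTIES",
    "PASSIVE_PROPERTIES",
    "OVERVIEW_PROPERTIES",
    "AP_GROUPS",
    "RunReport",
    "RecordingResult",
    "analyze_recording",
    "build_firing_table",
    "build_passive_table",
    "build_overview_table",
    "render_plots",
    "run_batch",
    "validate_properties",
]

log = logging.getLogger("ephysbatch")

DEFAULT_OUTPUT_FOLDER = "analysis_output"
DEFAULT_FIRING_NAME = "firing_properties"
DEFAULT_PASSIVE_NAME = "passive_membrane_properties"
DEFAULT_OVERVIEW_NAME = "neuron_overview"

#: the 24 selectable firing-table base properties, in sheet order
FIRING_PROPERTIES: tuple[str, ...] = (
    "Sweep", "Current step", "Steady membrane voltage",
    "N of spikes", "Latency", "Frequency", "First ISI", "Mean ISI", "ISI CV",
    "AP amplitude", "AP peak", "AP width", "AP half width", "AP threshold",
    "AP peak upstroke", "AP peak downstroke",
    "AP rise/fall rate", "AP rise/fall time",
    "AHP abs depth", "AHP time from peak", "AHP depth from threshold",
    "Amplitude AP1/APL", "Peak AP1/APL", "Half width AP1/APL",
)

#: the 10 selectable passive-table properties (Sweep is the row index)
PASSIVE_PROPERTIES: tuple[str, ...] = (
    "Current step", "Steady membrane voltage", "Voltage base",
    "Time constant", "Input resistance", "Capacitance", "Decay time constant",
    "Sag amplitude", "Sag ratio", "Sag time constant",
)

#: the 22 selectable overview properties (recording name is the row index)
OVERVIEW_PROPERTIES: tuple[str, ...] = (
    "Resting membrane potential", "Sag amplitude", "Sag ratio",
    "Membrane input resistance", "Membrane time constant",
    "Membrane capacitance", "Rheobase",
    "AP1 latency", "AP1 amplitude", "AP1 peak", "AP1 width", "AP1 half width",
    "AP1 threshold", "AP1 peak upstroke", "AP1 peak downstroke",
    "AP1 rise rate", "AP1 fall rate", "AP1 rise time", "AP1 fall time",
    "AP1 AHP abs depth", "AP1 AHP time from peak", "AP1 AHP depth from threshold",
)

#: single-AP column groups for waveform features
AP_GROUPS: tuple[str, ...] = ("Average AP", "AP1", "AP2", "APsL", "APL")

#: base properties that expand into per-feature x per-AP-group columns;
#: maps base property -> canonical waveform feature names
_WAVEFORM_EXPANSION: dict[str, tuple[str, ...]] = {
    **{name: (name,) for name in WAVEFORM_FEATURES
       if name not in ("AP rise rate", "AP fall rate", "AP rise time", "AP fall time")},
    "AP rise/fall rate": ("AP rise rate", "AP fall rate"),
    "AP rise/fall time": ("AP rise time", "AP fall time"),
}


def validate_properties(names, table: str) -> set[str]:
    """Check a property selection against the canonical list for one table."""
    canonical = {"firing": FIRING_PROPERTIES, "passive": PASSIVE_PROPERTIES,
                 "overview": OVERVIEW_PROPERTIES}[table]
    names = set(names)
    unknown = names - set(canonical)
    if unknown:
        raise ConfigError(
            f"unknown {table} properties {sorted(unknown)}; "
            f"valid names: {list(canonical)}")
    return names


@dataclass
class RecordingResult:
    """Per-recording analysis results, keyed by sweep index."""

    recording: Recording
    firing: dict[int, SweepFiringFeatures]
    passive: dict[int, SweepPassiveFeatures]
    overview: NeuronOverview


@dataclass
class RunReport:
    """Outcome of one batch run: per-recording and per-output status plus logs."""

    recording_status: dict[str, str] = field(default_factory=dict)  # ok | skipped: reason
    output_status: dict[str, str] = field(default_factory=dict)  # written | blocked: reason
    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (level, recording, msg)

    @property
    def skipped(self) -> list[str]:
        return [n for n, s in self.recording_status.items() if s != "ok"]

    @property
    def exit_code(self) -> int:
        """0 = clean, 1 = some recordings skipped, 2 = total failure."""
        if not self.recording_status or not any(
                s == "ok" for s in self.recording_status.values()):
            return 2
        return 1 if self.skipped else 0

    def add(self, level: str, recording: str, message: str) -> None:
        self.entries.append((level, recording, message))


class _CaptureHandler(logging.Handler):
    """Routes library log records into the RunReport with recording context."""

    def __init__(self, report: RunReport):
        super().__init__(level=logging.DEBUG)
        self.report = report
        self.current_recording = ""

    def emit(self, record: logging.LogRecord) -> None:
        level = {"DEBUG": "Info", "INFO": "Info", "WARNING": "Warning"}.get(
            record.levelname, "Error")
        self.report.add(level, self.current_recording, record.getMessage())


def analyze_recording(recording: Recording, config: AnalysisConfig) -> RecordingResult:
    """Run the full per-sweep and overview analysis on one recording.

    Every sweep lands in exactly one of the firing (>= 1 AP) or passive
    (0 APs) result sets.
    """
    window = config.window
    firing: dict[int, SweepFiringFeatures] = {}
    passive: dict[int, SweepPassiveFeatures] = {}
    for sweep in recording:
        infer_step_amplitude(sweep, window)
        spikes = detect_spikes(sweep, window, config.dvdt_threshold,
                               config.min_peak_voltage)
        if spikes:
            steady = steady_membrane_voltage(sweep, window)
            firing[sweep.index] = firing_features(
                spikes, window, sweep_index=sweep.index,
                step_amplitude=sweep.step_amplitude, steady_voltage=steady)
        else:
            passive[sweep.index] = passive_sweep_features(sweep, window)
    overview = neuron_overview(recording, window, firing, passive)
    return RecordingResult(recording=recording, firing=firing,
                           passive=passive, overview=overview)


def _firing_columns(selected: set[str]) -> list[str]:
    cols: list[str] = []
    for prop in FIRING_PROPERTIES:
        if prop not in selected:
            continue
        if prop in _WAVEFORM_EXPANSION:
            for feat in _WAVEFORM_EXPANSION[prop]:
                cols.extend(f"{feat} ({grp})" for grp in AP_GROUPS)
        else:
            cols.append(prop)
    return cols


def build_firing_table(results: dict[str, RecordingResult],
                       selected: set[str] | None = None) -> dict[str, pd.DataFrame]:
    """One DataFrame per recording: a row per sweep with >= 1 AP.

    Waveform base properties expand into Average AP / AP1 / AP2 / APsL / APL
    column groups.  A recording with no spiking sweep contributes an empty
    sheet (with a Warning).
    """
    selected = validate_properties(selected or FIRING_PROPERTIES, "firing")
    columns = _firing_columns(selected)
    sheets: dict[str, pd.DataFrame] = {}
    for name, res in results.items():
        rows = []
        for idx in sorted(res.firing):
            f = res.firing[idx]
            scalar = {
                "Sweep": f.sweep_index,
                "Current step": f.step_amplitude,
                "Steady membrane voltage": f.steady_voltage,
                "N of spikes": f.n_spikes,
                "Latency": f.latency,
                "Frequency": f.frequency,
                "First ISI": f.first_isi,
                "Mean ISI": f.mean_isi,
                "ISI CV": f.isi_cv,
                "Amplitude AP1/APL": f.amplitude_ap1_apl,
                "Peak AP1/APL": f.peak_ap1_apl,
                "Half width AP1/APL": f.halfwidth_ap1_apl,
            }
            groups = {"Average AP": f.average_ap, "AP1": f.ap1, "AP2": f.ap2,
                      "APsL": f.aps_l, "APL": f.ap_l}
            row = {}
            for col in columns:
                if col in scalar:
                    row[col] = scalar[col]
                else:
                    feat, grp = col.rsplit(" (", 1)
                    row[col] = groups[grp[:-1]].get(feat, math.nan)
            rows.append(row)
        if not rows:
            log.warning("%s: no sweep with an action potential; empty firing sheet", name)
        sheets[name] = pd.DataFrame(rows, columns=columns)
    return sheets


def build_passive_table(results: dict[str, RecordingResult],
                        selected: set[str] | None = None) -> dict[str, pd.DataFrame]:
    """One DataFrame per recording: a row per spike-free sweep (Sweep = index)."""
    selected = validate_properties(selected or PASSIVE_PROPERTIES, "passive")
    columns = [p for p in PASSIVE_PROPERTIES if p in selected]
    sheets: dict[str, pd.DataFrame] = {}
    for name, res in results.items():
        rows, index = [], []
        for idx in sorted(res.passive):
            p = res.passive[idx]
            values = {
                "Current step": p.step_amplitude,
                "Steady membrane voltage": p.steady_voltage,
                "Voltage base": p.voltage_base,
                "Time constant": p.time_constant,
                "Input resistance": p.input_resistance,
                "Capacitance": p.capacitance,
                "Decay time constant": p.decay_time_constant,
                "Sag amplitude": p.sag_amplitude,
                "Sag ratio": p.sag_ratio,
                "Sag time constant": p.sag_time_constant,
            }
            rows.append({c: values[c] for c in columns})
            index.append(idx)
        if not rows:
            log.warning("%s: no spike-free sweep; empty passive sheet", name)
        df = pd.DataFrame(rows, columns=columns,
                          index=pd.Index(index, name="Sweep"))
        sheets[name] = df
    return sheets


def build_overview_table(results: dict[str, RecordingResult],
                         selected: set[str] | None = None) -> pd.DataFrame:
    """Single sheet: one row per recording, recording name first."""
    selected = validate_properties(selected or OVERVIEW_PROPERTIES, "overview")
    columns = [p for p in OVERVIEW_PROPERTIES if p in selected]
    rows, index = [], []
    for name, res in results.items():
        ov = res.overview
        values = {
            "Resting membrane potential": ov.resting_membrane_potential,
            "Sag amplitude": ov.sag_amplitude,
            "Sag ratio": ov.sag_ratio,
            "Membrane input resistance": ov.membrane_input_resistance,
            "Membrane time constant": ov.membrane_time_constant,
            "Membrane capacitance": ov.membrane_capacitance,
            "Rheobase": ov.rheobase,
            **{k: math.nan for k in OVERVIEW_PROPERTIES if k.startswith("AP1")},
            **ov.ap1,
        }
        rows.append({c: values[c] for c in columns})
        index.append(name)
    return pd.DataFrame(rows, columns=columns,
                        index=pd.Index(index, name="Recording"))


def _write_workbook(sheets: dict[str, pd.DataFrame], path: Path,
                    index: bool) -> None:
    """XLSX workbook plus a CSV mirror directory next to it."""
    csv_dir = path.with_suffix("")
    csv_dir = csv_dir.parent / (csv_dir.name + "_csv")
    csv_dir.mkdir(parents=True, exist_ok=True)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, df in sheets.items():
            df.to_excel(writer, sheet_name=name[:31], index=index)
            df.to_csv(csv_dir / f"{name}.csv", index=index)


def render_plots(result: RecordingResult, window: ProtocolWindow,
                 selections: set[str], out_dir: Path) -> dict[str, Path]:
    """Write up to four PNGs for one recording; returns kind -> path.

    Sweeps share one color map across the protocol and recording plots so a
    current trace can be matched to its voltage response.  The regression
    line on the current-voltage plot reuses the overview membrane input
    resistance — the annotated slope and the table value are the same number.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    rec = result.recording
    n = len(rec)
    cmap = matplotlib.colormaps["viridis"]
    colors = [cmap(i / max(n - 1, 1)) for i in range(n)]
    written: dict[str, Path] = {}

    def save(fig, kind: str) -> None:
        path = out_dir / f"{rec.name}_{kind}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written[kind] = path

    if "protocol" in selections:
        fig, ax = plt.subplots(figsize=(6, 4))
        for sw, c in zip(rec, colors):
            ax.plot(sw.time, sw.current, color=c, lw=0.8)
        ax.set(xlabel="Time (ms)", ylabel="Current (pA)",
               title=f"{rec.name} — protocol")
        save(fig, "protocol")

    if "recording" in selections:
        fig, ax = plt.subplots(figsize=(6, 4))
        for sw, c in zip(rec, colors):
            ax.plot(sw.time, sw.voltage, color=c, lw=0.6)
        ax.set(xlabel="Time (ms)", ylabel="Voltage (mV)",
               title=f"{rec.name} — recording")
        save(fig, "recording")

    if "firing_current" in selections:
        fig, ax = plt.subplots(figsize=(5, 4))
        amps = [f.step_amplitude for f in result.firing.values()]
        freqs = [f.frequency for f in result.firing.values()]
        ax.plot(amps, freqs, "o-", color="tab:blue")
        ax.set(xlabel="Current step (pA)", ylabel="Firing frequency (Hz)",
               title=f"{rec.name} — firing/current")
        save(fig, "firing_current")

    if "current_voltage" in selections:
        fig, ax = plt.subplots(figsize=(5, 4))
        amps = np.array([p.step_amplitude for p in result.passive.values()])
        steadies = np.array([p.steady_voltage for p in result.passive.values()])
        ax.plot(amps, steadies, "o", color="tab:orange")
        slope = result.overview.membrane_input_resistance
        if np.isfinite(slope) and amps.size >= 2:
            intercept = steadies.mean() - slope * amps.mean()
            xs = np.linspace(amps.min(), amps.max(), 50)
            ax.plot(xs, intercept + slope * xs, "-", color="black",
                    label=f"Rin = {slope:.4f} GΩ")
            ax.legend()
        ax.set(xlabel="Current step (pA)", ylabel="Steady voltage (mV)",
               title=f"{rec.name} — current/voltage")
        save(fig, "current_voltage")
    return written


def run_batch(manifest: BatchManifest, config: AnalysisConfig) -> RunReport:
    """Analyse every recording in a manifest and write the selected outputs.

    The output folder is created inside the input folder (standard name
    when none is configured).  Identical inputs produce identical outputs:
    the pipeline has no stochastic element.
    """
    report = RunReport()
    capture = _CaptureHandler(report)
    log.addHandler(capture)
    log.setLevel(logging.DEBUG)
    out_dir = Path(manifest.folder) / (config.output_folder_name or DEFAULT_OUTPUT_FOLDER)
    try:
        results: dict[str, RecordingResult] = {}
        ref_duration: float | None = None
        for name, path in manifest.recordings:
            capture.current_recording = name
            try:
                rec = read_recording(path, config.recording_channel,
                                     config.protocol_channel)
                if ref_duration is None:
                    ref_duration = rec.duration
                elif abs(rec.duration - ref_duration) > 1e-6 * ref_duration:
                    raise AnalysisError(
                        f"sweep duration {rec.duration:g} ms differs from the "
                        f"batch duration {ref_duration:g} ms")
                results[name] = analyze_recording(rec, config)
                report.recording_status[name] = "ok"
                log.info("analysed %s (%d sweeps)", name, len(rec))
            except Exception as exc:
                report.recording_status[name] = f"skipped: {exc}"
                log.error("skipping %s: %s", name, exc)
        capture.current_recording = ""

        if not results:
            log.error("no recording could be analysed; no outputs produced")
            for kind in sorted(config.tables) + sorted(config.plots):
                report.output_status[kind] = "blocked: no analysable recordings"
            return report

        out_dir.mkdir(parents=True, exist_ok=True)
        table_jobs = {
            "firing": (build_firing_table, config.selected_firing,
                       config.firing_table_name or DEFAULT_FIRING_NAME, False),
            "passive": (build_passive_table, config.selected_passive,
                        config.passive_table_name or DEFAULT_PASSIVE_NAME, True),
            "overview": (build_overview_table, config.selected_overview,
                         config.overview_table_name or DEFAULT_OVERVIEW_NAME, True),
        }
        for kind in ("firing", "passive", "overview"):
            if kind not in config.tables:
                continue
            builder, selection, fname, with_index = table_jobs[kind]
            try:
                built = builder(results, selection)
                sheets = built if isinstance(built, dict) else {"Overview": built}
                _write_workbook(sheets, out_dir / f"{fname}.xlsx", index=with_index)
                report.output_status[kind] = "written"
                log.info("wrote %s.xlsx", fname)
            except Exception as exc:
                report.output_status[kind] = f"blocked: {exc}"
                log.error("%s table blocked: %s", kind, exc)

        for name, res in results.items():
            capture.current_recording = name
            for kind in sorted(config.plots):
                try:
                    render_plots(res, config.window, {kind}, out_dir)
                    report.output_status[f"{name}:{kind}"] = "written"
                except Exception as exc:
                    report.output_status[f"{name}:{kind}"] = f"blocked: {exc}"
                    log.error("plot %s for %s blocked: %s", kind, name, exc)
        capture.current_recording = ""
        return report
    finally:
        log.removeHandler(capture)
        if out_dir.is_dir():
            stamp = datetime.now().isoformat(timespec="seconds")
            lines = [f"{stamp} | {lvl} | {rec or '-'} | {msg}"
                     for lvl, rec, msg in report.entries]
            (out_dir / "run_log.txt").write_text("\n".join(lines) + "\n",
                                                 encoding="utf-8")
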