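"""Reading recordings from disk and enumerating batch folders.

Two on-disk formats are supported:

* Axon Binary Format (``.abf``, versions 1 and 2) via the optional ``pyabf``
  dependency (install the ``abf`` extra).
* A neutral tab-separated sweep table (``.tsv``): UTF-8, header line
  ``sweep<TAB>time_ms<TAB>voltage_mV<TAB>current_pA``, one row per sample,
  sweeps contiguous from 0.  This dialect lets the whole pipeline run and be
  tested without binary fixtures, and is what the simulator writes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelError, ConfigError, FormatError
from .recording import Recording, Sweep

__all__ = [
    "BatchManifest",
    "read_abf",
    "read_delimited",
    "write_delimited",
    "read_recording",
    "scan_folder",
    "SUPPORTED_EXTENSIONS",
]

log = logging.getLogger("ephysbatch")

DELIMITED_HEADER = ["sweep", "time_ms", "voltage_mV", "current_pA"]
SUPPORTED_EXTENSIONS = (".abf", ".tsv")


@dataclass(frozen=True)
class BatchManifest:
    """Deterministic (lexicographic) listing of the recordings in a folder."""

    folder: str
    recordings: tuple[tuple[str, str], ...]  # (name, path) pairs

    def __post_init__(self) -> None:
        names = [n for n, _ in self.recordings]
        if len(set(names)) != len(names):
            raise FormatError("recording names within a batch must be unique")

    def __len__(self) -> int:
        return len(self.recordings)


def read_abf(path: str, recording_channel: int = 0, protocol_channel: int = 1) -> Recording:
    """Read a multi-sweep ABF file into a :class:`Recording`.

    Voltage comes from ``recording_channel``, current from
    ``protocol_channel``; the sampling interval is taken from the file
    header.  Channel units are trusted only for scaling to mV/pA; if units
    are absent the values are assumed already in mV/pA and a Warning is
    logged.
    """
    if recording_channel == protocol_channel:
        raise ConfigError("recording and protocol channels must differ")
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise FormatError(
            f"cannot read {path!r}: ABF support requires the optional "
            "'pyabf' package (pip install ephysbatch[abf])"
        ) from exc
    p = Path(path)
    try:
        abf = pyabf.ABF(str(p))
    except Exception as exc:
        raise FormatError(f"cannot parse {p.name} as ABF: {exc}") from exc
    n_ch = abf.channelCount
    for ch in (recording_channel, protocol_channel):
        if ch >= n_ch:
            raise ChannelError(f"{p.name}: channel {ch} requested but file has {n_ch} channel(s)")

    def _scale(ch: int, kind: str) -> float:
        unit = (abf.adcUnits[ch] or "").strip()
        table = {"voltage": {"mV": 1.0, "V": 1000.0}, "current": {"pA": 1.0, "nA": 1000.0}}[kind]
        if unit in table:
            return table[unit]
        log.warning("%s: channel %d has units %r; assuming %s already scaled",
                    p.name, ch, unit, "mV" if kind == "voltage" else "pA")
        return 1.0

    v_scale = _scale(recording_channel, "voltage")
    i_scale = _scale(protocol_channel, "current")
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i, channel=recording_channel)
        time = abf.sweepX * 1000.0  # s -> ms
        volt = abf.sweepY * v_scale
        abf.setSweep(i, channel=protocol_channel)
        curr = abf.sweepY * i_scale
        sweeps.append(Sweep(index=i, time=time, voltage=volt, current=curr))
    return Recording(name=p.stem, sweeps=sweeps, sampling_interval=1000.0 / abf.sampleRate)


def read_delimited(path: str) -> Recording:
    """Read the neutral tab-separated sweep-table format."""
    p = Path(path)
    try:
        df = pd.read_csv(p, sep="\t", header=0, dtype=float,
                         names=None, engine="c")
    except Exception as exc:
        raise FormatError(f"cannot parse {p.name}: {exc}") from exc
    if list(df.columns) != DELIMITED_HEADER:
        raise FormatError(
            f"{p.name}: expected header {DELIMITED_HEADER}, got {list(df.columns)}")
    if df.isna().any().any():
        raise FormatError(f"{p.name}: ragged or non-numeric rows")
    sweeps = []
    for idx, grp in df.groupby("sweep", sort=True):
        if int(idx) != len(sweeps):
            raise FormatError(f"{p.name}: sweep indices not contiguous from 0")
        try:
            sweeps.append(Sweep(index=int(idx),
                                time=grp["time_ms"].to_numpy(),
                                voltage=grp["voltage_mV"].to_numpy(),
                                current=grp["current_pA"].to_numpy()))
        except ValueError as exc:
            raise FormatError(f"{p.name}: sweep {int(idx)}: {exc}") from exc
    if not sweeps:
        raise FormatError(f"{p.name}: no sweeps")
    try:
        return Recording(name=p.stem, sweeps=sweeps,
                         sampling_interval=sweeps[0].sampling_interval)
    except ValueError as exc:
        raise FormatError(f"{p.name}: {exc}") from exc


def write_delimited(recording: Recording, path: str) -> None:
    """Write a recording in the neutral tab-separated dialect (lossless to ~1e-9)."""
    frames = []
    for sw in recording:
        frames.append(pd.DataFrame({
            "sweep": sw.index,
            "time_ms": sw.time,
            "voltage_mV": sw.voltage,
            "current_pA": sw.current,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_recording(path: str, recording_channel: int = 0, protocol_channel: int = 1) -> Recording:
    """Dispatch on file extension to the right reader."""
    ext = Path(path).suffix.lower()
    if ext == ".abf":
        return read_abf(path, recording_channel, protocol_channel)
    if ext == ".tsv":
        return read_delimited(path)
    raise FormatError(f"unsupported recording format: {path!r}")


def scan_folder(folder: str) -> BatchManifest:
    """Enumerate supported recording files, lexicographically by name.

    Non-recording files are ignored (with a Warning for stray text files that
    look like data).  An empty folder yields an empty manifest and a Warning,
    not an error.
    """
    p = Path(folder)
    if not p.is_dir():
        raise FormatError(f"input folder does not exist: {folder!r}")
    entries = []
    for child in sorted(p.iterdir(), key=lambda c: c.name):
        if not child.is_file():
            continue
        if child.suffix.lower() in SUPPORTED_EXTENSIONS:
            entries.append((child.stem, str(child)))
        elif child.suffix.lower() in (".txt", ".csv", ".dat"):
            log.warning("ignoring non-recording file %s", child.name)
    if not entries:
        log.warning("no supported recordings found in %s", folder)
    return BatchManifest(folder=str(p), recordings=tuple(entries))
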