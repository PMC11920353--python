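"""Core data types for current-clamp sweeps and the window-mean primitives.

Units are fixed throughout the package: time in ms, voltage in mV, current in
pA.  With these units resistance comes out in mV/pA = GOhm and capacitance in
ms/GOhm = pF with no conversion factors.

Windows are half-open ``[a, b)`` on *time*: a sample exactly at the window end
belongs to the next segment, which avoids double-counting the stimulus edge
sample.  "Last 10%" segments are defined on time, not on sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BaseUndefinedError, ConfigError, WindowError

__all__ = [
    "Sweep",
    "Recording",
    "ProtocolWindow",
    "AnalysisConfig",
    "steady_membrane_voltage",
    "voltage_base",
    "infer_step_amplitude",
]

#: relative tolerance for "uniformly sampled" and for window-edge comparisons
_REL_TOL = 1e-6


@dataclass
class Sweep:
    """One stimulus episode: time base plus voltage and current traces.

    Parameters
    ----------
    index : int
        0-based sweep number within the recording.
    time : ndarray, ms
        Strictly increasing, uniformly spaced sample times.
    voltage : ndarray, mV
        Membrane voltage from the recording channel.
    current : ndarray, pA
        Injected current from the protocol channel.
    step_amplitude : float, pA
        Baseline-subtracted amplitude of the current step; filled in by
        :func:`infer_step_amplitude`.
    """

    index: int
    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    step_amplitude: float = float("nan")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValueError("a sweep needs at least 2 samples")
        if self.voltage.size != n or self.current.size != n:
            raise ValueError("time, voltage and current must have equal length")
        dt = np.diff(self.time)
        if dt.min() <= 0:
            raise ValueError("time must be strictly increasing")
        if (dt.max() - dt.min()) > _REL_TOL * dt.mean():
            raise ValueError("time must be uniformly spaced")

    @property
    def sampling_interval(self) -> float:
        """Sample spacing in ms."""
        return float((self.time[-1] - self.time[0]) / (self.time.size - 1))

    @property
    def duration(self) -> float:
        """Time covered by the sweep in ms (first sample to one past the last)."""
        return float(self.time[-1] - self.time[0] + self.sampling_interval)


@dataclass
class Recording:
    """A named, ordered collection of sweeps sharing one sampling rate."""

    name: str
    sweeps: list[Sweep]
    sampling_interval: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("recording name must be non-empty")
        if not self.sweeps:
            raise ValueError("recording must contain at least one sweep")
        for i, sw in enumerate(self.sweeps):
            if sw.index != i:
                raise ValueError("sweep indices must be contiguous from 0")
            if abs(sw.sampling_interval - self.sampling_interval) > _REL_TOL * self.sampling_interval:
                raise ValueError("all sweeps must share the recording sampling interval")
        n0 = self.sweeps[0].time.size
        if any(sw.time.size != n0 for sw in self.sweeps):
            raise ValueError("all sweeps must share the same duration")

    @property
    def duration(self) -> float:
        return self.sweeps[0].duration

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


@dataclass(frozen=True)
class ProtocolWindow:
    """The stimulus epoch: current-step start and end, ms from sweep start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    @property
    def duration(self) -> float:
        return self.end - self.start


#: canonical plot kinds
PLOT_KINDS = ("protocol", "recording", "firing_current", "current_voltage")


@dataclass
class AnalysisConfig:
    """Everything the batch driver needs to analyse a folder.

    ``selected_*`` sets of ``None`` mean "all canonical properties".  Blank
    output names fall back to the standard names at run time.
    """

    window: ProtocolWindow
    recording_channel: int = 0
    protocol_channel: int = 1
    selected_firing: set[str] | None = None
    selected_passive: set[str] | None = None
    selected_overview: set[str] | None = None
    tables: set[str] = field(default_factory=lambda: {"firing", "passive", "overview"})
    plots: set[str] = field(default_factory=lambda: set(PLOT_KINDS))
    output_folder_name: str = ""
    firing_table_name: str = ""
    passive_table_name: str = ""
    overview_table_name: str = ""
    dvdt_threshold: float = 10.0  # mV/ms; AP detection criterion
    min_peak_voltage: float = -20.0  # mV; minimum acceptable AP peak

    def __post_init__(self) -> None:
        if self.recording_channel < 0 or self.protocol_channel < 0:
            raise ConfigError("channel indices must be >= 0")
        if self.recording_channel == self.protocol_channel:
            raise ConfigError("recording and protocol channels must differ")
        if self.dvdt_threshold <= 0:
            raise ConfigError("dvdt_threshold must be positive")
        unknown = self.plots - set(PLOT_KINDS)
        if unknown:
            raise ConfigError(f"unknown plot kinds: {sorted(unknown)}")
        unknown = self.tables - {"firing", "passive", "overview"}
        if unknown:
            raise ConfigError(f"unknown tables: {sorted(unknown)}")


def _window_mask(time: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of samples with time in the half-open interval [lo, hi).

    A tolerance of 1e-6 sample intervals absorbs floating-point jitter in
    time bases built by accumulation, without ever moving a sample across an
    on-grid window edge.
    """
    dt = time[1] - time[0]
    tol = _REL_TOL * dt
    return (time >= lo - tol) & (time < hi - tol)


def _check_window(sweep: Sweep, window: ProtocolWindow) -> None:
    t0 = float(sweep.time[0])
    if window.start < t0 - _REL_TOL or window.end > sweep.duration + t0 + _REL_TOL:
        raise WindowError(
            f"window [{window.start}, {window.end}] ms outside sweep "
            f"[{t0}, {t0 + sweep.duration}] ms"
        )


def steady_membrane_voltage(sweep: Sweep, window: ProtocolWindow) -> float:
    """Mean voltage over the last 10% of the current-injection duration.

    The averaging segment is ``[end - 0.1*(end-start), end)``, half-open at
    the window end.
    """
    _check_window(sweep, window)
    lo = window.end - 0.1 * window.duration
    mask = _window_mask(sweep.time, lo, window.end)
    if not mask.any():
        raise WindowError("no samples in the steady-state segment")
    return float(sweep.voltage[mask].mean())


def voltage_base(sweep: Sweep, window: ProtocolWindow) -> float:
    """Mean voltage over the last 10% of the time before the injection.

    The segment is ``[0.9*start, start)``, half-open at the stimulus onset so
    a step beginning exactly at ``start`` is excluded.
    """
    if window.start <= 0:
        raise BaseUndefinedError("no pre-stimulus time: window starts at 0")
    _check_window(sweep, window)
    mask = _window_mask(sweep.time, 0.9 * window.start, window.start)
    if not mask.any():
        raise WindowError("no samples in the baseline segment")
    return float(sweep.voltage[mask].mean())


def infer_step_amplitude(sweep: Sweep, window: ProtocolWindow) -> float:
    """Baseline-subtracted current-step amplitude from the protocol channel.

    Mean current over the injection ``[start, end)`` minus mean current over
    the pre-stimulus baseline ``[0.9*start, start)``; robust to amplifier
    offsets.  The result is stored on ``sweep.step_amplitude``.
    """
    if window.start <= 0:
        raise BaseUndefinedError("no pre-stimulus time: window starts at 0")
    _check_window(sweep, window)
    step = _window_mask(sweep.time, window.start, window.end)
    base = _window_mask(sweep.time, 0.9 * window.start, window.start)
    if not step.any() or not base.any():
        raise WindowError("no samples in the step or baseline segment")
    amp = float(sweep.current[step].mean() - sweep.current[base].mean())
    sweep.step_amplitude = amp
    return amp
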