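"""Synthetic current-clamp recordings with exact ground truth.

The generator emulates the square-pulse step protocol used throughout the
package's validation: by default 21 steps of 10 pA from -100 to +100 pA,
delivered between 115 and 815 ms of a 1000 ms sweep (700 ms injection).

Subthreshold responses are built from closed-form exponentials so every
target quantity is known exactly:

* depolarizing / sag-free steps: the RC solution
  ``V(t) = RMP + I*R*(1 - exp(-t'/tau))`` during the step, and an
  exponential decay back to rest (same tau) after it;
* hyperpolarizing steps of a cell with sag: a single exponential (the true
  membrane tau) from baseline down to the sag trough at ``t_c = 5*tau``,
  then a single exponential (the true sag tau) from the trough back up to
  the steady level.  The trough sits exactly ``sag amplitude`` below steady,
  with the sag amplitude scaled linearly in |I| from its value at -100 pA.
  Each phase is exactly mono-exponential, so recovery tests for the membrane
  and sag time constants are sharp; the price is a corner (not a smooth
  turning point) at the trough, which the analysis never assumes.

Action potentials are inserted as stereotyped piecewise-linear waveforms
added on top of the subthreshold solution, giving exact ground-truth spike
times.  For steps at or above rheobase the spike count is
``max(1, round(fi_gain * (I - rheobase) * duration / 1000))`` and spikes are
evenly spaced from a fixed latency.  Additive Gaussian voltage noise (one
seeded stream per recording) is the only stochastic element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import BatchManifest, write_delimited
from .recording import Recording, Sweep

__all__ = [
    "CellParams",
    "ProtocolSpec",
    "GroundTruth",
    "simulate_recording",
    "write_fixture_batch",
]

#: ms between stimulus onset and the first inserted AP peak
SPIKE_LATENCY_MS = 20.0
#: ms kept free of spikes at the end of the step (room for the AHP)
SPIKE_END_MARGIN_MS = 20.0


@dataclass
class CellParams:
    """Ground-truth biophysics of one simulated cell.

    ``ap_shape`` is (threshold mV, peak mV, half-width ms, AHP depth mV);
    the absolute threshold/peak levels size the inserted waveform (height =
    peak - threshold) which rides on the local subthreshold voltage.
    """

    resting_potential: float = -68.0  # mV
    input_resistance: float = 0.2  # GOhm
    time_constant: float = 15.0  # ms
    sag_amplitude_at_minus100: float = 5.0  # mV, trough depth below steady at -100 pA
    sag_time_constant: float = 50.0  # ms
    rheobase: float = 40.0  # pA
    fi_gain: float = 0.5  # Hz/pA above rheobase
    ap_shape: tuple[float, float, float, float] = (-42.0, 38.0, 1.0, 12.0)
    noise_sd: float = 0.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_resistance <= 0 or self.time_constant <= 0 \
                or self.sag_time_constant <= 0:
            raise ValueError("resistance and time constants must be positive")
        thr, peak, hw, ahp = self.ap_shape
        if peak <= thr:
            raise ValueError("AP peak must exceed threshold")
        if hw <= 0 or ahp < 0:
            raise ValueError("AP half-width must be positive, AHP depth non-negative")


@dataclass
class ProtocolSpec:
    """Square-pulse step protocol (the step list is explicit)."""

    step_amplitudes: tuple[float, ...] = tuple(float(a) for a in range(-100, 101, 10))
    start: float = 115.0  # ms
    end: float = 815.0  # ms
    sweep_duration: float = 1000.0  # ms
    sampling_interval: float = 0.1  # ms

    def __post_init__(self) -> None:
        if not (0 < self.start < self.end <= self.sweep_duration):
            raise ValueError("require 0 < start < end <= sweep_duration")
        if not all(np.isfinite(self.step_amplitudes)):
            raise ValueError("step amplitudes must be finite")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Everything the generator knows: parameters plus per-sweep targets."""

    cell: CellParams
    protocol: ProtocolSpec
    step_amplitudes: list[float] = field(default_factory=list)
    spike_times: list[list[float]] = field(default_factory=list)  # peak times, ms
    steady_voltages: list[float] = field(default_factory=list)  # mV
    sag_amplitudes: list[float] = field(default_factory=list)  # mV (0 when no sag)

    @property
    def spike_counts(self) -> list[int]:
        return [len(s) for s in self.spike_times]


def _ap_template(dt: float, shape: tuple[float, float, float, float]) -> tuple[np.ndarray, int]:
    """Sampled additive AP bump; returns (samples, index of the peak sample).

    Piecewise linear: rise of the full AP height over one half-width, fall
    to ``-AHP depth`` sized so the waveform's width at half height matches
    the requested half-width, then a slow linear recovery (well below any
    dV/dt detection criterion).
    """
    thr, peak, half_width, ahp_depth = shape
    height = peak - thr
    t_rise = half_width
    t_fall = half_width * (height + ahp_depth) / height
    t_recover = 10.0
    if half_width / dt < 4:
        raise ValueError("sampling too coarse: need >= 4 samples per AP half-width")
    knots_t = np.array([0.0, t_rise, t_rise + t_fall, t_rise + t_fall + t_recover])
    knots_v = np.array([0.0, height, -ahp_depth, 0.0])
    tt = np.arange(0.0, knots_t[-1] + dt, dt)
    return np.interp(tt, knots_t, knots_v), int(round(t_rise / dt))


def _subthreshold(t: np.ndarray, amp: float, cell: CellParams,
                  proto: ProtocolSpec) -> np.ndarray:
    """Closed-form noiseless subthreshold voltage for one step amplitude."""
    rmp, r, tau = cell.resting_potential, cell.input_resistance, cell.time_constant
    steady = rmp + amp * r
    v = np.full_like(t, rmp)
    dt_tol = 1e-6 * proto.sampling_interval
    in_step = (t >= proto.start - dt_tol) & (t < proto.end - dt_tol)
    tp = t[in_step] - proto.start
    sag = cell.sag_amplitude_at_minus100 * abs(amp) / 100.0 if amp < 0 else 0.0
    if sag > 0:
        t_c = min(5.0 * tau, 0.5 * proto.duration)
        e_c = math.exp(-t_c / tau)
        trough = steady - sag
        v_inf1 = (trough - rmp * e_c) / (1.0 - e_c)
        phase1 = v_inf1 + (rmp - v_inf1) * np.exp(-tp / tau)
        phase2 = steady + (trough - steady) * np.exp(-(tp - t_c) / cell.sag_time_constant)
        v[in_step] = np.where(tp <= t_c, phase1, phase2)
    else:
        v[in_step] = steady + (rmp - steady) * np.exp(-tp / tau)
    after = t >= proto.end - dt_tol
    if after.any():
        v_end = float(v[in_step][-1]) if in_step.any() else rmp
        v[after] = rmp + (v_end - rmp) * np.exp(-(t[after] - proto.end) / tau)
    return v


def simulate_recording(cell: CellParams, protocol: ProtocolSpec | None = None,
                       name: str = "simulated_cell") -> tuple[Recording, GroundTruth]:
    """Simulate one multi-sweep recording; returns it with its ground truth."""
    proto = protocol or ProtocolSpec()
    dt = proto.sampling_interval
    n = int(round(proto.sweep_duration / dt))
    t = np.arange(n) * dt
    rng = np.random.default_rng(cell.seed)
    template, peak_off = _ap_template(dt, cell.ap_shape)
    truth = GroundTruth(cell=cell, protocol=proto)
    dt_tol = 1e-6 * dt
    in_step = (t >= proto.start - dt_tol) & (t < proto.end - dt_tol)

    sweeps = []
    for i, amp in enumerate(proto.step_amplitudes):
        v = _subthreshold(t, amp, cell, proto)
        spike_times: list[float] = []
        if amp >= cell.rheobase:
            freq = cell.fi_gain * (amp - cell.rheobase)
            n_spk = max(1, int(round(freq * proto.duration / 1000.0)))
            isi = (proto.duration - SPIKE_LATENCY_MS - SPIKE_END_MARGIN_MS) / n_spk
            for k in range(n_spk):
                peak_t = proto.start + SPIKE_LATENCY_MS + k * isi
                peak_i = int(round(peak_t / dt))
                lo = peak_i - peak_off
                hi = min(lo + template.size, n)
                v[lo:hi] += template[:hi - lo]
                spike_times.append(t[peak_i])
        if cell.noise_sd > 0:
            v = v + rng.normal(0.0, cell.noise_sd, size=n)
        current = np.where(in_step, amp, 0.0)
        sweeps.append(Sweep(index=i, time=t.copy(), voltage=v, current=current))
        truth.step_amplitudes.append(float(amp))
        truth.spike_times.append(spike_times)
        truth.steady_voltages.append(cell.resting_potential + amp * cell.input_resistance)
        truth.sag_amplitudes.append(
            cell.sag_amplitude_at_minus100 * abs(amp) / 100.0 if amp < 0 else 0.0)
    rec = Recording(name=name, sweeps=sweeps, sampling_interval=dt)
    return rec, truth


def write_fixture_batch(folder: str, n_cells: int, seed: int,
                        protocol: ProtocolSpec | None = None,
                        noise_sd: float = 0.0) -> tuple[BatchManifest, list[GroundTruth]]:
    """Write ``n_cells`` delimited recordings with randomized, recorded cells.

    Cell parameters are drawn from physiological ranges (R 0.1-0.5 GOhm, tau
    8-30 ms, RMP -75..-60 mV, sag 0-8 mV at -100 pA, rheobase 30-60 pA) from
    a single stream seeded by ``seed``; runs are fully deterministic.  A
    ``ground_truth.txt`` sidecar (tab-separated key/value, one block per
    cell) records every parameter; its extension keeps it out of the batch
    manifest.
    """
    proto = protocol or ProtocolSpec()
    out = Path(folder)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truths = []
    lines = []
    for c in range(n_cells):
        cell = CellParams(
            resting_potential=float(rng.uniform(-75.0, -60.0)),
            input_resistance=float(rng.uniform(0.1, 0.5)),
            time_constant=float(rng.uniform(8.0, 30.0)),
            sag_amplitude_at_minus100=float(rng.uniform(0.0, 8.0)),
            sag_time_constant=float(rng.uniform(30.0, 60.0)),
            rheobase=float(rng.choice([30.0, 40.0, 50.0, 60.0])),
            fi_gain=0.5,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        name = f"cell_{c + 1:02d}"
        rec, truth = simulate_recording(cell, proto, name=name)
        write_delimited(rec, str(out / f"{name}.tsv"))
        truths.append(truth)
        for key, value in asdict(cell).items():
            lines.append(f"{name}\t{key}\t{value}")
    (out / "ground_truth.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    from .io import scan_folder
    return scan_folder(str(out)), truths
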