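"""Passive membrane properties per sweep and the per-neuron overview.

All passive properties are computed on sweeps without any detected action
potential.  Units: mV / pA / ms, so input resistance is mV/pA = GOhm and
capacitance is ms/GOhm = pF.

Per-sweep input resistance uses the baseline-subtracted response
``(steady - base) / I``: the steady membrane voltage is a *response* to the
injected current, and dividing the absolute membrane potential by the step
would be physiologically meaningless.  The overview input resistance is
instead the OLS slope of steady voltage on injected current across
spike-free sweeps, which absorbs the resting potential into the intercept;
the two definitions agree for an ideal ohmic cell but respond differently
to offsets, which is why both are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError
from .recording import (ProtocolWindow, Recording, Sweep, _window_mask,
                        steady_membrane_voltage, voltage_base)

__all__ = [
    "SweepPassiveFeatures",
    "NeuronOverview",
    "fit_time_constant",
    "input_resistance_sweep",
    "sag_features",
    "passive_sweep_features",
    "neuron_overview",
]

log = logging.getLogger("ephysbatch")

#: nominal step amplitudes (pA, inclusive) whose onset tau enters the
#: overview membrane time constant; measured amplitudes are rounded to 1 pA
#: before the comparison so floating-point jitter cannot drop a nominal
#: -50/-40 pA step out of range.
TAU_STEP_RANGE = (-50.0, -40.0)


@dataclass
class SweepPassiveFeatures:
    """Passive-table row for one spike-free sweep."""

    sweep_index: int
    step_amplitude: float  # pA
    steady_voltage: float  # mV
    voltage_base: float  # mV
    time_constant: float = math.nan  # ms, onset fit (hyperpolarizing only)
    input_resistance: float = math.nan  # GOhm, (steady-base)/I
    capacitance: float = math.nan  # pF, tau / Rin
    decay_time_constant: float = math.nan  # ms, offset fit
    sag_amplitude: float = math.nan  # mV
    sag_ratio: float = math.nan
    sag_time_constant: float = math.nan  # ms


@dataclass
class NeuronOverview:
    """Per-recording summary row."""

    recording_name: str
    resting_membrane_potential: float = math.nan  # mV
    sag_amplitude: float = math.nan  # mV, most hyperpolarized step
    sag_ratio: float = math.nan
    membrane_input_resistance: float = math.nan  # GOhm, regression slope
    membrane_time_constant: float = math.nan  # ms
    membrane_capacitance: float = math.nan  # pF
    rheobase: float = math.nan  # pA
    ap1: dict[str, float] = field(default_factory=dict)  # latency + 14 waveform features


def _exp_model(t: np.ndarray, v_inf: float, a: float, tau: float) -> np.ndarray:
    return v_inf + a * np.exp(-t / tau)


def fit_time_constant(sweep: Sweep, window: ProtocolWindow, segment: str,
                      steady_voltage: float | None = None) -> float:
    """Least-squares single-exponential time constant over one segment.

    ``segment`` selects the fitted span:

    onset
        stimulus start to the voltage minimum within the window
        (hyperpolarizing charge phase; the membrane covers 63% of its total
        change in one time constant).
    offset
        window end to five initial-guess time constants past it, capped at
        the trace end (the decay after the step).
    sag
        voltage minimum to the window end (relaxation from the sag trough
        back to the steady level).

    The fit is deterministic: initial values ``V_inf = steady voltage``,
    ``A = V(t0) - V_inf``, ``tau = segment duration / 5``; ``tau`` is bounded
    to ``(0, window duration]``.  Raises :class:`FitError` on degenerate
    input (flat trace) or non-convergence.
    """
    t, v = sweep.time, sweep.voltage
    tol = 1e-6 * sweep.sampling_interval
    win = _window_mask(t, window.start, window.end)
    if not win.any():
        raise FitError("window contains no samples")
    min_i = int(np.flatnonzero(win)[np.argmin(v[win])])
    if segment == "onset":
        mask = (t >= window.start - tol) & (t <= t[min_i] + tol)
    elif segment == "sag":
        mask = (t >= t[min_i] - tol) & (t < window.end - tol)
    elif segment == "offset":
        tau_guess = window.duration / 5.0
        mask = (t >= window.end - tol) & (t <= window.end + 5.0 * tau_guess + tol)
    else:
        raise ValueError(f"unknown segment {segment!r}")
    ts, vs = t[mask], v[mask]
    if ts.size < 4:
        raise FitError(f"{segment} segment too short to fit ({ts.size} samples)")
    ts = ts - ts[0]
    if steady_voltage is None:
        steady_voltage = float(vs[-1])
    a0 = float(vs[0] - steady_voltage)
    if abs(a0) < 1e-6 and abs(vs.max() - vs.min()) < 1e-6:
        raise FitError(f"{segment} segment is constant; no exponential to fit")
    tau0 = min(max(ts[-1] / 5.0, 1e-3), window.duration)
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, ts, vs, p0=(steady_voltage, a0, tau0),
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, window.duration]),
            xtol=1e-8, ftol=1e-8, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{segment} exponential fit did not converge: {exc}") from exc
    v_inf, a, tau = popt
    if not np.isfinite(tau) or tau <= 0 or tau > window.duration or abs(a) < 1e-6:
        raise FitError(f"{segment} fit degenerate (A={a:.3g}, tau={tau:.3g})")
    return float(tau)


def input_resistance_sweep(steady_voltage: float, base_voltage: float,
                           step_amplitude: float) -> float:
    """Per-sweep Ohm's-law input resistance ``(steady - base) / I`` in GOhm.

    Returns NaN for a 0 pA step (no stimulus, no response to divide by).
    """
    if step_amplitude == 0 or not np.isfinite(step_amplitude):
        return math.nan
    return (steady_voltage - base_voltage) / step_amplitude


def sag_features(sweep: Sweep, window: ProtocolWindow, steady_voltage: float,
                 base_voltage: float) -> tuple[float, float, float]:
    """Sag amplitude (mV), sag ratio and sag time constant (ms).

    Sag amplitude is the steady voltage minus the in-window voltage minimum
    (positive when a sag exists); sag ratio is
    ``(voltage base - steady voltage) / sag amplitude``.  When the sag
    amplitude is indistinguishable from zero the ratio and time constant are
    missing.
    """
    t, v = sweep.time, sweep.voltage
    win = _window_mask(t, window.start, window.end)
    v_min = float(v[win].min())
    sag_amp = steady_voltage - v_min
    if sag_amp <= max(1e-9, 1e-6 * abs(steady_voltage)):
        return sag_amp, math.nan, math.nan
    sag_ratio = (base_voltage - steady_voltage) / sag_amp
    try:
        sag_tau = fit_time_constant(sweep, window, "sag", steady_voltage)
    except FitError as exc:
        log.warning("sweep %d: sag time constant: %s", sweep.index, exc)
        sag_tau = math.nan
    return sag_amp, sag_ratio, sag_tau


def passive_sweep_features(sweep: Sweep, window: ProtocolWindow) -> SweepPassiveFeatures:
    """All passive-table properties for one spike-free sweep.

    Onset/sag time constants and sag features apply to hyperpolarizing
    sweeps only; the decay (offset) time constant is fitted for any step.
    Capacitance is ``tau / Rin`` exactly, by construction.
    """
    steady = steady_membrane_voltage(sweep, window)
    base = voltage_base(sweep, window)
    amp = sweep.step_amplitude
    feats = SweepPassiveFeatures(
        sweep_index=sweep.index, step_amplitude=amp,
        steady_voltage=steady, voltage_base=base,
        input_resistance=input_resistance_sweep(steady, base, amp),
    )
    if np.isfinite(amp) and amp != 0:
        try:
            feats.decay_time_constant = fit_time_constant(sweep, window, "offset", base)
        except FitError as exc:
            log.warning("sweep %d: decay time constant: %s", sweep.index, exc)
    if np.isfinite(amp) and amp < 0:
        try:
            feats.time_constant = fit_time_constant(sweep, window, "onset", steady)
        except FitError as exc:
            log.warning("sweep %d: time constant: %s", sweep.index, exc)
        feats.sag_amplitude, feats.sag_ratio, feats.sag_time_constant = sag_features(
            sweep, window, steady, base)
    if np.isfinite(feats.time_constant) and np.isfinite(feats.input_resistance) \
            and feats.input_resistance != 0:
        feats.capacitance = feats.time_constant / feats.input_resistance
    return feats


def neuron_overview(recording: Recording, window: ProtocolWindow,
                    firing: dict[int, "object"],
                    passive: dict[int, SweepPassiveFeatures]) -> NeuronOverview:
    """Per-recording summary from the per-sweep firing and passive results.

    * resting membrane potential: mean voltage over the last 10% of the
      pre-stimulus time of sweep 0;
    * sag: from the most hyperpolarized (minimum step amplitude) sweep, ties
      broken by lowest sweep index;
    * membrane input resistance: OLS slope of steady voltage on step
      amplitude across spike-free sweeps (needs >= 2 of them);
    * membrane time constant: mean onset tau of spike-free sweeps with step
      amplitude in [-50, -40] pA inclusive (rounded to 1 pA);
    * membrane capacitance = tau / R;
    * rheobase: minimum step amplitude among sweeps with >= 1 spike;
    * AP1: latency plus the 14 waveform features of the first spike of the
      rheobase sweep.
    """
    ov = NeuronOverview(recording_name=recording.name)
    try:
        ov.resting_membrane_potential = voltage_base(recording.sweeps[0], window)
    except Exception as exc:
        log.warning("%s: resting membrane potential: %s", recording.name, exc)

    if passive:
        rows = sorted(passive.values(), key=lambda r: r.sweep_index)
        amps = np.array([r.step_amplitude for r in rows])
        steadies = np.array([r.steady_voltage for r in rows])
        ok = np.isfinite(amps) & np.isfinite(steadies)
        if ok.sum() >= 2:
            ov.membrane_input_resistance = float(
                stats.linregress(amps[ok], steadies[ok]).slope)
        else:
            log.warning("%s: fewer than 2 spike-free sweeps; no regression",
                        recording.name)
        taus = [r.time_constant for r in rows
                if np.isfinite(r.time_constant)
                and TAU_STEP_RANGE[0] <= round(r.step_amplitude) <= TAU_STEP_RANGE[1]]
        if taus:
            ov.membrane_time_constant = float(np.mean(taus))
        else:
            log.warning("%s: no spike-free sweep in [%g, %g] pA; no membrane tau",
                        recording.name, *TAU_STEP_RANGE)
        if np.isfinite(ov.membrane_time_constant) and \
                np.isfinite(ov.membrane_input_resistance) and \
                ov.membrane_input_resistance != 0:
            ov.membrane_capacitance = (ov.membrane_time_constant
                                       / ov.membrane_input_resistance)
        # sag from the most hyperpolarized step
        hyp = [r for r in rows if np.isfinite(r.step_amplitude)]
        if hyp:
            most = min(hyp, key=lambda r: (r.step_amplitude, r.sweep_index))
            if most.step_amplitude < 0:
                ov.sag_amplitude = most.sag_amplitude
                ov.sag_ratio = most.sag_ratio

    if firing:
        rheo_idx = min(firing, key=lambda i: (firing[i].step_amplitude, i))
        rheo = firing[rheo_idx]
        ov.rheobase = rheo.step_amplitude
        ov.ap1 = {"AP1 latency": rheo.latency}
        # "AP amplitude" -> "AP1 amplitude", "AHP abs depth" -> "AP1 AHP abs depth"
        ov.ap1.update({
            ("AP1 " + k[3:]) if k.startswith("AP ") else ("AP1 " + k): v
            for k, v in rheo.spikes[0].features().items()})
    return ov
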