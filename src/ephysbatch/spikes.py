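"""Action-potential detection and per-sweep firing properties.

Detection criterion: an AP is a local voltage maximum at or above
``min_peak_voltage`` whose rise contains an upward crossing of the dV/dt
threshold (default 10 mV/ms), with a 1 ms refractory period between accepted
peaks.  The spike's time anchor is its peak; spikes whose peak falls outside
the stimulus window are excluded.  dV/dt is computed by central differences
on the uniform sample grid, so mV/ms is numerically identical to V/s.

Landmarks per spike:

threshold
    last sample before the peak at which dV/dt first exceeds the threshold
    (the final upward crossing of the criterion before that peak).
peak
    the local voltage maximum.
AHP
    voltage minimum between the peak and the next spike's threshold, or the
    window end for the last spike (post-window activity never contributes).

Width and half-width crossings are located by linear interpolation between
adjacent samples, which keeps the features stable under resampling of a
band-limited waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .recording import ProtocolWindow, Sweep, _window_mask

__all__ = [
    "SpikeEvent",
    "SweepFiringFeatures",
    "WAVEFORM_FEATURES",
    "detect_spikes",
    "firing_features",
]

REFRACTORY_MS = 1.0

#: canonical names of the 14 per-AP waveform features, in table order,
#: mapped to SpikeEvent attributes
WAVEFORM_FEATURES: dict[str, str] = {
    "AP amplitude": "amplitude",
    "AP peak": "peak_voltage",
    "AP width": "width",
    "AP half width": "half_width",
    "AP threshold": "threshold_voltage",
    "AP peak upstroke": "peak_upstroke",
    "AP peak downstroke": "peak_downstroke",
    "AP rise rate": "rise_rate",
    "AP fall rate": "fall_rate",
    "AP rise time": "rise_time",
    "AP fall time": "fall_time",
    "AHP abs depth": "ahp_voltage",
    "AHP time from peak": "ahp_time_from_peak",
    "AHP depth from threshold": "ahp_depth_from_threshold",
}


@dataclass
class SpikeEvent:
    """One detected action potential with landmarks and waveform features."""

    threshold_time: float
    threshold_voltage: float
    peak_time: float
    peak_voltage: float
    ahp_time: float
    ahp_voltage: float
    amplitude: float = math.nan  # peak - threshold, mV
    width: float = math.nan  # ms, at threshold voltage
    half_width: float = math.nan  # ms, at threshold + amplitude/2
    peak_upstroke: float = math.nan  # V/s, max dV/dt on the rise
    peak_downstroke: float = math.nan  # V/s, min dV/dt on the fall
    rise_rate: float = math.nan  # V/s, threshold -> peak chord
    fall_rate: float = math.nan  # V/s, peak -> AHP chord
    rise_time: float = math.nan  # ms
    fall_time: float = math.nan  # ms
    ahp_time_from_peak: float = math.nan  # ms
    ahp_depth_from_threshold: float = math.nan  # mV

    def features(self) -> dict[str, float]:
        """Waveform features keyed by canonical property name."""
        return {name: getattr(self, attr) for name, attr in WAVEFORM_FEATURES.items()}


@dataclass
class SweepFiringFeatures:
    """Per-sweep firing properties (only sweeps with >= 1 spike)."""

    sweep_index: int
    step_amplitude: float
    steady_voltage: float
    n_spikes: int
    latency: float  # ms, window start to first AP peak
    frequency: float  # Hz, n_spikes / window duration * 1000
    first_isi: float  # ms
    mean_isi: float  # ms
    isi_cv: float  # population SD / mean
    spikes: list[SpikeEvent] = field(default_factory=list)
    average_ap: dict[str, float] = field(default_factory=dict)
    ap1: dict[str, float] = field(default_factory=dict)
    ap2: dict[str, float] = field(default_factory=dict)
    aps_l: dict[str, float] = field(default_factory=dict)
    ap_l: dict[str, float] = field(default_factory=dict)
    amplitude_ap1_apl: float = math.nan
    peak_ap1_apl: float = math.nan
    halfwidth_ap1_apl: float = math.nan


def _interp_crossing(t: np.ndarray, v: np.ndarray, i: int, j: int, level: float) -> float:
    """Time where v crosses `level` between samples i and j (linear)."""
    if v[j] == v[i]:
        return float(t[i])
    frac = (level - v[i]) / (v[j] - v[i])
    return float(t[i] + frac * (t[j] - t[i]))


def _complete_waveform(spike: SpikeEvent, t: np.ndarray, v: np.ndarray,
                       dvdt: np.ndarray, thr_i: int, peak_i: int, ahp_i: int) -> None:
    """Fill in the derived waveform features from the landmark samples."""
    spike.amplitude = spike.peak_voltage - spike.threshold_voltage
    spike.rise_time = spike.peak_time - spike.threshold_time
    spike.fall_time = spike.ahp_time - spike.peak_time
    spike.ahp_time_from_peak = spike.ahp_time - spike.peak_time
    spike.ahp_depth_from_threshold = spike.threshold_voltage - spike.ahp_voltage
    if spike.rise_time > 0:
        spike.rise_rate = spike.amplitude / spike.rise_time
    if spike.fall_time > 0:
        spike.fall_rate = (spike.ahp_voltage - spike.peak_voltage) / spike.fall_time
    spike.peak_upstroke = float(dvdt[thr_i:peak_i + 1].max())
    spike.peak_downstroke = float(dvdt[peak_i:ahp_i + 1].min())

    def width_at(level: float) -> float:
        # upward crossing before the peak
        up = math.nan
        for k in range(peak_i - 1, max(thr_i - 2, -1), -1):
            if v[k] <= level < v[k + 1]:
                up = _interp_crossing(t, v, k, k + 1, level)
                break
        # first downward crossing after the peak (fast-AHP re-crossings ignored)
        down = math.nan
        for k in range(peak_i, ahp_i):
            if v[k] >= level > v[k + 1]:
                down = _interp_crossing(t, v, k, k + 1, level)
                break
        return down - up  # nan-propagating

    spike.width = width_at(spike.threshold_voltage)
    spike.half_width = width_at(spike.threshold_voltage + spike.amplitude / 2.0)


def detect_spikes(sweep: Sweep, window: ProtocolWindow,
                  dvdt_threshold: float = 10.0,
                  min_peak_voltage: float = -20.0) -> list[SpikeEvent]:
    """Detect APs whose peak lies inside the stimulus window.

    Returns a list of completed :class:`SpikeEvent`, ordered by peak time.
    An empty list is a valid result (subthreshold sweep).
    """
    t, v = sweep.time, sweep.voltage
    dvdt = np.gradient(v, t)
    refractory = max(1, int(round(REFRACTORY_MS / sweep.sampling_interval)))
    peak_idx, _ = find_peaks(v, height=min_peak_voltage, distance=refractory)
    tol = 1e-6 * sweep.sampling_interval
    peak_idx = peak_idx[(t[peak_idx] >= window.start - tol) & (t[peak_idx] < window.end - tol)]

    # upward crossings of the dV/dt criterion
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1

    landmarks: list[tuple[int, int]] = []  # (thr_i, peak_i)
    prev_peak = -1
    for p in peak_idx:
        cand = crossings[(crossings <= p) & (crossings > prev_peak)]
        if cand.size == 0:
            continue  # no fast rise before this maximum: not an AP
        landmarks.append((int(cand[-1]), int(p)))
        prev_peak = int(p)

    # AHP: minimum between this peak and the next spike's threshold
    # (window end for the last spike)
    end_i = int(np.flatnonzero(_window_mask(t, window.start, window.end))[-1]) if landmarks else 0
    spikes: list[SpikeEvent] = []
    for k, (thr_i, peak_i) in enumerate(landmarks):
        stop_i = landmarks[k + 1][0] if k + 1 < len(landmarks) else end_i
        stop_i = max(stop_i, peak_i + 1)
        ahp_i = peak_i + int(np.argmin(v[peak_i:stop_i + 1]))
        spike = SpikeEvent(
            threshold_time=float(t[thr_i]), threshold_voltage=float(v[thr_i]),
            peak_time=float(t[peak_i]), peak_voltage=float(v[peak_i]),
            ahp_time=float(t[ahp_i]), ahp_voltage=float(v[ahp_i]),
        )
        _complete_waveform(spike, t, v, dvdt, thr_i, peak_i, ahp_i)
        spikes.append(spike)
    return spikes


def _feature_map(spike: SpikeEvent | None) -> dict[str, float]:
    if spike is None:
        return {name: math.nan for name in WAVEFORM_FEATURES}
    return spike.features()


def firing_features(spikes: list[SpikeEvent], window: ProtocolWindow,
                    sweep_index: int = 0, step_amplitude: float = math.nan,
                    steady_voltage: float = math.nan) -> SweepFiringFeatures:
    """Assemble the firing-table row for one sweep from its detected spikes.

    Requires at least one spike.  ISI statistics use peak-to-peak intervals
    and the population (divide-by-n) standard deviation; they are reported as
    missing when fewer than two spikes exist.  Single-AP property maps cover
    the first, second, second-last and last AP: for two spikes the
    second-last coincides with the first; for one spike AP2 and APsL are
    missing and APL equals AP1.
    """
    if not spikes:
        raise ValueError("firing_features requires at least one spike")
    n = len(spikes)
    peaks = np.array([s.peak_time for s in spikes])
    latency = float(peaks[0] - window.start)
    frequency = n / window.duration * 1000.0
    if n >= 2:
        isis = np.diff(peaks)
        first_isi = float(isis[0])
        mean_isi = float(isis.mean())
        isi_cv = float(isis.std() / mean_isi) if mean_isi != 0 else math.nan
    else:
        first_isi = mean_isi = isi_cv = math.nan

    ap1, apl = spikes[0], spikes[-1]
    ap2 = spikes[1] if n >= 2 else None
    aps_l = spikes[-2] if n >= 2 else None

    feats = SweepFiringFeatures(
        sweep_index=sweep_index, step_amplitude=step_amplitude,
        steady_voltage=steady_voltage, n_spikes=n, latency=latency,
        frequency=frequency, first_isi=first_isi, mean_isi=mean_isi,
        isi_cv=isi_cv, spikes=spikes,
        ap1=_feature_map(ap1), ap2=_feature_map(ap2),
        aps_l=_feature_map(aps_l), ap_l=_feature_map(apl),
    )
    feats.average_ap = {
        name: float(np.mean([getattr(s, attr) for s in spikes]))
        for name, attr in WAVEFORM_FEATURES.items()
    }
    if apl.amplitude:
        feats.amplitude_ap1_apl = ap1.amplitude / apl.amplitude
    if apl.peak_voltage:
        feats.peak_ap1_apl = ap1.peak_voltage / apl.peak_voltage
    if apl.half_width:
        feats.halfwidth_ap1_apl = ap1.half_width / apl.half_width
    return feats
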