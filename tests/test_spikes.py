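"""AP detection, waveform features, and per-sweep firing statistics."""

import math

import numpy as np
import pytest

import ephysbatch as eb
from ephysbatch.spikes import WAVEFORM_FEATURES, SpikeEvent
from conftest import WINDOW, make_sweep


def triangle_sweep(dt=0.01, t0=200.0, baseline=-40.0):
    """Flat baseline with one triangular AP: threshold (-40 mV, t0),
    peak (+20 mV, t0+1), AHP (-50 mV, t0+3), then flat at the AHP level."""
    t = np.arange(int(round(1000.0 / dt))) * dt
    knots_t = [0.0, t0, t0 + 1.0, t0 + 3.0, 1000.0]
    knots_v = [baseline, baseline, 20.0, -50.0, -50.0]
    return make_sweep(t, np.interp(t, knots_t, knots_v))


def bump(t, peak_t, rise=1.0, fall=1.5, recover=10.0, height=90.0, ahp=10.0):
    """Additive piecewise-linear AP waveform peaking at peak_t."""
    knots_t = [peak_t - rise, peak_t, peak_t + fall, peak_t + fall + recover]
    knots_v = [0.0, height, -ahp, 0.0]
    out = np.interp(t, knots_t, knots_v)
    out[(t < knots_t[0]) | (t > knots_t[-1])] = 0.0
    return out


class TestDetection:
    def test_subthreshold_sweep_yields_no_spikes(self):
        rec, _ = eb.simulate_recording(eb.CellParams(rheobase=1e9))
        for sw in rec:
            assert eb.detect_spikes(sw, WINDOW) == []

    def test_spikes_outside_window_are_excluded(self):
        t = np.arange(20000) * 0.05
        v = np.full_like(t, -65.0)
        inside = [150.0, 250.0, 350.0, 450.0, 550.0]
        for pt in inside + [900.0]:  # one AP after the window end
            v = v + bump(t, pt)
        spikes = eb.detect_spikes(make_sweep(t, v), WINDOW)
        assert [s.peak_time for s in spikes] == pytest.approx(inside, abs=0.05)

    def test_identical_aps_have_identical_features(self):
        t = np.arange(20000) * 0.05
        v = np.full_like(t, -65.0) + bump(t, 200.0) + bump(t, 400.0)
        a, b = eb.detect_spikes(make_sweep(t, v), WINDOW)
        assert a.amplitude == pytest.approx(b.amplitude, abs=1e-9)
        assert a.half_width == pytest.approx(b.half_width, abs=1e-9)

    def test_simulator_spike_counts_match_ground_truth(self, default_cell_result):
        res, truth = default_cell_result
        for i, n_true in enumerate(truth.spike_counts):
            n_got = res.firing[i].n_spikes if i in res.firing else 0
            assert n_got == n_true

    def test_dense_train_one_spike_per_4ms(self):
        t = np.arange(20000) * 0.05
        v = np.full_like(t, -65.0)
        times = [200.0 + 4.0 * k for k in range(10)]
        for pt in times:
            v = v + bump(t, pt, rise=0.5, fall=0.75, recover=2.0)
        spikes = eb.detect_spikes(make_sweep(t, v), WINDOW)
        assert [s.peak_time for s in spikes] == pytest.approx(times, abs=0.05)


class TestWaveformFeatures:
    def test_triangular_ap_arithmetic(self):
        (s,) = eb.detect_spikes(triangle_sweep(), WINDOW)
        assert s.threshold_voltage == pytest.approx(-40.0, abs=0.2)
        assert s.amplitude == pytest.approx(60.0, abs=0.2)
        assert s.rise_time == pytest.approx(1.0, abs=0.02)
        assert s.rise_rate == pytest.approx(60.0, rel=0.01)
        assert s.fall_rate == pytest.approx(-35.0, rel=0.01)
        assert s.ahp_depth_from_threshold == pytest.approx(10.0, abs=0.2)
        assert s.ahp_voltage == pytest.approx(-50.0, abs=1e-9)
        assert s.half_width <= s.width

    def test_widths_match_dense_resampling_oracle(self):
        sw = triangle_sweep(dt=0.01)
        (s,) = eb.detect_spikes(sw, WINDOW)
        # oracle: brute-force crossing search on a 1000x oversampled trace
        # (restricted to the spike neighbourhood)
        t_dense = np.arange(195.0, 210.0, 0.01 / 1000)
        v_dense = np.interp(t_dense, sw.time, sw.voltage)
        for level, got in ((s.threshold_voltage, s.width),
                           (s.threshold_voltage + s.amplitude / 2, s.half_width)):
            above = v_dense > level
            idx = np.flatnonzero(above[1:] != above[:-1])
            peak_i = int(np.argmax(v_dense))
            ups = idx[idx < peak_i]
            downs = idx[idx >= peak_i]
            oracle = t_dense[downs[0]] - t_dense[ups[-1]]
            assert got == pytest.approx(oracle, abs=0.005)

    def test_symmetric_ap_mirrors_rise_and_fall(self):
        dt = 0.01
        t = np.arange(int(round(1000.0 / dt))) * dt
        knots_t = [0.0, 300.0, 302.0, 304.0, 1000.0]
        knots_v = [-70.0, -70.0, 10.0, -70.0, -70.0]
        (s,) = eb.detect_spikes(make_sweep(t, np.interp(t, knots_t, knots_v)), WINDOW)
        assert s.rise_time == pytest.approx(s.fall_time, abs=1e-9)
        assert s.peak_upstroke == pytest.approx(-s.peak_downstroke, abs=1e-9)


def spike_at(pt):
    return SpikeEvent(threshold_time=pt - 1, threshold_voltage=-40.0,
                      peak_time=pt, peak_voltage=20.0,
                      ahp_time=pt + 2, ahp_voltage=-50.0,
                      amplitude=60.0, half_width=1.0)


class TestFiringFeatures:
    def test_frequency_formula(self):
        spikes = [spike_at(150.0 + 90 * k) for k in range(7)]
        f = eb.firing_features(spikes, WINDOW)
        assert f.frequency == pytest.approx(10.0)  # 7 spikes / 700 ms * 1000

    def test_periodic_train_has_zero_isi_cv(self):
        f = eb.firing_features([spike_at(150.0 + 50 * k) for k in range(5)], WINDOW)
        assert f.isi_cv == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_isi_statistics(self):
        f = eb.firing_features([spike_at(p) for p in (120.0, 150.0, 200.0, 300.0)],
                               WINDOW)
        assert f.latency == pytest.approx(5.0)
        assert f.first_isi == pytest.approx(30.0)
        assert f.mean_isi == pytest.approx(60.0)
        # population-SD convention, direct formula oracle
        isis = np.array([30.0, 50.0, 100.0])
        assert f.isi_cv == pytest.approx(
            math.sqrt(((isis - 60.0) ** 2).mean()) / 60.0, rel=1e-12)

    def test_single_spike_edge_cases(self):
        f = eb.firing_features([spike_at(200.0)], WINDOW)
        assert f.n_spikes == 1
        assert math.isnan(f.first_isi) and math.isnan(f.mean_isi)
        assert all(math.isnan(v) for v in f.ap2.values())
        assert all(math.isnan(v) for v in f.aps_l.values())
        assert f.ap_l == f.ap1
        assert f.amplitude_ap1_apl == f.peak_ap1_apl == f.halfwidth_ap1_apl == 1.0

    def test_two_spikes_second_last_is_first(self):
        f = eb.firing_features([spike_at(200.0), spike_at(260.0)], WINDOW)
        assert f.aps_l == f.ap1
        assert f.ap2 == f.ap_l

    def test_average_of_identical_spikes_equals_each(self):
        spikes = [spike_at(p) for p in (200.0, 260.0, 320.0)]
        f = eb.firing_features(spikes, WINDOW)
        for name in WAVEFORM_FEATURES:
            a, b = f.average_ap[name], f.ap1[name]
            assert (a == pytest.approx(b, abs=1e-12)) or (
                math.isnan(a) and math.isnan(b))

    def test_requires_at_least_one_spike(self):
        with pytest.raises(ValueError):
            eb.firing_features([], WINDOW)


def test_shift_invariance_of_all_features():
    """Translating the time base and the window together changes nothing."""
    rec, _ = eb.simulate_recording(eb.CellParams())
    sw = rec.sweeps[16]  # a spiking sweep
    shifted = eb.Sweep(index=0, time=sw.time + 250.0, voltage=sw.voltage,
                       current=sw.current)
    win2 = eb.ProtocolWindow(WINDOW.start + 250.0, WINDOW.end + 250.0)
    f0 = eb.firing_features(eb.detect_spikes(sw, WINDOW), WINDOW)
    f1 = eb.firing_features(eb.detect_spikes(shifted, win2), win2)
    assert f1.n_spikes == f0.n_spikes
    assert f1.latency == pytest.approx(f0.latency, abs=1e-6)
    assert f1.mean_isi == pytest.approx(f0.mean_isi, abs=1e-6)
    for name in WAVEFORM_FEATURES:
        assert f1.average_ap[name] == pytest.approx(f0.average_ap[name], abs=1e-6)
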