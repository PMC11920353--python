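# Methods

## Scope and data model

`ephysbatch` analyses multi-sweep whole-cell current-clamp recordings of
square current-step protocols. A *sweep* is one stimulus episode (uniform
time base in ms, voltage in mV, current in pA); a *recording* is an ordered
set of sweeps sharing one sampling rate and duration; the *protocol window*
[start, end) is the stimulus epoch, supplied by the user because step timing
is a property of the acquisition protocol, not reliably of the file. Units
are never converted: mV/pA = GΩ and ms/GΩ = pF, so resistance and
capacitance fall out of the arithmetic directly.

All analysis windows are half-open [a, b) on time: a sample exactly at a
window edge belongs to the following segment, so the stimulus edge sample is
never double-counted, and "last 10 %" segments are defined on time, not on
sample count. Window masks use a tolerance of 10⁻⁶ sample intervals, large
enough to absorb accumulation error in a float time base and small enough
never to move a sample across an on-grid edge.

The injected step amplitude is measured from the protocol channel as the
mean current over the step minus the mean over the pre-stimulus baseline.
This baseline subtraction makes the estimate robust to amplifier offsets and
is linear in the injected current.

## Spike detection and waveform features

An action potential is a local voltage maximum at or above the
minimum-peak gate whose rise contains an upward crossing of the dV/dt
criterion, with a 1 ms refractory period between accepted peaks. Defaults:
10 mV/ms and −20 mV, both exposed in the configuration; derivative-threshold
detection is the convention of the standard feature-extraction libraries in
this field. dV/dt is computed by central differences on the uniform grid.
The spike's time anchor is its peak throughout (latency is measured to the
first peak, ISIs peak-to-peak); peaks outside the stimulus window are
excluded. The threshold point is the last sample before the peak at which
dV/dt first exceeds the criterion; the AHP is the voltage minimum between
the peak and the next spike's threshold (window end for the last spike, so
post-window activity never contributes).

Width (at the threshold voltage) and half-width (at threshold + amplitude/2)
locate their crossings by linear interpolation between adjacent samples,
which keeps these features stable to well under 1 % when a band-limited
waveform is resampled at twice the interval. When a fast AHP re-crosses the
threshold level, the first downward crossing after the peak is used. ISI CV
uses the population (divide-by-n) standard deviation — it describes the
observed ISI sequence, not an estimate of a parent distribution. For a
single spike the AP2 and second-last-AP columns are missing and the last AP
equals AP1 (all three AP1/APL ratios are exactly 1); for two spikes the
second-last AP coincides with AP1. The per-sweep "average AP" averages
waveform features over all spikes of that sweep; ratio features are computed
once per sweep and never averaged.

## Passive properties

Every sweep lands in exactly one of the firing (≥ 1 AP) or passive (0 APs)
result sets; this partition also decides which sweeps enter the passive
table, the current–voltage regression and plot, and the τ averaging.

Exponential fits use the model V(t) = V∞ + A·e^(−t/τ) with deterministic
initialisation (V∞ = steady voltage, A = first-sample residual,
τ₀ = segment duration/5), τ bounded to (0, window duration], and
trust-region least squares at 10⁻⁸ tolerances — no randomness anywhere in
the pipeline. Three segments are fitted: *onset* (stimulus start to the
in-window voltage minimum), *sag* (voltage minimum to window end) and
*offset* (window end to five initial-guess time constants later, capped at
the trace end; the cap length is this package's choice, long enough to
contain the decay at any plausible τ). A flat segment (|A| ≈ 0) or a τ at
the bounds raises a fit error, which the callers convert to a missing value
plus a Warning — a failed fit never discards a recording.

Per-sweep input resistance is the baseline-subtracted Ohm's law
(V_steady − V_base)/I. The steady voltage is a *response* to the injected
current; dividing the absolute membrane potential by the step would be
dimensionally a resistance but physiologically meaningless. The overview
input resistance is instead the OLS slope of steady voltage on injected
current over spike-free sweeps (≥ 2 required), which absorbs any constant
offset into the intercept; both definitions are reported because they react
differently to offsets. Capacitance is τ/R exactly, per sweep and in the
overview, so the C·R = τ identity holds to machine precision by
construction.

Sag amplitude is steady voltage minus the in-window minimum (positive when
a sag exists); sag ratio is (V_base − V_steady)/sag amplitude; both come
from the most hyperpolarized step (minimum measured amplitude, ties broken
by lowest sweep index) in the overview. A sag amplitude indistinguishable
from zero leaves the ratio and sag τ missing. The overview membrane τ
averages onset fits over spike-free sweeps whose step amplitude, rounded to
1 pA, lies in [−50, −40] pA inclusive — rounding keeps a nominal −50 or
−40 pA step from dropping out of range through measurement jitter. Rheobase
is the minimum step amplitude among spiking sweeps (not first-in-file-order,
so non-monotonic protocols work), and the overview AP1 features come from
the first spike of that sweep. The resting membrane potential uses only
sweep 0's pre-stimulus tail (last 10 % of the time before the step), which
is deliberately distinct from a whole-trace 0 pA average.

The 0 pA sweep, when present, participates in the regression and the
passive table but has no per-sweep input resistance (nothing to divide by).

## Batch behaviour and outputs

Recordings are processed in lexicographic name order. Three isolation
contracts hold: a recording that fails to read or analyse is skipped with an
Error entry and excluded from every table; a failure in one table or plot
blocks only that output; if nothing can be analysed, nothing is written.
Recordings in one folder must share sweep duration (step count and
amplitudes may differ); a mismatched file is skipped, the batch continues.

The firing and passive workbooks hold one sheet per recording (sheet name =
recording name); the overview is a single sheet, one row per recording.
Each workbook gets a CSV-per-sheet mirror for diff-able testing and
downstream scripting. Missing values are written as empty cells — never 0
or a sentinel, which would silently corrupt downstream statistics. Cells
carry full double precision. With all properties selected the tables expose
24 firing, 10 passive and 22 overview base properties (34 per-sweep in
total); waveform properties expand into Average AP/AP1/AP2/APsL/APL column
groups, with "rise/fall rate" and "rise/fall time" each counting as one
selectable covering two features. Default output names: folder
`analysis_output`, workbooks `firing_properties`,
`passive_membrane_properties`, `neuron_overview`.

ABF reading (versions 1 and 2) is delegated to the optional `pyabf`
dependency; when it is absent the reader raises a recoverable format error,
so a batch containing `.abf` files still processes everything else. Channel
units are trusted only to scale to mV/pA; unknown units are assumed already
scaled, with a Warning. The neutral tab-separated sweep-table format is the
reference format for tests and simulation output.

## The synthetic-data generator

The generator reproduces the study conditions the package is validated
under: 21 steps of 10 pA from −100 to +100 pA (the step list is explicit
and overridable), delivered between 115 and 815 ms of a 1000 ms sweep —
a 700 ms injection — at a 0.1 ms sampling interval (10 kHz, typical for
current clamp and fine enough for ≥ 4 samples per AP half-width, which the
generator enforces). Default cell: RMP −68 mV, R 0.2 GΩ, τ 15 ms, sag
5 mV at −100 pA with τ_sag 50 ms, rheobase 40 pA, f–I gain 0.5 Hz/pA —
mid-range values for cortical pyramidal neurons.

Subthreshold responses are closed-form. Sag-free steps follow the RC
solution exactly. For a cell with sag, a hyperpolarizing response is built
piecewise: a single exponential with the true membrane τ from baseline to
the sag trough at t_c = 5τ, then a single exponential with the true sag τ
from the trough back to the steady level, the trough sitting exactly one
sag amplitude (linear in |I|, anchored at −100 pA) below steady. Each phase
is exactly mono-exponential, so the onset and sag fits have sharp ground
truth; the cost is a corner rather than a smooth turning point at the
trough, a feature of real sag the generator does not reproduce (the
analysis nowhere assumes smoothness there). Other simplifications relative
to real data: no seal/access-resistance artifacts, no stimulus-edge
transients, spike shape is a fixed piecewise-linear template added on top
of the subthreshold solution (exact spike times, no adaptation of shape or
rate within a sweep), and noise is additive white Gaussian voltage noise
from one seeded stream per recording. Passing recovery tests therefore
demonstrates correctness of the measurement definitions and numerics, not
robustness to every artifact of experimental recordings.

Spike counts for a step at or above rheobase are
max(1, round(f·Δt/1000)) with f = gain·(I − rheobase), evenly spaced from a
20 ms latency; the floor guarantees the rheobase sweep fires. Detected
frequency is therefore quantized to whole spikes per window, which is why
the f–I slope check regresses over strictly suprathreshold steps.

One interaction worth knowing: with 0.5 mV noise and a high-R cell, the
largest depolarizing steps can settle above the −20 mV peak gate, and noise
fluctuations there occasionally satisfy the dV/dt criterion — detected
counts can then exceed the programmed counts. This is faithful detector
behaviour on a trace depolarized past the gate, not a failure mode of the
detector, and it is why exact spike-count recovery is asserted only on
noiseless data.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
3-cell batches for the end-to-end, determinism and isolation checks, and a
9-cell grid (R ∈ {0.1, 0.2, 0.5} GΩ × τ ∈ {8, 15, 30} ms), noiseless and
with 0.5 mV noise, for parameter recovery — sizes chosen to exercise the
full physiological range while keeping a complete run in well under a
minute. Recovery on noiseless data is expected within 2 % for R and τ
(observed: ≤ 0.01 %), 0.1 mV for RMP, exact for rheobase and spike counts;
with 0.5 mV noise, within 10 % for R and τ.

## Known limitations

Voltage-clamp data, non-uniform sampling, multi-electrode files, NWB/HEKA/
Igor/WinWCP formats, burst and adaptation statistics, and two-exponential
membrane fits are out of scope. The AP width definition at threshold is
ambiguous when a spike never recovers to its threshold voltage before the
next spike; the feature is then missing for that spike. Excel sheet names
are truncated to 31 characters (an XLSX limit); CSV mirrors keep full names.
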