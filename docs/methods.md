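# Methods

## The model

Two overlapped narrowband vibrations of amplitudes `a1, a2` (mm/s) and
frequencies `f_a, f_b` (Hz) superpose at the recording point into a signal
whose amplitude envelope is

```
env(t) = sqrt(a1² + a2² + 2·a1·a2·cos(2π·|f_a − f_b|·t))
```

— periodic with the beat period `T = 1000/Δf` ms, reaching `a1 + a2` at the
maxima and `|a1 − a2|` at the minima. For equal amplitudes the envelope
touches zero once per beat, so a threshold rule segments the overlap into
fused pulses repeating at Δf per second, each slightly shorter than `T`
(the pulse ends where the envelope crosses the threshold, not at the zero).
Mean pulse duration against Δf therefore follows `duration ≈ c·Δf^(−1)`;
`fit_power_law` estimates the relation by least squares on log10–log10 axes
(the spreadsheet "power" trendline convention), with R² computed in log
space. A broadband signal overlapping a tone produces no such line in the
envelope spectrum: its envelope fluctuation is spread over the signal's
bandwidth, which is the operational meaning of "interference does not
occur" tested by `envelope_periodicity`.

## Synthetic songs

`songgen` carries default per-song parameter sets for the *E. heros*
repertoire — duration, onset-to-onset repetition time, dominant frequency
and frequency-sweep endpoints, each as (mean, sd) for the lowest- and
highest-mean individual (`column="min"/"max"`). Every sampled parameter is
drawn from a normal truncated at zero; `sd_scale=0` gives deterministic
pulses at the configured means. Waveform synthesis integrates an
instantaneous-frequency trajectory into a phase-continuous sinusoid:

- **linear** (female call FS-1, male response MS-1): straight sweep between
  the endpoint frequencies. Only window-averaged endpoint frequencies are
  observable in recordings; a linear trajectory is the simplest model
  consistent with them.
- **plateau** (rival song MRS): equal thirds — sweep down to the middle
  frequency, hold, sweep down to the end frequency — modelling the rapid
  decreases separated by flat stretches seen in rival-song sonograms.
- **u_shape** (overlapped MS-1 reaction): piecewise-linear down-then-up
  sweep given by a start frequency, downward and upward sweep depths and a
  trough position (default 0.4 of the pulse).
- **broadband** (courtship MS-2): Gaussian noise shaped in the frequency
  domain to a Gaussian power spectrum centred on the dominant frequency
  with FWHM equal to the `bandwidth` parameter (default 200 Hz), zeroed
  below 20 Hz. A flat band-pass realisation was rejected for two reasons:
  a wide Butterworth band-pass peaks at the geometric band centre (~64 Hz
  for a 5–205 Hz band), not at the dominant frequency, and near-DC content
  smears the analytic-signal envelope far across inter-pulse gaps. A
  symmetric spectrum centred on the nominal dominant frequency keeps that
  parameter meaningful for a broadband signal.

The amplitude envelope is a linear-ramp trapezoid with 10% rise and fall by
default (recordings show no quantitative onset ramps; 10% avoids spectral
splatter from hard edges). The default sample rate is 4096 Hz — at least 4×
any song component, keeping traces compact; WAV export can resample.

MS-2 places its short pulses in trains (default 5 per train) at the
within-train repetition time, trains spaced at a courtship alternation
interval (default 2475.4 ms, the female calling rate that the trains
alternate with).

## Duet simulation

The female emits FS-1 at her repetition time. Each emitted FS-1 triggers
one MS-1 after a truncated-normal latency (default 600 ± 150 ms; no
published value exists, so the default is set low enough relative to the
female pulse duration that natural overlap occurs, as it does on plants). A
pending FS-1 whose onset falls inside an ongoing MS-1 is suppressed with a
Bernoulli `inhibition_probability` (default 0.5; both outcomes occur in
nature and no rate is reported). Ground-truth overlap flags come from
interval intersection on the emitted timeline — the same computation a
brute-force oracle performs, which the tests exploit.

With `reactions_enabled`, the masking reactions are applied in one pass to
the overlap pattern of the unreacted timeline (the insects react to hearing
an overlap; the schedule is not re-planned): overlapped female pulses are
prolonged by a frequency-dependent multiplier derived from the published
control-vs-masked duration ratios (strong near 100–125 Hz, absent at 75 and
200 Hz), and overlapped male pulses switch to the U-shaped sweep with their
start frequency raised to restore a target FS-1/MS-1 start-frequency
separation (default 48.5 Hz). Relative source gains at the recording point
are free parameters of the substrate model; the package defaults to equal
gains.

## Substrate

The plant is a flat-gain summing junction with additive Gaussian noise,
white within 20–500 Hz (substrate noise is uncharacterised; band-limited
white noise provides the "noise level" the segmentation rule needs).
Bending-wave dispersion, resonance and amplitude–distance profiles are out
of scope — no transfer functions are available to parameterise them
honestly, and none of the measured quantities here depend on them.

## Measurement conventions

- **Envelope**: analytic-signal (Hilbert) magnitude smoothed by a centred,
  odd-length moving average (default 2 ms). The smoothing window must stay
  well below the beat period being measured; the interference path defaults
  to 0.5 ms, adequate for beat rates to 100 Hz.
- **Threshold**: `k ×` RMS of the raw trace in a silent interval. `k = 2`
  is the package default. For interference-pulse segmentation `k = 3` is
  used and recommended: the noise envelope is Rayleigh-distributed, so it
  exceeds `2×RMS` with probability ~0.14 per correlation time — enough to
  bury a large fraction of the brief envelope minima between beat pulses
  and to fire spuriously in silence (measured: ~120 false pulses in 5 s of
  silence at `k = 2` versus ~4 at `k = 3`).
- **Segmentation**: onset at the upward envelope crossing of the threshold,
  offset at the downward crossing of 90% of it (hysteresis against ripple);
  sub-threshold gaps shorter than `min_gap` (default 3 ms) merged, pulses
  shorter than `min_duration` (default 5 ms) discarded. The interference
  path uses `min_gap = 0.3 ms` (a beat minimum at Δf = 100 Hz lasts under
  2 ms and must not be merged) while keeping `min_duration = 5 ms`, which
  removes sub-beat noise pops (threshold excursions of the background last
  about one noise correlation time, ~1 ms) without touching real beat
  pulses, which last ≥ ~8 ms for Δf ≤ 100 Hz.
- **Dominant frequency**: magnitude-spectrum peak of the mean-removed,
  Blackman-Harris-windowed segment, zero-padded to a ≤ 0.5 Hz grid,
  restricted to 20–500 Hz, parabolically interpolated. Segments must be at
  least 50 ms. For a windowed linear chirp the peak sits at the sweep's
  centre frequency; for the plateau shape it sits at the plateau frequency
  (the flat third concentrates the energy). These are the values the
  round-trip recovery tests expect.
- **FM metrics**: dominant frequency over the first and last 500 ms of the
  pulse (plus a centred middle window on request); for pulses shorter than
  1500 ms the window shrinks to a third of the duration so the windows
  never overlap. `fm_per_1000ms` divides the start/end difference by the
  duration.
- **Sectioned interference measurement**: pulses inside a masked region are
  assigned to consecutive 1000-ms sections by onset; each section reports
  mean, sd and count, with the region's Δf attached. Δf of a region is
  taken from region-wise dominant frequencies (instantaneous Δf tracking of
  two simultaneously frequency-modulated signals is not attempted).
- **Envelope periodicity**: the envelope spectrum is magnitude-averaged
  over half-overlapped one-second Blackman-Harris windows; without
  averaging, speckle alone makes the maximum of even an aperiodic
  envelope's spectrum ~3× its median. Modulation depth uses the 5th/95th
  envelope percentiles.
- **Statistics**: Student's two-sample two-tailed *t* test by default
  (Welch switchable) and one-way ANOVA; zero-variance degeneracies report
  `t = 0, p = 1` (identical) or an infinite statistic with `p = 0`.

## Numerical limitations worth knowing

- The analytic envelope of a hard-gated (zero-rise) tone has ~1/t edge
  precursors: at a threshold of 10% of amplitude they extend a rectangular
  pulse by ~7 ms total. Default pulses have 10% ramps, which make the
  effect negligible; for rectangular stimuli keep thresholds at or above
  ~25% of amplitude when edge accuracy matters.
- The spectral peak of a broadband noise pulse cannot be localised below
  the segment's intrinsic resolution `1/T` (zero-padding adds grid points,
  not information): for a 58-ms courtship pulse that is ~17 Hz, and
  per-pulse peak estimates scatter accordingly. Recovery checks therefore
  compare the median over many pulses at the natural-bin tolerance.
- Durations are quantised to one sample (0.24 ms at the default rate).

## What the synthetic data does and does not show

The generator reproduces the time/frequency statistics of the songs and the
physics of envelope superposition, so passing tests demonstrate that the
measurement definitions recover the generating parameters and that beating
quantitatively explains the frequency-dependent pulsed amplitude pattern of
overlapped calls. It does not emulate plant filtering (resonance,
dispersion, frequency-dependent attenuation), within-pulse amplitude
structure beyond a trapezoid, or behavioural variability beyond
truncated-normal parameter draws and Bernoulli inhibition — so agreement
with natural recordings is expected only where those factors are secondary.
In particular, mean interference-pulse durations measured at Δf = 6 Hz on
real plants can exceed the analytic beat period of 166.7 ms; in this model
that is impossible by construction (a pulse cannot outlast its beat
period), and the simulated value at Δf = 6 Hz lands just below the period
instead. Test and script problem sizes are desk scale — traces of a few
seconds, five-fold replication for stochastic means, 200 replicates for
significance rates — chosen so the whole suite reruns in seconds.
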