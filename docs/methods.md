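# Methods

This note records the models, numerical choices, and known limitations of
ephyskit, in the spirit of a package's own methods documentation: what is
computed, under which assumptions, and what passing tests do and do not
demonstrate.

## Data model

All streaming computation operates on `SampleBlock`s: a channels × samples
matrix of voltages in µV at a fixed sampling rate, tagged with the absolute
sample offset of its first column.  A recording is an iterator of such
blocks.  Every streaming operator carries its filter state across blocks,
so chunked processing is sample-for-sample identical to processing the
concatenated stream; the test suite asserts this block-boundary invariance
to 1e-9 µV for all streaming filters.  Filters are causal (not zero-phase)
because the system models an online rig where the future is unavailable.

## Surrogate recordings

The generator emulates what an extracellular electrode sees, as a sum of
four components per channel:

- Gaussian background noise (default SD 8 µV, about the level of a decent
  headstage plus neural background);
- one slow oscillation (default 2 Hz, 40 µV, random phase per channel) as
  a stand-in for slow cortical rhythms;
- mains hum (default 60 Hz, 20 µV) with a *common* phase across channels,
  since line pickup is shared across the array;
- extracellular action potentials from a per-channel set of units placed
  at homogeneous-Poisson times with a 1 ms refractory period enforced by
  thinning.

The spike template is a biphasic (negative-then-positive) sum of two
Gaussians: trough width σ = 0.09 of the total template width (1.2 ms
default, so FWHM ≈ 0.25 ms), followed by a positive afterwave of 0.2×
the trough amplitude at 0.58 of the width.  The positive-lobe parameters
were chosen so that the waveform's *causally band-passed* image has a late
undershoot below 6% of its trough: steep causal high-pass stages
necessarily produce a charge-balancing rebound, and an unrealistically
sharp or unbalanced template retriggers any threshold detector on its own
tail.  The template is rescaled after construction so the trough depth
equals the requested amplitude exactly.

Determinism: all randomness derives from one root seed through
`numpy.random.SeedSequence.spawn`, one child per channel, so each channel
is reproducible in isolation and two runs with the same seed are
bit-identical.

What the surrogate does *not* model: electrode drift, spike-waveform
nonstationarity, bursting (amplitude adaptation), spatial spread of a unit
across neighbouring channels, and impedance beyond a per-channel gain.
Detection and sorting scores on surrogate data are therefore upper bounds
on real-data performance; the tests demonstrate correctness of the
pipeline, not field-grade sorting accuracy.

Two deterministic signals support integrity checks of the acquisition
path.  The periodic pattern is a per-period linear ramp (every phase a
distinct level, identical on all channels) so that the peak-to-peak
amplitude of every complete period is exactly constant; the bath-sinusoid
signal is one sinusoid scaled by per-channel gains (emulating electrode
impedance differences) plus independent noise.

## Filtering

- Band filters are Butterworth, applied causally with persistent
  second-order-section state.  `FilterSpec.order` is the true filter
  order; for band-pass designs the underlying prototype order is half of
  it, since a band-pass doubles the prototype's order.  The default
  4th-order realization keeps the spike-band step response tight; an
  8-pole band-pass was rejected because its undershoot on spike-shaped
  transients reaches half the trough amplitude, which defeats threshold
  detection.  Defaults: LFP = low-pass 300 Hz; spike band = 300–6000 Hz,
  with a 300–7000 Hz variant available as a preset.
- The line-noise notch is a second-order IIR notch with a 4 Hz −3 dB
  bandwidth at 50 or 60 Hz (other frequencies allowed with a warning).
  Measured steady-state attenuation at the notch exceeds 30 dB, with
  passband change below 1 dB a decade away.
- The consecutive-averaging filter removes regularly repeating,
  non-sinusoidal noise by subtracting the running mean of the last
  `n_periods` periods at each phase.  Integer periods use an exact
  per-phase FIFO; non-integer periods (60 Hz at 31.25 kHz is 520.83
  samples) accumulate phase fractionally and read/write a 1-sample
  template grid with linear interpolation, with the per-bin history kept
  as an `n_periods`-deep running mean.  On white noise the output variance
  inflates by at most `1/n_periods` plus sampling error, as expected for
  subtracting an n-period mean.
- Common average referencing subtracts, per target group, the per-sample
  mean of its reference channels.  With all channels referenced to all
  channels the operation is idempotent and forces an exactly zero
  cross-channel mean.
- The short-time spectrum is a Hann-windowed PSD (scipy spectrogram,
  density scaling), defaults 0.5 s window, 50% overlap; integrating a
  frame over frequency recovers that frame's power.  Band summaries use
  delta < 4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–80 Hz; the band
  names are standard, the edges a documented convention.

## Spike detection and sorting

The automatic threshold is `-k σ̂` (negative polarity) with
`σ̂ = median(|x - median x|)/0.6745`, the MAD-based noise SD, which the
spikes themselves barely perturb; default `k = 4`.  A constant input has
σ̂ = 0 and is rejected as an invalid threshold rather than silently
producing zero.

Detection registers an event at the first sample beyond threshold,
suppresses further crossings for a 1 ms refractory period, aligns the
waveform on the extremum adjacent to the crossing, and cuts 0.5 ms before
to 1.0 ms after it; incomplete windows at stream edges are dropped.  At
`k = 4`, band-passed Gaussian noise itself crosses threshold at close to
1 event/s (the Rice upcrossing rate `ν₀·exp(-k²/2)` for an effective
bandwidth of a few kHz), a floor independent of spike amplitude.
Detection precision therefore depends on the true multiunit rate; the
test suite evaluates the ≥95% recall/precision property on a busy
electrode (4 units × 8 Hz ≈ 32 Hz multiunit, every unit at SNR ≥ 10),
which is where such a detector is meant to operate.

Sorting reduces each waveform to (V_max, V_min, trough-to-zero-crossing
time), z-scores the three features, and projects them onto their first
principal axis (sign fixed for determinism) to obtain one scalar per
spike — the "one-dimensional variable".  Deterministic 1-D k-means
(sorted-quantile initialisation) is fitted for k = 1..4.  A candidate k is
valid if its smallest cluster holds ≥1% of events and every pair of
neighbouring clusters is separated by d' ≥ 2 (gap between centres over the
sum of within-cluster spreads).  Among valid candidates the largest
silhouette wins, ties resolving to the smaller k; with no valid candidate
all events form one cluster.  The separation floor exists because
silhouette alone cannot distinguish a split unimodal cloud (measured
0.49–0.59) from genuine multi-unit structure compressed into four
clusters (measured ≈0.68); an artificially split unimodal Gaussian scores
d' ≈ 1.3, well under the floor.  Labels are renumbered by descending mean
|V_min|, so unit 0 always carries the largest spikes, and the whole
procedure depends only on the multiset of events (order-invariant).  Four
units per electrode is a hard cap.  The zero-crossing feature is
implemented as the trough-to-first-sign-change *time* (window end as a
sentinel when the waveform never crosses zero); a crossing *count* would
be an alternative reading.

The sorter is pluggable through a registry: any callable with the same
signature can be registered and selected by name.

## PSTH and CSD

The PSTH is a running mean over trials — spike counts per bin (10 ms
default) or an LFP trace — updated as
`mean ← mean + (trial - mean)/n`, which is algebraically the batch mean,
so incremental and batch accumulation agree to machine precision and the
result is invariant to trial order.  Trial conditions are not
distinguished.

CSD uses the classic three-point second spatial difference along one
shank's depth column: `CSD_i = -σ (V_{i-1} - 2V_i + V_{i+1})/Δz²`,
default σ = 0.3 S/m (with σ in S/m and V in µV over µm, the result is in
µA/mm³); passing `sigma_s_per_m=None` returns the unscaled second
difference in µV/µm², since reports differ on whether printed CSDs are
conductivity-scaled.  Edge electrodes are dropped (no padding); spacing
must be uniform to 1%.  Depth columns come from the array geometry:
electrodes sharing a planar location (coordinates compared after rounding
to 0.1 µm, guarding against config-file formatting noise) form one
column, sorted by depth; columns of fewer than three electrodes are
flagged CSD-incapable.  The depth axis defaults to z for 3D arrays and
the longer axis for 2D arrays, overridable per array.

## Acquisition engine and raw format

A trial is prepared (files opened), armed, and started by a trigger
event — the software stand-in for the hardware digital start line; no
samples flow before the trigger.  Every block is written to disk first;
display/processing callbacks run afterwards inside protection that counts
and logs exceptions without interrupting acquisition.  Disk-write
failures are deliberately *not* protected and abort the trial with an
error status.  Out-of-range samples are clipped and counted, never
raised mid-trial.

The raw format is int16, little-endian, channel-interleaved frames
(`<base>.i16raw`) with a JSON sidecar carrying sampling rate, channel
count, µV-per-LSB scale, geometry name, start time, sample and clip
counts.  The scale defaults to `input_range/32768`, so the full input
range fits int16 and the round-trip error is at most half an LSB; values
already on the int16 grid round-trip exactly.

Reliability checks: in periodic mode the recording is folded into
consecutive periods per channel; the maximum deviation of the per-period
peak-to-peak amplitude from its median must be exactly zero, and the
cross-correlation peak lag of every channel against channel 0 must be
exactly zero samples (computed by FFT cross-correlation with zero-padding,
which breaks the circular ties of a perfectly periodic signal in favour of
lag 0).  In sinusoid mode channels are RMS-equalized first (undoing the
per-channel gains), lags must vanish modulo one period within a 1-sample
jitter tolerance, and the correlation period is estimated from the
dominant frequency of the channel-vs-channel-0 cross-spectra (magnitude
averaged over channels, parabolic interpolation around the peak bin); its
reciprocal recovers the injected frequency.  The acceptance run uses 16
channels for 60 s at 31.25 kHz — large enough that a single dropped
sample or a one-sample channel offset is detected, small enough to run on
one CPU in well under two minutes.

## Remote control

Messages are `COMMAND | DATA !` lines (UTF-8, one per line): command and
payload separated by a vertical bar, terminator `!`; commands without
payload omit the bar.  Payloads may not contain the terminator; this is
rejected at message-construction time, as the wire syntax has no escaping.
The command set is INIT (name a recording), START (arm a trial; samples
flow only on the trigger), STOP (finalize), COMTEST (ping), RUNFUN,
GETVAR/SETVAR (session variables, serialized as text).  Replies are
`OK | detail !` / `ERR | detail !` lines — the reply grammar is this
package's own convention.  The acquisition side is the TCP *client* and
dials the controller, so several engines can serve one controller.
RUNFUN executes only pre-registered routine names: remote evaluation of
arbitrary code strings was deliberately not implemented, a behavioural
difference from lab-internal remote-eval conventions, because an open
socket must not be an eval server.  START's payload is parsed as
`<base>-<trialindex>` when it matches that pattern, else used verbatim.

## Capacity planning

Analog cards contribute `slots × channels_per_card` channels; digital
cards `cards × usable_lines × channels_per_line`, with one line per card
reserved for the trial trigger (15 of 16 usable on the shipped digital
preset: 15 × 96 = 1440 per card).  Disk bandwidth is
`channels × f_s × bytes_per_sample` in decimal MB/s (10⁶ bytes), the
convention under which 1440 channels at 31.25 kHz and 16 bits come to
90 MB/s.  Presets cover 32-channel analog cards at 25 kHz (7 PCI or 18
PXI slots), an 80-channel 9.375 kHz card, and the digital configuration
above.

## Problem sizes and limitations

Test and acceptance runs use deliberately modest sizes — tens of seconds
at 25–31.25 kHz, 1–16 channels, a thousand short trials for the
protection property — chosen so the full suite exercises every contract
on a single CPU.  The engine is synchronous: the trigger pulls blocks in
the foreground, which is faithful to trial semantics (sample conservation,
write-first protection) but does not model concurrent display load or
real-time deadlines.  Timing claims (intertrial latency, draw rates) are
out of scope, as are DAQ driver bindings, GUI rendering, audio output
devices, and offline template-matching sorters.
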