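# Methods

This note records the models, defaults and numerical choices behind
`ripplepipe`, and what the synthetic test-bed does and does not establish.

## Synthetic data model

**Trajectory.** Exploration is a mean-reverting (Ornstein–Uhlenbeck)
velocity process integrated at the tracker step (25 ms) with reflective
walls. The stationary speed distribution is approximately Rayleigh; the
default mean speed of 8 cm/s and velocity autocorrelation time of 0.7 s
were chosen once as typical of a mouse exploring a novel enclosure, and
make the default 24-min walk space-filling (>90% of 2-cm bins of a
60×60 cm arena visited). Real mouse trajectories are not OU processes —
they have wall-following, immobility bouts and goal-directed runs — but
any smooth space-filling walk suffices for the map statistics exercised
here. Arena sizes are not constrained by the study design; 60×60 cm is a
nominal default, configurable.

**Place cells.** Each cell is a single 2-D Gaussian field:
λ(x) = b + A·exp(−‖x−c‖²/2σ²), with σ = 5 cm, peak A uniform on
4–12 Hz and baseline b = 0.1 Hz by default. Between the two exposures the
centre is displaced by a per-cell drift magnitude in a uniformly random
direction (rejection-sampled to stay inside the arena, with a clamped
fallback) and the peak is multiplied by a rate-scale factor; drift 0 and
scale 1 reproduce the session-1 model exactly. Multi-field cells, theta
modulation, directionality and interneuron dynamics are out of scope.

**Spikes.** Inhomogeneous Poisson: per tracker step, a Poisson count with
mean λ(x(t))·Δt, placed uniformly within the step. This is exact for the
piecewise-constant rate and leaves no refractoriness or burstiness; the
cofiring and map statistics therefore see pure Poisson variability,
which is the relevant null for parameter-recovery tests but flatters
real-data noise.

**Sleep LFP.** Two channels at 2 kHz (full ripple band with margin; the
in-vivo system digitized far faster, but only the <400 Hz content is
analysed): a stratum-pyramidale channel of 1/f-amplitude-shaped Gaussian
background (SD 200 int16 units) plus ripple bursts, and a radiatum
channel of independent background plus concurrent negative sharp waves
(half-amplitude width ~28 ms, 4× background SD). Ripples are Gaussian-
enveloped sinusoids at 160 Hz — the predominant ripple frequency — with a
7-cycle (~44 ms) envelope, amplitude 5× the SD of the band-passed
(100–250 Hz) background, random phase, Poisson event times thinned to a
0.3 s minimum separation at 0.3 events/s. Ground truth records the ±2
envelope-SD support of every injected burst. When the background SD is
zero the amplitude reference falls back to 200 int16 units.

**Suppression.** Each spike inside a light pulse is deleted independently
with probability equal to the suppression level (default 0.8 for
"strong"); an optional rebound appends Poisson spikes at 2× the unit's
mean rate in the 50 ms after each pulse (off by default — rebound is
displayed in the source experiments but never tested).

**Session timeline.** The default simulated day is 20 min pre-sleep,
24 min exploration 1, three 20-min recorded sleep blocks with closed-loop
stimulation, 24 min exploration 2, 20 min post-sleep, and a 30-min
half-intensity regular-pulse sleep used for per-cell inhibition testing.

## Detection

The analog detector is emulated as: differential signal (pyramidale −
radiatum) → causal 4-pole Butterworth band-pass → gain 10 → rectified
comparator. The device's center frequency (150 Hz) and pole count are
known but its bandwidth and comparator setting are not; the band defaults
to 100–200 Hz (bracketing the ripple band; an order-2 band-pass design
has the 4 analog poles) and the threshold to 4 SD of the filtered signal,
both configurable. Each upward crossing outside an active pulse emits a
200 ms TTL; TTLs cannot retrigger while active and there is no extra
refractory period after offset. Delayed (control) mode shifts the laser
onsets by exactly 1.32 s — a pure sample shift, so pulse count and total
duration (light energy) are identical between modes by construction.

The offline detector is deliberately non-stringent: zero-phase band-pass
(100–250 Hz), rectification, 10 ms moving-average envelope, z-score
against whole-session statistics, threshold 2 SD, events of 15–500 ms
with gaps under 10 ms merged. Its purpose is to find truncated,
low-amplitude event remnants that the stringent online path misses.

Detection evaluation matches detected onsets to ground-truth events
greedily (earliest unmatched detection within the event ± tolerance,
default 50 ms); latency is reported in seconds and in ripple cycles
(latency × 160 Hz). At the default amplitudes the online threshold sits
near the envelope peak, so online recall is deliberately partial (~50–70%)
while precision stays high — matching the stringent-online /
non-stringent-offline division of labour.

## Spectra

Multi-taper estimates use DPSS tapers with time–bandwidth NW = 3 and 5
tapers on 150 ms windows (unreported in the source; standard defaults,
configurable). Windows are mean-subtracted; power is one-sided and scaled
so that its integral equals the segment variance. The event-triggered
spectrogram tiles 150 ms windows at 75% overlap across ±1 s around each
event; events whose span leaves the signal are dropped, and a zero count
of usable events is an error. `align_shift` subtracts a constant from the
event times before alignment, so delayed-mode laser onsets with
`align_shift = 1.32` reproduce the TTL-aligned map bin-for-bin. The
normalized spectrum subtracts the mean spectrum at events + 400 ms from
the mean at events; it is signed by design. At 2 kHz and 150 ms windows
the frequency resolution is 6.67 Hz, which places 160 Hz exactly on a bin.

## Maps and stability

Occupancy uses 2 cm square bins, a 2.5 cm/s speed filter (on for
explorations, off for whole-session mean rates), and a 0.1 s minimum
occupancy for bin validity. Spikes are positioned by linear interpolation
of the tracker and pass the same speed filter. Smoothing (Gaussian,
σ = 1 bin) is applied to counts and dwell separately before division.
None of these values are reported in the source study; they are the
field's standard choices and all sit in the configuration. Sparsity is
computed on the (smoothed) map actually supplied; spatial coherence is
always computed on the unsmoothed map — the metric's usual convention —
with an optional Fisher z transform (off by default), and requires at
least 8 valid bins with valid neighbours.

Rate change uses whole-session mean rates with the speed filter off.
Map correlation uses only bins valid in both maps (≥10 by default) and
returns NaN for zero-variance maps, excluding the cell. Cofiring uses
250 ms temporal bins (unreported; configurable — coarser bins raise all
coefficients, finer bins shrink them toward zero, and the cross-session
similarity is much less sensitive than the individual coefficients);
pairs require both units to carry ≥10 spikes and nonzero count variance
in a session, with exclusions recorded. The per-pair-per-session quantity
is a scalar Pearson correlation over temporal bins, and the cross-session
similarity is the Pearson correlation of those scalars across pairs —
the only reading under which a Fisher Z comparison with n = number of
cell pairs is coherent. The alternative reading (per-pair binwise product
vectors) is noted but not implemented.

## Inhibition testing

Per pulse, the in-pulse spike count is paired with the count in the
pulse-length window immediately preceding onset (the referenced
prior method's exact baseline is not restated in the source; this is the
natural paired design). A two-sided Wilcoxon signed-rank test (zero
differences dropped; exact null for ≤25 informative pairs, normal
approximation above) gives the per-cell p; direction follows the sign of
the median nonzero difference at α = 0.05, with no multiple-testing
correction across cells (per-cell significance is reported raw, as in the
source). All pairs tied means no evidence: p = 1 (or NaN for a fully
silent unit), direction "unchanged". ANOVA and KS tests delegate to
scipy; both are cross-checked in the test suite against independent
sums-of-squares and ECDF-scan oracles at 1e-10.

## Determinism and problem sizes

Every generator accepts a seed and returns bit-identical output for
identical parameters; the day pipeline spawns per-stage seeds from one
root seed, and identical configuration yields a byte-identical report.
The test suite and the acceptance script use scaled-down problem sizes
chosen to keep the statistics well-resolved at interactive runtimes:
2-minute sleep segments (~60 events) for detection properties, 10 minutes
(~130 events) for spectral recovery, 200 map pairs for the null
correlation, 50 cells × 600 pulses for inhibition efficiency, and 24-min
explorations for map/cofiring recovery.

## Limitations

Passing tests on this generator demonstrate correctness of the analysis
chain and recoverability of known parameters — not that the defaults
reproduce the full statistics of in-vivo data. In particular the
generator has no theta/behavioural-state structure, no spike sorting
errors, no bursting or refractoriness, no eSWR events during exploration
(their exclusion from rate computations is therefore moot here), no
light-evoked field artifact, and sleep spiking during the pulse sleep is
homogeneous Poisson. The day-exclusion rule (>5 min of continuous
movement during the middle sleep) is implemented against tracking data
and skipped with a logged notice when no tracking exists during sleep,
as in the fully synthetic day; wake/sleep staging beyond that movement
rule is out of scope.
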