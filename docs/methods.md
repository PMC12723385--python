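# Methods

This note documents the models and procedures the package implements, the
choices made where the methods literature leaves the design open, and what
the synthetic-data tests do and do not demonstrate about real recordings.

## Midline kinematics

A tracked tadpole is 11 ordered points p1 (head extremity) to p11 (tail
tip), assumed equidistant at body_length/10 even though real tracked
spacing varies slightly. At each interior point the curvature angle is the
angle between the vector arriving at the vertex and the vector leaving it,
`arccos(a.b/|a||b|)`. The arccos form is unsigned; bipolar angle traces
require a sign, which we take from the orientation of the turn in the
tracking plane (z component of a x b), left bend positive. A frame with
coincident consecutive points yields NaN for all nine angles of that frame
rather than a silent zero, because a partial sum would bias the
sum-of-angles trace.

The sum of the nine angles summarises body shape: |sum| near 2 pi is a
C/O-shaped coil, near pi an S-shaped struggle, at or below 0.5 pi a
swimming bend. Traces are low-pass filtered with a 4th-order Butterworth
at 50 Hz (cutoff from standard practice for 240 fps tracking; the order
and the zero-phase forward-backward application are our choices — a causal
filter would add a frequency-dependent lag that biases the propagation
regressions). Filtering is linear, so the filtered sum equals the sum of
the filtered angles exactly.

**Half cycles** are bounded by zero crossings of the mean-subtracted sum
trace; each holds one extremum, and its amplitude is half the difference
between that extremum and the adjacent opposite one (a sinusoid of
amplitude A yields half cycles of amplitude A and duration 1/2f). The
alternative segmentation — extremum to extremum — gives the same durations
for near-sinusoidal rhythms; zero crossings are less sensitive to flat
extrema.

**Classification** uses amplitude bands centred between the observed class
means (coiling ~4.1 rad, struggling ~2.4 rad, swimming ~1.0 rad):
coiling at |amplitude| >= 3.2 rad (initial vs transitional decided by a
caller-supplied release marker), struggling at 1.2-3.2 rad with
caudorostral or synchronous propagation, swimming at < 1.2 rad with
rostrocaudal propagation. Everything else is `unclassified`, with the
amplitude distance to each band reported. The thresholds are configurable.

**Propagation speed** cross-correlates each angle trace against a
reference angle (alpha4 by default) and regresses the lag nearest zero on
vertex position; the speed is -1/slope so that caudorostral (tail-to-head)
propagation is positive everywhere in the package. Numerical choices:

* The search window is +/-0.6 of the dominant cycle period (from the
  Fourier amplitude peak). "The peak close to zero" then has an exact
  meaning: the correlation maximum inside the window, because the
  one-cycle-away aliases sit outside it. Taking the *maximum* rather than
  the literal nearest-zero local maximum also makes the estimate immune to
  ripple riding on the correlation envelope (the in-burst event rhythm of
  smoothed burst traces produces such ripple).
* The correlation is normalised by the lag-dependent overlap count.
  Without this the triangular envelope of finite-length correlation pulls
  large lags toward zero and inflates recovered speeds by 5-10% for slow
  waves.
* Lags are refined to sub-sample precision by parabolic interpolation
  through the peak — necessary at 240 fps, where swimming lags between
  neighbouring vertices are ~3 ms against a 4.2 ms frame interval.
* Estimates are reported `synchronous` (no finite speed) when every lag is
  below one sample or the regression p-value is >= 0.05.

**Curvature origin.** Struggling bends can diverge from a point about
two-thirds down the body, travelling toward head and tail simultaneously.
Per-angle timing is taken as the cross-correlation lag against the sum
trace; for each candidate split vertex two lag-vs-position regressions are
fitted (rostral and caudal of it), and the split minimising the pooled
squared residual under the opposite-slope constraint is the origin.
Branch speeds are -1/slope, so the rostral branch is positive and the
caudal branch negative. A non-significant caudal fit is reported as "no
caudal propagation detected" (seen in about a third of real videos); with
no valid split the origin is undefined.

**Yaw** is the peak-to-peak excursion of the p1->p2 heading angle within
a cycle, in degrees.

Missing or low-likelihood tracked points are linearly interpolated across
gaps of up to 3 frames at read time; longer gaps stay NaN and drop out of
the regressions.

## Burst and rhythm statistics

Traces are digitised extracellular recordings (>= 5 kHz; 10 kHz typical).
Preprocessing zeroes declared stimulus-artifact windows, full-wave
rectifies, and smooths with a 2.5 ms moving average iterated 4 times
(impulse response: the boxcar self-convolved four times, near-Gaussian).
The moving average uses circular boundary handling so the trace mean is
preserved exactly; for traces thousands of windows long the wrap-around
is negligible. `iterations=0` gives the rectified-only trace used for
per-spike event triggering; the smoothed version serves cross-correlation
and burst-envelope work.

**Event triggering** places the crossing level k standard deviations
(k = 5 by default) above the mean of a quiet baseline window. Referencing
the mean matters on rectified traces, which have a positive noise floor;
a bare k*sd level can sit below the floor and never be crossed upward. A
1 ms refractory period prevents double-triggering on one potential.

**Bursts** merge events closer than `max_gap` (15 ms by default, just
above the 13 ms bound separating within-burst from between-burst
intervals). Duration is last-minus-first event; cycle period the interval
between burst starts; duty cycle mean duration over mean period.
`min_events` discards stray sub-threshold groups — the automated stand-in
for the visual inspection that rejects isolated noise events between
cycles.

**Rhythmicity index.** Consecutive inter-event intervals are histogrammed
(5 ms bins by default; the bin width is always reported with the result),
smoothed with a 3-bin moving average, and
R = (peak - trough)/(peak + trough) computed from the initial peak, the
deepest trough after it, and the dominant later peak. Implementation
choices that make R stable on realistic histograms:

* Zero padding at both ends lets boundary modes register as peaks, so a
  perfectly periodic train (single isolated mode, empty bins elsewhere)
  scores R = 1 exactly.
* A lone mode starting at the zero-interval boundary is the signature of
  a monotone-decaying, Poisson-like histogram: R = 0, flagged.
* The "following peak" is the *tallest* later peak, not the first local
  bump: with a triggered noise floor, 1-count singletons otherwise win
  and randomise R. On Poisson trains R stays below ~0.15.

R lies in [0, 1] and is invariant to uniform time rescaling when the bin
width is rescaled identically.

**Two-channel propagation** uses the same windowed cross-correlation
machinery on preprocessed same-side channels;
speed = -(position difference)/delay, caudorostral positive. Sub-sample
delays flag the pair synchronous. The estimator is antisymmetric under
channel swap.

**Spike-phase calibration.** Motoneuron spike phases within struggling
cycles are (spike - onset)/period minus the rostrocaudal conduction
delay (0.185 - 0.00225 x period) x L/1.65, with 0.5 added for
contralateral recordings and the result wrapped to (-0.5, 0.5] (boundary
to +0.5). The period in the calibration is in seconds — in milliseconds
the delay would already be negative at observed struggling periods, which
settles the unit ambiguity.

## Surrogate motoneuron commands

The default roster places 311 motoneurons per side between 0.5 and
4.8 mm from the mid/hindbrain border: 248 in the classical 0.5-3.0 mm
backfill range plus a caudal extension whose density falls from 4 to 2
cells per 100 um (10 bins of 4, 7 of 3, 1 of 2). Only those totals are
constrained by counting data; the rostral bin-by-bin profile packaged
here is a synthetic digitization (descending 15 -> 5 per 100 um) pinned
to them. Somata are spread evenly inside each bin, so the roster is
deterministic.

Commands are built per side, per neuron (in position order), per cycle,
with every random draw flowing from one integer seed:

* **Struggling** (default 4 Hz, 8 cycles): left/right bursts in
  anti-phase; burst onsets follow the position-delay map
  (x_ref - x)/v, caudal neurons leading at +40 mm/s; spike count per
  burst is a discretised normal truncated at >= 1, with mean and SD
  interpolated between the recorded group centroids (6.1 +/- 4.1 at
  ~1.0 mm, 1.9 +/- 0.9 at ~2.25 mm, clamped outside — the groups were
  defined as < 1.5 mm and 1.5-3 mm); inter-spike intervals are
  inverse-transform draws from the empirical CDF of an ISI sample
  truncated at 13 ms. Bursts exceeding the local duty window (linear
  0.40 at 0.5 mm to 0.60 at 4.8 mm) are truncated with a warning.
* **Swimming** (20 Hz): one spike per neuron per cycle, rostrocaudal at
  -130 mm/s. **Reverse** variants regenerate with the propagation speed
  negated and the same seed, so each neuron keeps its spike multiset
  while the delay map flips; reversing twice restores the original to
  1e-9 ms.
* **Initial coil**: one burst of exactly 15 spikes per neuron on the side
  opposite to stimulation, onset spread under 1 ms across the roster.

The recorded ISI samples are not available, so the packaged default
source is a synthetic stand-in: log-normal with median 5 ms (sigma 0.5
rostral, 0.6 caudal), truncated to (0, 13] ms by resampling, generated
deterministically. Any measured sample can be swapped in through
`CommandConfig.isi_source_*`; a two-sample rank test cannot distinguish
generated ISIs from their source at alpha = 0.01.

The configured duty profile bounds burst length; it is not the emitted
burst duration, since the recorded spike counts and 13 ms-truncated ISIs
produce bursts of a few tens of milliseconds. The closed-loop tests
therefore verify frequency and propagation against the configuration and
duty against the table's own burst statistics.

## Grip, drag and lever mechanics

Compression Delta-w is dimensionless: the compressed distance divided by
the head width (0.83 mm). Contact area per forceps tip is
A = 1.35 Dw - 0.0043 mm^2, clamped at zero below the formula's small
positive root (tiny-compression behaviour is otherwise undefined). Hooke
friction is 2 mu E A(Dw) Dw with mu = 0.08 (from the 4.5-degree slide
angle, mu = tan alpha) and E = 700 Pa, expanding to
151.2 Dw^2 - 0.48 Dw uN; the simulation-fitted alternative is
49 Dw^2 + 19.8 Dw uN. Both are exposed; they agree closely only where
the curves cross (Dw ~ 0.17-0.24) and differ by tens of percent at small
compressions, consistent with the imprecision of the contact-area
estimate. Neither is privileged.

The side-view body is an ellipse with a = body_length/2 = 2.5 mm and b
fixed by the 4.95 mm^2 total side area; section areas are exact
elliptic-segment integrals, hence additive over any partition. Section
masses default to area-proportional shares of a 141.41 mg body and are
fully configurable.

Pressure drag per section is zeta A_proj rho v^2 / 2 (zeta = 1.18)
directed against the section-centre velocity (the mean of its endpoint
velocities), where A_proj = A sin(angle between section axis and
velocity) — full area broadside, minimal axially. The formula is a
broadside approximation: frames where sections move within 15 degrees of
their own axis are counted in a `low_validity` column rather than
silently trusted. Skin-friction drag is neglected; at the struggling
Reynolds number (~190 for 85 mm/s over 2 mm in 0.00089 Pa s water)
pressure drag dominates. Mass x acceleration uses central differences of
the section mass-centres, optionally after a 50 Hz zero-phase low-pass
(the differentiation scheme is our choice); 2D input is lifted to z = 0
and all force outputs keep three axes.

The lever model: F2 = F1 L1 / L2, F2x = F2 cos(alpha); escape when F2x
exceeds the grip friction. The fulcrum position and the moving-segment
set that defines F1 are caller inputs, not inferred.

## Synthetic data: what it emulates and what it does not

`make_tracked_movement` builds midlines whose vertex angles are sinusoids
sharing one frequency, with phases set by the propagation map (uniform
travelling wave, synchronous, or bidirectional diverging from an origin
fraction) and a common amplitude scaled so the sum-of-angles trace peaks
exactly at the configured value. Coordinates are integrated head-to-tail
with exact per-segment rotations, so coiling shapes (|sum| near 2 pi) are
representable without small-angle error; i.i.d. Gaussian noise is added
to coordinates. Presets for the four movement types are centred on the
observed class means (coiling 4.1 rad / 2.7 Hz, struggling 2.4 rad /
4 Hz / +42.5 mm/s, transitional 4.0 rad / -218 mm/s, swimming 1.0 rad /
20 Hz / -156 mm/s).

`make_vr_traces` renders bursts of biphasic spike waveforms on Gaussian
noise, with burst onsets following the longitudinal delay map, optional
per-channel onset jitter and dropout (applied independently per event and
per whole burst, emulating the sporadic bursting seen toward the tail),
at 10 kHz. A quiet lead-in long enough for three jitter SDs keeps the
baseline window clean for threshold estimation.

These generators emulate the *timing structure* of the data, not its
physics: midline waves are kinematic (not hydrodynamically consistent),
spike waveforms are identical copies (no amplitude variation, no
overlapping units), and noise is white. Passing the closed-loop suites
therefore demonstrates that the estimators recover known parameters under
realistic timing, sampling and noise-floor conditions — not that they are
robust to tracking failures, electrode drift or spike-sorting ambiguity.

Slow-wave recovery is only well-posed when the wavelength v/f exceeds
about 1.5 body lengths (otherwise distant vertices approach anti-phase
and the lag is ambiguous); the recovery sweep co-varies frequency with
speed accordingly, as the recorded rhythms do.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
movements of 1-3 s at 240 fps, traces of 4-12 s at 10 kHz, commands of
6-8 cycles over the 622-neuron roster, and 10-seed replicate sweeps —
sizes at which every estimator is well-conditioned while the whole suite
completes in well under a minute. All stochastic paths draw from
`numpy.random.default_rng` seeded per run; identical seeds give
byte-identical outputs everywhere, including file round-trips.

## Known limitations

* The rhythmicity index inherits the histogram's bin-width sensitivity;
  results always carry the bin width used.
* The curvature-origin search assumes a single divergence point and at
  least three vertices per branch; multiple origins are not modelled.
* Propagation estimates require a dominant rhythm; arrhythmic epochs are
  rejected rather than estimated.
* The drag model treats sections as rigid, independently moving plates;
  it is a screening tool, not a substitute for fluid simulation.
* The ISI stand-in and the rostral roster profile are synthetic; swap in
  measured samples where available.
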