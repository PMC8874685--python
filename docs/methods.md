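# Methods

This note records the model, the algorithmic choices, the synthetic
test bed, and the places where the design was genuinely open — in
enough detail that a maintainer can tell which behaviors are contracts
and which are judgment calls.

## Signal model and conventions

A trial is a 100 Hz stream of 3-axis accelerometer (m/s²), gyroscope
(rad/s) and magnetometer samples from a sensor on the instep, axes
X = forward, Y = up, Z = left.  The coronal-axis gyroscope (rotation
about Z) records plantar/dorsiflexion of the ankle and is the most
informative single channel for gait.  A *stride* is one full cycle of
one foot, bounded **at stance end**; its four phases in order are
pushoff → swing → heelstrike → stance, separated by toe-off (TO),
heel-touch (HT) and the settling into full foot contact, with heel-off
(HO) coinciding with the stride boundary.  All intervals are half-open
`[start, end)` in sample indices; one timestamp tick is 0.01 s.

## Template

`build_template` resamples each labeled stride segment (stance-end to
stance-end) to 200 samples by per-channel linear interpolation and
averages the selected segments sample-by-sample.  Selection takes
`ceil(0.30 · count)` strides per height group at evenly spaced
positions in time order (a seeded uniform random draw is available as
an alternative).  One global template is used at inference; per-group
templates are deliberately out of scope.  Averaging smooths the
waveform, which is also why fluctuation-type descriptors match it less
well than magnitude-aware ones (see "Descriptor behavior" below).

## Normalization

Z-normalization uses the unbiased standard deviation (divisor n−1) and
refuses constant input.  For batch processing the whole trial is
normalized at once; the template is normalized once per channel.  This
keeps query and template on a common scale while remaining a pure
per-channel affine map.

## Descriptors

Each sample is described by its `l = 31`-sample neighborhood (edge
replication at stream boundaries):

* **RAW** — the window itself (d = l).
* **PAA** — means of 5 near-equal intervals.
* **DWT** — concatenated 3-level Haar coefficients.
* **SLOPE** — least-squares line slope per interval (5 intervals).
* **DERIVATIVE** — the first-order derivative sequence of the window
  (central differences).  Implemented as the derivative itself, not as
  SLOPE applied to the derivative: a linear ramp must map to a constant
  equal to its slope, which only the former satisfies.
* **HOG1D** — per-interval histograms (2 intervals × 8 bins) of
  gradient orientations `arctan(0.1·g)`, votes weighted by gradient
  magnitude.

SLOPE, DERIVATIVE and HOG1D contain no additive-offset term and are
therefore offset-invariant (to machine precision — the offset perturbs
the floating-point inputs at the ulp level before any formula runs).

Compound descriptors concatenate one magnitude-aware and one
fluctuation-capturing block with equal weights.  Each per-sample block
vector is L2-normalized before concatenation; the two families' raw
distance scales differ by an order of magnitude, and without
normalization one block silently dominates.  The cost is that the
magnitude block then contributes only window *shape*, making compounds
somewhat more noise-sensitive than their magnitude component alone.

Template descriptors use **periodic (wrap) padding** for their window
context: a template is one cycle of a periodic signal, so the samples
"before" its first sample are the tail of the previous cycle.  Edge
replication there fabricates flat context that systematically pulls
match starts ~50–100 ms inward; wrap padding removes that bias.  Query
streams are not periodic and keep edge replication.

A single neighborhood exception: `l = 1` is admitted for RAW only, in
which case the descriptor cost degenerates to the conventional
pointwise DTW cost — useful for testing and comparison.

## Streaming matcher

The engine is the SPRING construction with shape-descriptor costs: one
(n+1)-column of accumulated distances with a permanently-zero boundary
row, plus a start-index column; per sample the column update touches
O(n) cells (the implementation is a vectorized min-plus prefix scan
over the "down" chain, tie-broken diagonal > left > down, verified
against a scalar reference on tied integer costs).  A candidate
(s, e, d_min) is replaced whenever a cheaper full-template alignment
ends at the current sample, and confirmed — reported — when every live
path either has accumulated distance ≥ d_min or started after the
candidate.  No distance threshold exists anywhere.

Three bookkeeping details matter in practice and were settled
empirically (each provably necessary on periodic streams):

1. **Selective invalidation, not full column reset.**  After a report,
   only paths overlapping the reported match are set to +∞.  Resetting
   the whole column kills the next cycle's partially formed path and
   makes the matcher skip alternate cycles.  The hard reset is still
   available as `star_pad` (it is also the initial state).
2. **Overlap tolerance of l//2 samples.**  A stride boundary is only
   defined up to the descriptor window half-width, and the next cycle's
   best path routinely starts a few samples before the previous match
   ends.  Treating such paths as competitors delays confirmation by a
   full cycle and then destroys them; treating them as next-cycle
   duplicates (not competitors, spared by the reset) restores per-cycle
   reporting.  Emitted intervals are clipped to the previous reported
   end, so reported strides remain strictly disjoint.
3. **Duration gating at emission.**  Confirmed candidates shorter than
   0.25 s or longer than 2.0 s are physiologically impossible and are
   discarded at emission (they never truncate or displace genuine
   matches); over-long alignments are also ineligible to become
   candidates.  `time_filter` additionally exists as the explicit
   post-hoc operation.  With gates disabled (the engine default), the
   matcher is the pure construction, and its best match equals an
   exhaustive brute-force subsequence DTW exactly — the test suite
   asserts bit-level agreement of (start, end, distance) across
   descriptor kinds and random streams.

A live full-template candidate at end of stream is flushed.  Because a
loosely worn sensor can invert signal polarity, `segment` matches both
the original and the sign-flipped stream.  The winning run is chosen by
`count / median(distance)` rather than count alone: on signals where
the wrong orientation fragments into many spurious matches, a raw count
picks the garbage; discounting by the median per-stride warping
distance keeps the count criterion but makes it fit-aware.

Smoothing: accelerometer channels pass a 5-sample (50 ms) centered
moving average before use; larger windows visibly erode the heel-strike
transient that event detection needs.  Gyroscope channels are not
smoothed.  Multi-axis schemes are fused to one signal by the per-sample
2-norm before description; unfused multi-axis schemes sum per-channel
descriptor distances.

## Gait events and phases

Within a detected stride (coronal gyro = gyro Z, sagittal acc = acc X,
both configurable):

* **TO** — the robust form of "first zero crossing after stride start":
  locate the dominant positive swing peak of the 50 ms-smoothed signal
  and walk back to the last non-positive sample.  A plain first-crossing
  rule false-triggers on noise around the quiet stance boundary.
* **HT** — the largest standardized high-pass residual (signal minus
  its 50 ms moving average, scaled by the MAD) summed over the coronal
  gyro and the sagittal accelerometer, searched after TO; maxima below
  a 3-sigma-per-channel floor are flagged missing.
* **Settling** (heelstrike → stance) — first sample after HT whose
  50 ms sliding variance drops below `theta_var`.
* **HO** — first sample after settling whose sliding variance exceeds
  `theta_var`, validating the next cycle's start; if it never does, the
  event is placed at the boundary and flagged.

`theta_var` defaults to 0.2 (rad/s)² over a 50 ms window: stance noise
variance stays near 0.11 even at power SNR 10, while a ~2 rad/s
push-off onset crosses 0.2 within its first few samples.  (A threshold
of 0.5 would be blind to gentle push-offs: the sliding variance of a
2 rad/s sinusoidal onset never exceeds ~0.3.)

Phases tile the stride exactly: pushoff `[start, TO)`, swing
`[TO, HT)`, heelstrike `[HT, settling)`, stance `[settling, end)`.
Strides missing TO or HT are excluded from phase metrics and counted.
Toe-off, being a zero crossing, is by definition level-dependent; the
offset-invariance that holds for the residual- and variance-based
detectors does not extend to it.

## Evaluation

Detections and labels are paired one-to-one greedily by descending
Jaccard ratio; a pair is a true positive iff Jaccard ≥ 0.5 (a
boundary-distance mode at ±150 ms is available).  For disjoint interval
sets the greedy pairing attains the optimal assignment (a detection can
exceed Jaccard 0.5 with at most one label), which the suite checks
against a Hungarian-algorithm oracle.  Precision, recall and F follow
the standard formulas; undefined ratios are reported as 0 with a flag.
Scoring is restricted to the annotated span (midpoint rule): the quiet
stretches between the synchronization stomps and the walk carry no
labels, so detections there are unverifiable rather than false.
`sweep` aggregates mean ± standard deviation of F across recordings per
speed stratum and grid cell.

## Synthetic gait generator

`synthgait` is the test bed standing in for real recordings.  Each
trial is quiet lead-in + stomps + strides + stomps + quiet tail.
Stride durations are drawn per stride from N(mean, (0.1·mean)²)
clipped to [0.25, 2.0] s, with speed-class means 0.9 / 1.1 / 1.4 s
(fast / mid / slow); phase fractions default to
(0.15, 0.35, 0.10, 0.40) — stance ≈ 40 % of the cycle.  Waveforms are
sums of raised sinusoid lobes, damped oscillations and Gaussian spikes
encoding only the qualitative facts the detectors use: a negative
plantar-flexion lobe crossing zero exactly at TO, a positive swing
lobe, a sharp HT spike shared between coronal gyro and forward
accelerometer followed by a damped settling oscillation that decays
into stance, gravity (9.81 m/s²) on the vertical axis, and
high-magnitude stomp spikes.  Stance includes a low-amplitude
(0.4 rad/s) weight-transfer rock: a literally motionless stance would
carry no positional information, making the stance-end boundary
unidentifiable *in principle* for any matcher; the rock stays an order
of magnitude below the stance-break variance threshold.  Noise is
additive white Gaussian per sensor; `noise_sd_for_snr` computes the
per-sensor level for a requested power SNR against the clean signal.
Ground truth (stride intervals, phase tiling, event times, stomp
positions) is recorded exactly as the signal is laid down.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: soft-tissue and mounting resonances,
turning and non-straight walking, speed drift within a trial,
inter-subject waveform shape differences beyond a global amplitude
scale, magnetometer disturbances, and colored or impulsive sensor
noise.  Results on it bound the method's behavior under its stated
assumptions, not its field performance.

## Problem sizes

The shipped tests and the acceptance script use 60-stride evaluation
walks (~70 s of signal), a 20-stride template trial, 20 random streams
of length ≤ 120 against a 20-sample template for the brute-force
equivalence check, and streams of 1k–4k samples for the complexity
audit.  These sizes make every property they probe already binding —
cycle skipping, junk displacement and boundary bias all manifest well
below 60 strides — while the whole suite runs in seconds.

## Known limitations

* At a walk's onset, a quiet-region candidate occasionally confirms
  late enough to consume the head of the first stride; the first cycle
  of a trial is then lost (~1 stride in 60 on some seeds).  This is the
  threshold-free construction's intrinsic cost at activity transitions.
* HOG1D alone degrades quickly with noise (its flat-window histograms
  are degenerate in stance); it is useful mainly inside compounds.
* The reporting delay of a confirmed stride is up to one cycle; stride
  *times* are exact, but downstream consumers see them about a cycle
  late.  Real-time consumers should account for this latency.
* Evaluation against manually labeled data inherits the labeling's own
  boundary uncertainty; the Jaccard-0.5 criterion is deliberately
  tolerant of it.
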