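# Methods

## Problem setting

Two sensors measure one phenomenon at different, possibly uneven rates. We
model the high-frequency stream as a uniform reference signal R of length
L_R with index timestamps t_i = i, and the low-frequency stream as a
companion Q whose j-th observation corresponds, under a known down-sampling
ratio d, to a group G_j of d consecutive reference observations. An
alignment algorithm returns a warping path — ordered links (i, j) under
boundary, monotonicity and continuity constraints — and we want to measure
(a) how far that path is from the known optimal grouping and (b) how badly
it suffers from singularities (one observation capturing long runs of the
other signal).

## Companion generation

From a uniform reference R the generator builds an intermediate warped
signal R′ and the companion Q:

* **Time warp.** t′_i = i − c·s_i with s_i = e^{−|t_i−t_A|/w} / (1+e^{−|t_i−t_A|/w})²,
  the derivative of the logistic sigmoid: maximal (0.25) at the anchor t_A
  and decaying smoothly, so the warp is contained in the signal bounds.
  Defaults: t_A = L/2, w = 0.1·L (validated against w < 0.5·L). The raw
  maximum shift is only 0.25 time units, so a multiplier c (`shift_scale`)
  is exposed: 1.0 reproduces the formula verbatim, and the benchmark preset
  uses 8.0 (a 2-time-unit peak shift at length 200 — visible but far from
  violating monotonicity; the monotonicity of t′ is checked and a
  too-strong warp raises, naming the first folded index). The value used
  is recorded in every benchmark report header.
* **Amplitude distortion.** Inside |t−t_A| < w the default ``as-printed``
  variant adds e^{−((t−t_A)/w)²} − 1 (a downward dip, discontinuous at the
  window edge — implemented verbatim for fidelity); ``positive-gaussian``
  adds the bump without the −1 offset and is continuous; ``none`` disables
  the distortion (used by identity-pipeline tests).
* **Down-sampling.** Q_j takes the timestamp of the (j·d)-th reference
  observation in 1-based counting (0-based indices d−1, 2d−1, …), giving
  L_Q = floor(L_R/d); amplitudes are linear interpolations of R′ as a
  function of its warped timestamps, clamped at the ends. This indexing is
  the only convention that keeps every companion timestamp inside the
  reference range, makes d = 1 an exact identity, and tiles the reference
  into consecutive d-blocks.

**Ground truth.** For each Q_j the optimal group is the window of d
consecutive R′ observations minimizing the summed Euclidean distance in
the (t, v) plane, with groups ordered and non-overlapping. We find the
joint minimizer exactly with a dynamic program over window starts
(O(L_Q·L_R), ties toward the smaller start index) rather than greedily:
the DP always agrees with exhaustive enumeration (verified on small
instances), whereas a greedy scan can be trapped. When L_R = L_Q·d the
constraints force the front tiling G_j = {jd, …, jd+d−1} regardless of
distances, which is what the worst-case error-rate normalization assumes.

## Metrics

* **Error rate.** Each path link (i, k) is charged |k − j(i)| where j(i) is
  the optimal group of reference observation i; the sum is divided by
  ½·L_Q·(L_Q−1)·(1+d) − (L_Q−1), the total charge of the worst admissible
  path (all of Q on the first R observation, all of R on the last Q
  observation). ER = 0 exactly at the optimal alignment and ER = 1 exactly
  at that worst case. The charge is summed *per link* — with any
  single-k-per-observation rule the worst case would not reach its own
  denominator, because the first reference observation touches every
  companion observation. Boundary: the normalization is exact when d
  divides L_R; with leftover reference observations the recovered grouping
  can shift off the front tiling and a path may exceed the denominator, in
  which case `error_rate` raises rather than silently clamping (only
  sub-1e-9 float excess is clamped). Experiments therefore use lengths
  divisible by d.
* **Singularity score.** SS = Σ_j (m̃_j − d)²/L_Q with m̃_j = m_j, the
  number of reference observations linked to Q_j, except that when M > 1
  companion observations collapse onto one reference observation every
  such Q_j with a single link contributes with m̃_j = 1/M. Since d ≥ 1
  this inflates the squared term, penalizing the direction (many
  low-frequency observations onto one high-frequency observation) that is
  genuinely worse. SS = 0 iff every m_j = d with no such runs.
* **Path length W** (link count) is kept as the classical comparator; two
  paths of equal W can differ arbitrarily in SS.

## Alignment engines

All four engines share one dynamic program: steps {(1,1),(1,0),(0,1)},
ties broken diagonal-first then reference-advancing, both in accumulation
and traceback. A single shared convention makes "EventDTW equals DTW when
no events exist" an exact path identity, not an approximate one.

* DTW: pointwise cost |v_R − v_Q|.
* Derivative DTW: same cost on the Keogh derivative estimate
  d_i = ((v_i − v_{i−1}) + (v_{i+1} − v_{i−1})/2)/2, endpoints copied.
* Shape DTW: Euclidean distance between raw length-`window_len`
  subsequences centered on each observation (edge-padded); window 5 by
  default, window 1 degenerates to DTW.
* EventDTW: see below.

### Events

A *slope* is a maximal strictly monotone run of at least two observations
(plateaus terminate runs and belong to none; adjacent up/down runs share
their turning point). Its *elevation* is observation count × amplitude
range. The reference's key slopes are the top ceil(frac·N) by elevation,
both directions ranked jointly, ties to the earlier start (frac = 0.2 by
default: restricting events to prominent slopes keeps noise from becoming
an alignment anchor). Each companion slope is matched to the
same-direction key slope with the nearest start timestamp; pairs farther
apart than a proximity threshold — half the median key-slope span by
default, configurable — are excluded, and each key slope accepts only its
nearest claimant (losers are excluded, not reassigned). A matched slope
becomes an event anchored at its amplitude extrema: the start point is the
observation of maximum amplitude and the end point the observation of
minimum amplitude, so an upslope's information flows backward in time from
its peak. Along the slope the information decays exponentially,
I = e^{ln(0.1)·|t − t_s| / |t_e − t_s|}: 1 at the peak, 0.1 at the far
end — far enough from 1 to create contrast along the event, far enough
from 0 to separate on-event from off-event observations — and 0 off all
events. Overlapping same-direction events keep the maximum I, preserving
I ≤ 1. EventDTW then aligns the sequences of 3-vectors (v, I_up, I_down)
under the Euclidean distance; channels are unweighted because amplitudes
are standardized beforehand (per-channel weights are exposed but default
off). Event preparation is O(L_R + L_Q); the alignment itself is the
shared O(L_R·L_Q) dynamic program.

## Preprocessing

Gaussian smoothing (sigma = 1 index unit, truncation 4σ, reflect padding)
followed by population z-scoring. Smoothing operates in index space;
for strongly irregular timestamps this is an approximation, a known
limitation. Order (smooth, then standardize) and both parameters are
configurable; standardization makes the amplitude channel commensurate
with the information channels and with other datasets.

## Benchmark protocol and problem sizes

Per dataset: draw a reference (default family: three random harmonics,
amplitudes U(0.5, 2), 1–5 cycles, random phases, length 200; a random-walk
family provides a rough, unfavourable contrast), preprocess, generate the
companion (d = 5, shift_scale 8.0, as-printed bump), align with all four
engines, score ER and SS, and tabulate the percent of datasets each
algorithm wins per metric, ties splitting credit equally so columns sum to
100. All randomness flows through one seeded generator; a fixed seed gives
byte-identical reports. Default sizes (20 datasets of length 200) keep a
full run under a second while leaving each signal long enough to carry
several distinct events.

The sine-mixture family emulates smooth, peaked physiological rhythms with
a localized warp — the regime the event mechanism targets. It does not
emulate measurement noise, missing samples, baseline wander, or timestamp
jitter in the companion; passing benchmarks therefore demonstrate correct
mechanics and the expected ordering on clean peaked signals, not
performance on raw wearable-sensor streams.

## Numerical choices and degenerate inputs

Signals must be finite, strictly time-increasing, length ≥ 2; constant
signals cannot be standardized (error) and contain no slopes (EventDTW
falls back to DTW). Derivative DTW needs length ≥ 3. Degenerate events
(t_s = t_e) raise. Exhaustive-enumeration checks use absolute tolerance
1e-10; exact-identity claims (ER endpoints, zero-event reduction,
determinism) are asserted without tolerance.

## Limitations

Single-anchor warps only; no timestamp jitter in the generated companion;
event detection is not guaranteed to find or match corresponding events in
noisy pairs (mismatched events can mislead the alignment); plateau regions
carry no event information and still align like plain DTW there.
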