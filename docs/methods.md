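# Methods

## Signal model and assumptions

A walking trial is a multichannel ground-contact-force (GCF) time
series: one channel per sensor site (heel, ball) per foot, sampled at a
constant rate (default 1000 Hz), in kilogram-force. The model behind the
detector:

* During loading (early stance) each channel rises monotonically for
  many consecutive samples; during unloading it falls monotonically.
* Off the ground the channel carries low-amplitude noise whose
  low-pass-filtered magnitude is Rayleigh distributed — the magnitude of
  isotropic two-dimensional Gaussian noise, pdf
  `x/σ² · exp(−x²/2σ²)`, mean `σ√(π/2)`.
* Forces are non-negative; sensor voltages map linearly to force
  (0–5 V ↔ 0–200 kgf) at the I/O boundary only.

## Area segmentation (sliding windows)

Each incoming sample contributes the sign of its first difference.
Both windows always shift: a rise pushes (1, 0) into the
(ascending, descending) windows, a fall pushes (0, 1), a tie — possible
with quantised sensors — pushes (0, 0), supporting neither run. The
first sample has no difference and is labelled unstable. Counts use
strict inequality (`count > limit`). Each window therefore holds exactly
the sign pattern of the last `N` differences, and the counts decay
naturally when a run ends.

A parameter validator rejects combinations for which both counts could
exceed their limits simultaneously; the feasibility condition is
`L_asc + L_desc + 2 ≤ max(N_asc, N_desc)` (pack the rises into the most
recent slots of the shorter window, fill the rest of the longer window
with falls). The defaults (35/38, 36/40) are safely exclusive:
35 + 36 + 2 = 73 > 40.

With the defaults and symmetric i.i.d. noise, escaping the unstable area
needs ≥ 36 positive signs among the last 38 differences — probability
below `(1 + 38 + 703)/2³⁸ < 10⁻⁸` per sample even ignoring the negative
lag-1 correlation of i.i.d.-sequence differences, consistent with the
measured 0/10⁶.

## Threshold computation (CFAR)

While a channel is unstable its samples accumulate in a buffer. When the
unstable interval ends in a fresh ascent, the buffer is sealed:

* The trailing `trim_tail` samples (default 38, the ascending window
  size) are dropped — the window detector declares the ascent with
  roughly that lag, so the buffer tail already belongs to the new
  loading phase and would bias the mean upward.
* If fewer than `min_unstable_samples` (default 20) remain, the previous
  threshold is reused with a warning; short unstable intervals are
  expected at fast cadence, where the noise segment shrinks.
* Otherwise `σ̂ = x̄√(2/π)` and `T = σ̂√(−2 ln p)`. The identity
  `P(X > T) = p` for `X ~ Rayleigh(σ)` is exact; the package verifies it
  empirically to within 4 Monte-Carlo standard errors at 10⁶ draws.

The false-alarm parameter is interpreted by `pf_mode`: a probability, an
inverse gain (default; value 20.5 ⇒ p = 1/20.5), a negative log, or a
percentage. The gain form is the default because the optimised operating
point is conventionally quoted as a gain-like number > 1, and its
reciprocal lands in the conventional false-alarm range; all four
readings are selectable.

Status is boundary-inclusive: on-ground iff `F ≥ T`.

## Phase rule and the two interval-level reconciliations

Per sample and foot the rule is: a channel in the unstable area counts
as off-ground regardless of its threshold status (default,
"discussion-consistent" mode); in continuous areas the thresholded
status decides. (heel, ball) = (1,0) → Heel-Strike, (1,1) → Full-Stance,
(0,1) → Heel-Off, (0,0) → Swing. A literal rule-table mode maps
both-channels-unstable to Full-Stance instead of Swing, preserving the
published table row verbatim; the default follows the physically
coherent reading (both off-ground ⇒ swing). Before a channel's first
threshold exists, statuses in continuous areas are undefined and the
emitted phase is UNDEFINED (warm-up); both-unstable still resolves to
Swing, which needs no threshold.

The instantaneous window counts do not quite implement the
interval-level rule ("the whole loading/unloading hump is one on-ground
region"), so the streaming detector adds two small state machines,
both O(1):

* **Peak bridging.** Around a force maximum the ascending count decays
  below its limit ~3 samples after the peak while the descending count
  only exceeds its limit ~37 samples later, leaving a short spurious
  "unstable" gap mid-hump. The channel therefore stays in its contact
  region from the ascent-declared event until the descent hands back to
  noise; a gap outlasting the largest window size (40 samples) ends the
  region regardless — the safety valve for non-gait signals such as a
  rise into a flat plateau.
* **Off-latch.** After the force first crosses below the threshold
  within a contact region, the status stays off-ground until the region
  ends. A smooth hump crosses the threshold exactly twice (up, down);
  without the latch, the expected fraction `p` of post-descent noise
  samples exceeding `T` during the window-decay lag would re-assert
  contact and emit spurious Full-Stance blips.

Raw per-sample area labels remain available in the channel traces for
inspection; only the phase rule consumes the region-level labels.

## Preprocessing

Optional Butterworth low-pass, default order 2 at 200 Hz, causal. The
causal filter is initialised at the steady state of the first sample
(no start-up transient; constants pass through exactly) and the
streaming filter class produces bit-identical output to the batch call,
so stream and batch runs agree exactly. A zero-phase forward-backward
mode exists for offline use only. The cut-off deliberately stays high: a
warning is emitted below 50 Hz because aggressive smoothing distorts the
off-ground magnitude distribution that the CFAR stage assumes. Filter
undershoot below zero is clipped at the detector input (forces are
physically non-negative, and the Rayleigh estimator requires it).

## Synthetic gait generator

The generator emulates the statistical structure the detector exploits,
not musculoskeletal dynamics:

* Cadence model `cycle_s = 1.4 / (0.35 + 0.15·v)` for speed `v` in km/h
  — monotone decreasing, ≈2.15 s at 2 km/h to ≈1.12 s at 6 km/h, in the
  range reported for adult treadmill walking.
* Per cycle, the heel channel carries a hump over the first
  `stance − lag` = 45 % of the cycle and the ball the same hump shifted
  by the lag (15 %), ending at the stance fraction (60 %). The hump is
  `peak · sin(πu)^0.25` with `peak = 0.6 ×` body mass: strictly monotone
  on either side of a single maximum (clean runs for the windows) with
  steep shoulders, so the 1 %-of-body-mass truth crossings sit at the
  hump edges and the stance-time bookkeeping matches the stance fraction
  to within 2 %.
* Off-ground samples are i.i.d. Rayleigh (default scale 0.3 kgf —
  sub-1 % of body weight, a realistic filtered FSR noise floor).
  On-ground samples are the clean hump; the right foot is the left
  shifted by half a cycle. Identical spec + seed ⇒ identical output.
* Optional "tremble" bursts — short (< ascending limit) raised-cosine
  artefacts added to off-ground samples — model a foot shaking in swing.

What passing on this generator does **not** show: robustness to real
FSR drift/hysteresis, partial foot contact, double-support force
sharing, pathological gait sequences, or non-Rayleigh noise after heavy
filtering. Those need real recordings.

## Parameter searches

* Window search: exhaustive over all admissible `(L, N)` pairs per side,
  scored by the testing probability (fraction of known off-ground
  samples labelled continuous), computed by a vectorised cumulative-sum
  labeller proven equal to the streaming path. Selection among
  zero-probability combos: smallest `N_asc + N_desc`, then smallest
  `L_asc + L_desc`, then lexicographic — larger windows only add lag.
* False-alarm search: exhaustive over a user grid, scored by mean
  agreement against reference-labelled training recordings; the full
  score table is returned for plotting.

## Evaluation

Reliability between two label series is the percentage of samples with
equal phases, UNDEFINED excluded pairwise (how the first, warm-up cycle
should be scored is otherwise undefined). Test–retest consistency uses
the one-way random-effects single-measurement ICC,
`(BMS − WMS)/(BMS + (k−1)·WMS)`; the implementation is cross-checked
against an independent ANOVA decomposition (≤1e-10) and against
pingouin's ICC(1,1). The bundled 22-subject × 5-method reliability table
ships for demonstration; its ICC is near zero because between-subject
spread is small relative to within-subject spread across methods.

## Numerical and testing choices

* Detection is scale-equivariant (thresholds scale with the buffer, area
  labels depend only on diff signs), so kgf vs volt processing changes
  nothing but units; kgf is canonical internally.
* Problem sizes in the test-bench runs: 10⁶ samples for the
  zero-misclassification and CFAR-identity checks, 30 s at 1000 Hz per
  speed for end-to-end detection, 100 seeded 6-s trials for tremble
  robustness, shorter 500 Hz trials for unit tests.
* Agreement in end-to-end checks is reported outside ±38-sample bands
  around true transitions: the window detector has an irreducible
  ≈`L_asc + 1`-sample declaration lag, which is a property of the
  method, not an implementation error. Raw (band-inclusive) agreement on
  the same trials is ≈95–96 % at 1000 Hz.

## Known limitations

* Jumping (both feet airborne) reads as Swing on both feet; no jump
  detector is included.
* Toe-off/initial-contact sub-events need an extra sensor site and are
  out of scope.
* At fast cadence with low sampling rates the unstable interval can fall
  below `min_unstable_samples`; the detector then reuses the previous
  threshold and logs it.
* The proportional-method and self-tuning-triple-threshold reference
  detectors are plug-in slots only; their internals are defined in
  external work and are not reimplemented here.
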