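# Methods

This note documents the models, algorithms, parameter choices and
limitations of the `synwalk` package. It is written for a reader who
wants to understand what the code computes and why, and what passing
its tests does and does not establish about real recordings.

## EMG preprocessing

Raw EMG (8 paretic-side muscles — TA, Sol, MG, VM, RF, MH, LH, GM — at
1926 Hz) is processed per channel:

1. **Band-pass 20–500 Hz**, Butterworth of order 4 applied forward and
   backward (`scipy.signal.sosfiltfilt`), i.e. zero phase lag. The
   filter is *designed* at the stated order; the bidirectional pass
   doubles the effective roll-off, which is the common convention in
   gait EMG work. If a recording's sampling rate puts 500 Hz at or
   above Nyquist, the high cutoff is clamped to 0.45·fs with a warning.
2. **De-mean, rectify** (in that order), then **low-pass 10 Hz**, same
   zero-phase order-4 Butterworth. Negative ripple introduced by the
   low-pass is clipped to zero (NNMF requires nonnegative input); the
   clipped magnitude is logged at debug level.
3. **Amplitude normalization**: each muscle is divided by its maximum
   amplitude over the whole recording session. By default the maxima
   pool all three walking conditions (`norm_scope: session`), so
   envelopes are comparable across conditions; per-condition
   normalization is available as a config flag. The session reading was
   chosen because a single "maximum amplitude recorded" naturally spans
   the session; both behaviors are tested.
4. **Stride segmentation** at paretic heel contacts. The first and last
   three gait cycles are removed (walkway acceleration/deceleration)
   and the first 20 remaining strides kept. Fewer than 20 surviving
   strides produce a warning and the analysis proceeds with what
   remains; zero strides is an error. Graceful degradation was chosen
   over failure because desk-scale and synthetic runs legitimately use
   shorter recordings.
5. **Time normalization**: each stride is linearly interpolated onto a
   100-point gait-cycle base (0–100 %), and strides are concatenated
   along time into the muscles × (100·strides) envelope matrix that the
   factorization consumes.

Filter edge handling is `sosfiltfilt`'s default odd-reflection padding
(3·(2·sections+1) samples); signals too short for stable padding raise
a labelled error rather than returning garbage.

## Synergy extraction (NNMF)

`V ≈ W·C` is fitted by Lee–Seung multiplicative updates for the
Frobenius objective. Initial `W`, `C` entries are i.i.d. uniform on
(0, 1] — strictly positive, so no element is locked at zero by the
multiplicative rule. Under these updates the residual is
non-increasing, which the tests assert per iteration.

Stopping (per restart): iteration ends when the RMS residual improves
by less than `tol_residual = 1e-6`, when the largest relative element
change in `W` and `C` falls below `tol_relative_change = 1e-4`, or at
`max_iter = 2000`. Two numerical choices deserve note:

- The residual tolerance is applied on the RMS scale of the input
  (`threshold = tol_residual · RMS(V)`), making stopping invariant to
  amplitude units. On exact low-rank data this converges to
  VAF ≥ 1−1e-6; a strictly absolute threshold stalls marginally short
  of that on normalized envelopes.
- `max_iter` caps runaway restarts; the tolerances alone do not
  guarantee termination.

The factorization is repeated from `n_restarts` independent seeded
initializations and the solution with the lowest RMS residual is kept.
The library default is 1000 restarts; tests and the synthetic demo use
10–50, which on this problem class (8 × 2000, well-separated bursts)
reaches the same optimum — restart seeds are drawn so that a smaller
restart count is a prefix of a larger one, making "more restarts never
worse" a testable property. All randomness flows from one master seed
(`SeedSequence([seed, k, restart])`), so results are bit-reproducible.

Identifiability: NNMF is defined up to column permutation and scale.
Reported `W` columns are unit Euclidean norm (with `C` rescaled
reciprocally) so the 0.3 significance threshold is well defined, and
synergies are ordered by the gait-cycle percent of their mean
activation peak. Tests of recovery compare factorization quality and
greedy-matched cosines, never column order.

## Synergy-count selection and VAF1

`VAF_n = 1 − ΣΣerror²/ΣΣEMG²` over all muscles and time points;
per-muscle VAF restricts both sums to one row. The selected `n` is the
smallest k satisfying, jointly:

- global VAF_k > 0.90;
- VAF_{k+1} − VAF_k ≤ 0.05 (vacuous at k = m, since no larger model
  exists);
- per-muscle VAF ≥ 0.75 for every muscle.

"Smallest jointly-satisfying k" is the standard reading of this rule
family; a literal "highest k with VAF above 90 %" is not well defined
because VAF is non-decreasing in k. If no k satisfies all three
criteria the smallest k meeting the global criterion alone is returned
with a `selection_fallback` diagnostic flag (the local 75 % criterion
can in principle veto every k; silently failing seemed worse than a
flagged answer). Model orders are fitted incrementally and fitting
stops as soon as the selection is decided, unless the full VAF curve is
requested.

`VAF1` is the global VAF of the best one-synergy model, in [0, 1]
internally and reported as a percentage in result tables. For a
nonnegative matrix the best rank-1 approximation is the leading SVD
pair (Perron–Frobenius), giving the closed-form oracle
`VAF1 = σ₁²/Σσᵢ²` against which the implementation is tested.

## Subtype classification

Canonical module membership: module 1 {VM, RF, GM}, module 2 {Sol,
MG}, module 3 {TA, RF}, module 4 {MH, LH}. RF is biarticular and
belongs to modules 1 and 3; it is therefore *distinctive* of neither.
Distinctive sets — module 1 {VM, GM}, module 2 {Sol, MG}, module 3
{TA}, module 4 {MH, LH} — drive assignment so that a shared muscle can
never create a spurious merge.

For a 3-synergy solution (solutions with n ≠ 3 are labelled
`unclassified`; the merging analysis is defined only for three-synergy
participants, classified in the comfortable-walking condition):

1. Each synergy's significant muscles are those with unit-norm weight
   ≥ 0.3. Note a unit-norm 8-vector always has an entry ≥ 1/√8 ≈ 0.354,
   so an empty significant set occurs only for a degenerate zero
   column.
2. A synergy is assigned every module whose distinctive muscles it
   fully covers (coverage fraction configurable).
3. If exactly one synergy carries two modules and the other two carry
   the remaining two modules (all four accounted for), the merged pair
   maps to the subtype: {1,2} → subtype 1, {1,4} → subtype 2, {3,4} →
   subtype 3; any other pair → `other_merge`; no merged synergy →
   `non_merged`.
4. Ambiguous threshold patterns fall back to cosine similarity against
   graded templates (the four module vectors and the six normalized
   pair sums); only an irresolvable pattern returns `unclassified`,
   always with per-synergy evidence attached.

The assignment procedure beyond the 0.3 threshold is a design choice of
this package (the threshold-pattern rule with distinctive muscles and a
cosine fallback); the field describes "comparing weight coefficients
across synergies" without an algorithm.

## Kinematics

- **Limb angle**: signed angle between the downward vertical through
  the hip and the hip→ankle vector, positive when the ankle is anterior
  (flexion). The coordinate frame is declared in config (`y_axis:
  up|down`); image coordinates are flipped internally. The angle series
  (not the raw coordinates) is low-pass filtered at 6 Hz, zero-phase
  order-4 Butterworth. The computation is invariant to uniform scaling
  and translation of the coordinates, so image-pixel and metric inputs
  behave identically.
- **Events**: insole pressure is authoritative — heel contact at the
  rising crossing of 20 % of the pressure peak, toe-off at the falling
  crossing. Shank anterior-posterior acceleration peaks and
  twice-differentiated ankle-keypoint acceleration peaks cross-validate
  the paretic contacts; disagreement beyond 30 ms warns and keeps the
  insole events. Events at the extreme ends of a finite stream are
  excluded from validation (a transient at sample 0 has no detectable
  peak).
- **Gaps**: keypoint dropouts up to 5 frames are filled by linear
  interpolation; longer gaps stay NaN and the affected strides are
  discarded by the caller.
- **Peaks**: per-stride maximum (flexion) and minimum (extension) of
  the 100-point normalized angle, with across-stride means.
- **Symmetry index**: `SI = 100·(SS_p − SS_np)/(½(SS_p+SS_np))` on
  single-support durations (paretic single support = contralateral
  swing, toe-off to heel contact). The difference-over-half-sum form
  (Robinson) with paretic-minus-non-paretic ordering makes negative
  values mean a shorter paretic support phase, matching the clinical
  sign convention. The literature cites several symmetry indices; this
  choice is pinned by that sign requirement.
- **Cadence**: steps/minute; each side's heel-contact intervals counted
  over that side's own first-to-last contact span (lead-in/run-out
  outside the counted steps does not dilute the rate).

## Synthetic gait generator

The generator is the forward model of the factorization, with known
ground truth:

- **Weights**: graded canonical module vectors (unit norm). A merged
  synergy's weight vector is the normalized sum of its parents';
  its activation is the pointwise maximum of the parents' — the
  simplest construction that realizes "two modules driven as one".
- **Activations**: truncated Gaussian bursts on the circular 0–100 %
  cycle — module 1 centred at 15 % (early stance, σ 8), module 2 at
  45 % (late stance/push-off, σ 8), module 3 bimodal at 5 % and 70 %
  (weight acceptance + early swing, σ 5/8), module 4 at 92 % wrapping
  into initial contact (σ 8). These timings are canonical burst
  patterns, not a reproduction of any measured cohort; per-module
  activation timing is not numerically reported in the clinical
  literature this emulates.
- **Envelopes**: `V = W·C` plus additive Gaussian noise (`noise_sd` is
  a fraction of each channel's envelope peak), clipped at zero to
  preserve nonnegativity, then row-scaled so each muscle's maximum is 1
  (mirroring the amplitude normalization applied to recordings).
  Ground truth is re-expressed on the emitted scale (rows scaled,
  columns re-unit-normalized) so `V = W_true·C_true` holds exactly at
  zero noise and recovered weights are directly comparable.
- **Raw EMG**: zero-mean Gaussian carriers band-limited to 20–450 Hz at
  1926 Hz, amplitude-modulated by the channel envelope resampled onto a
  jittered stride timeline (stride-duration CV 0.03 by default). All
  streams of one condition share a single seeded timeline, so insole,
  keypoint and EMG data stay mutually consistent.
- **Kinematics**: the limb angle follows `mid + amp·cos` with peaks at
  the configured flexion (+14.5°, late swing at 90 % cycle) and
  extension (−14.4°) setpoints — subtype-1 comfortable-walking means
  used as generator defaults; hip and ankle keypoints are back-computed
  with a 0.85 m limb in a metric y-up frame at 60 Hz. Each paretic heel
  contact adds a 6 mm Gaussian impact dip (σ 15 ms) to the ankle
  trajectory: it gives keypoint-derived acceleration a physical
  landmark at heel strike (the 6 Hz angle filter removes it from angle
  outputs). Insole pressure (100 Hz) is a smoothed stance pulse per
  side (60 % duty, 1 %-cycle ramps); shank AP acceleration has one
  dominant Gaussian peak per paretic heel contact.
- **Walking conditions**: `p-long` raises peak flexion by 2° and
  sharpens activation bursts (width × 0.75 — less temporal overlap,
  hence more complex structure and lower VAF1), `np-long` deepens peak
  extension by 3.7°; offsets follow the direction and rough size of the
  condition effects reported for experimentally lengthened steps. Each
  condition gets its own seed stream.

What the generator does *not* emulate: biomechanically consistent joint
kinematics (the angle is a smooth periodic curve, not forward
dynamics), ground-reaction forces, bilateral EMG, electrode artifacts,
ECG contamination, inter-muscle crosstalk, or realistic inter-subject
weight variability. Passing the round-trip tests therefore shows the
*pipeline* is correct and self-consistent — it does not validate the
physiological assumptions against patients.

## Problem sizes and defaults

| parameter | default | notes |
|---|---|---|
| strides analyzed | 20 | after trimming 3+3 cycles; 27 generated |
| cycle time base | 100 points | per stride |
| EMG / keypoint / insole rates | 1926 / 60 / 100 Hz | generator + expected recordings |
| band-pass, envelope LP, angle LP | 20–500, 10, 6 Hz | zero-phase order 4 |
| NNMF tolerances | 1e-6 (residual, RMS(V) scale), 1e-4 (elements) | per restart |
| restarts | 1000 (library) / 10–50 (tests, demo) | prefix-consistent seeds |
| VAF thresholds | 0.90 global, 0.05 increment, 0.75 per muscle | selection rule |
| weight significance | 0.3 | on unit-norm columns |
| generator noise | 0.05 of envelope peak | study-level envelope noise |

Test-scale ensembles (40 seeds per merge pair at noise 0.05, 10
restarts) and the two-minute acceptance script are the package's chosen
desk-scale problem sizes; the selection behavior at these sizes matches
the 50-restart runs wherever both are exercised.

## Known limitations

- The multiplicative-update NNMF converges slowly near the optimum;
  very flat optima may differ between restarts at the 1e-6 level,
  which is why the VAF-curve monotonicity invariant carries a 1e-3
  tolerance at test restart counts.
- The local 75 % criterion can reject every model order on adversarial
  data; the fallback then reports the global-criterion minimum with a
  diagnostic flag rather than an error.
- Event detection assumes reasonably clean insole pulses; heavily
  degraded pressure signals (e.g. drag-to-contact gait) would need a
  different onset detector.
- Group-level inferential statistics (condition × subtype ANOVA,
  correlations with walking speed) are deliberately out of scope; the
  cohort summary reports descriptive means ± SD/SE only.
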