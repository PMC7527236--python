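# Methods

## Data model and units

Time is in seconds, lengths in cm, speeds in cm/s, angles in degrees. A
*stride* is paw contact to the next contact of the same paw; *stance* runs
from contact to the following lift and *swing* completes the stride, so
stride = stance + swing exactly (event times are shared). Only complete
strides are analyzed: the terminal contact without a successor is dropped,
and a pass enters coordination analyses only if its reference hindlimb
contributes at least `min_cycles_per_pass` complete cycles (default 3,
configurable — a conservative proxy for typical inclusion criteria, which
are rarely published in full).

Event tables are long-format CSV (`animal, timepoint, task, surface, pass,
limb, event_type, time_s` with `event_type ∈ {contact, lift}`); marker
tables are long-format CSV (`animal, pass, frame, marker, x_cm, y_cm`) with
the frame rate supplied in configuration, since the acquisition rate is a
property of the recording session, not of the table. Validation enforces
strictly increasing contacts and lifts and strict contact/lift
interleaving; violations name the offending pass.

## Interlimb coupling

The coupling phase of a limb pair for one reference stride is
φ = (t_paired − t_start)/T, where t_paired is the paired limb's first
contact in the half-open window [t_start, t_start + T). The half-open
window prevents double assignment of a contact to two strides. A reference
stride with no paired contact yields no sample (it is logged; such 1:1
violations are what the stepping index would expose). The contact event —
rather than lift — defines the phase; this is the standard footfall-phase
convention and is configurable in principle by supplying lift times as the
event series.

The reference limb is the right limb of each pair: left-right hindlimbs
(RH→LH), left-right forelimbs (RF→LF), homolateral hindlimb-forelimb
(RH→RF) and diagonal hindlimb-forelimb (RH→LF).

Folding maps φ to [0.5, 1.0] via fold(φ) = φ if φ ≥ 0.5 else 1 − φ. The
fold is idempotent and identifies φ with 1 − φ, removing lead-limb
arbitrariness (0.25 and 0.75 — the two gallop configurations — coincide).
The upper half was chosen as the canonical branch; the lower branch
[0.0, 0.5] carries the same information and keeping one avoids double
bookkeeping.

### Control band and altered steps

Folded phases from all control time points of the same task/surface pool
into one band per limb pair: mean ± k·SD (sample SD, n − 1), clipped to
[0.5, 1.0], with k = 2 by default. The band is two-sided before clipping;
for pairs whose control mean sits at the 0.5 boundary the lower limit clips
to 0.5, so the distinction between a one- and two-sided band is immaterial
there. A step is altered when its folded phase falls outside [lower,
upper]. Because the folded distribution of a tight alternating pattern is
half-normal-like rather than normal, the k = 2 band covers roughly 95–98%
of control steps — i.e. a ~2–5% false-positive floor, which any comparison
of altered-step proportions inherits on both sides.

The coefficient of variation is 100·SD/mean of the folded phase per
animal-timepoint group (sample SD; the folded scale is bounded below by
0.5, so the mean cannot vanish). The quadrupedal stepping index is
100 × hindlimb/forelimb complete-cycle counts; 100 denotes 1:1 stepping.

## Circular statistics

Phases live on [0, 1) in all public interfaces and are scaled by 2π
internally. The circular summary reports the mean direction (atan2 of mean
sine/cosine, mapped back to [0, 1)), resultant length R and circular
variance 1 − R; when R is numerically zero (below 1e−12) the mean direction
is undefined and reported as NaN.

Watson's two-sample U² is computed from the pooled sort: with F and G the
empirical cumulative fractions at the N = n₁ + n₂ ordered pooled points and
d = F − G,

    U² = (n₁n₂/N²)·[Σd² − (Σd)²/N].

Tied values: every member of a tied block takes the block's final
cumulative d — the empirical-measure evaluation. This choice is symmetric
in the two samples and order-independent (averaging the intermediate
cumulative values inside a block would depend on the arbitrary within-block
ordering), agrees with direct O(N²) counting, and reduces to the standard
formula when all values are distinct. The default p-value is a seeded
random permutation of pooled labels (10,000 permutations, reported as
(b + 1)/(B + 1)); the asymptotic alternative uses the null series
2·Σ (−1)^(m−1) exp(−2m²π²U²), adequate for n ≳ 50 (it reproduces the
classical 5% critical value 0.187 to three decimals). Permutation is the
default because the sample sizes in per-animal analyses can be small and
the permutation p is exact up to Monte-Carlo error; every permutation run
records its seed.

## Proportion test

The two-sample proportion z uses the **unpooled** standard error and no
continuity correction; two-tailed p from the standard normal. The unpooled
form is the one consistent with the published values this package is
designed to reproduce (back-derivation from the printed counts singles it
out; the pooled form, available behind a flag, gives e.g. 10.07 where 11.31
is reported). The statistic is undefined (raised as an error) only when
both proportions are degenerate in the same direction.

## Gait taxonomy, phase-frequency, speed relations

Girdle coupling categories on the folded scale: alternating [0.5, 0.65),
phase-shifted [0.65, 0.85), synchronous [0.85, 1.0]. No numeric boundaries
are published for these categories; the defaults center the three canonical
patterns (0.5, 0.75, 1.0) with equal guard bands and are configurable. A
stride set is walk-trot if both girdles alternate, full-bound if both are
synchronous, half-bound if the hindlimbs are synchronous and the forelimbs
are not, gallop if either girdle is phase-shifted while the hindlimbs are
not synchronous, otherwise unclassified. Walk and trot are deliberately not
distinguished. Gait assignment pairs each reference hindlimb stride with
the temporally overlapping right-forelimb stride; strides without a girdle
partner are unclassified.

Phase-frequency tables count steps at/below vs above a threshold step
frequency (default 5 Hz, the walk-trot → gallop transition zone) and export
the raw (phase, frequency) pairs for polar plotting. Speed relations use
Spearman rank correlation (average ranks on ties) plus ordinary
least-squares slope/intercept/R² — "line of best fit" semantics, not robust
regression. Slopes of two independent fits are compared with
t = (b₁ − b₂)/√(SE₁² + SE₂²) on n₁ + n₂ − 4 df.

## Kinematic angle models

All angles are interior angles via arccos of normalized dot products,
clamped to [−1, 1] against rounding, and are invariant under global
translation, rotation and uniform scaling. The hindlimb model's vertices
are the hip (proximal angle, between hip→iliac-crest and hip→ankle) and the
ankle (distal angle, between ankle→hip and ankle→toe) — inferred from the
segment list, as vertex assignments are conventionally left implicit.
Frames with coincident defining points are dropped and logged. Peak
detection is the global maximum within the stride, earliest on ties, with
no smoothing by default. The base-of-support angle is measured at the groin
between the caudally extended body axis (shoulder-midpoint → groin) and the
groin → paw direction, at initial contact only (paw rotation drifts during
stance as weight transfers). The trunk angle is the acute angle between the
iliac-crest→hip line and the water-surface line, evaluated per frame and
averaged per stroke cycle.

## Synthetic generator

The generator emulates the statistical structure the analyses assume, not
limb dynamics. Per pass: a speed drawn uniformly from `speed_range`
(default 20–100 cm/s); reference (right hindlimb) contacts at cumulative
stride times with 3% lognormal jitter; the other limbs placed within each
reference stride at von Mises phase draws — left-right hindlimb (mean 0.5)
and homolateral hindlimb-forelimb (mean 0.5) relative to the right
hindlimb, left-right forelimb (mean 0.5) relative to the right forelimb,
so the diagonal coupling (≈ synchrony) emerges by composition. Lifts follow
contacts at the speed-dependent duty-cycle fraction. With probability
`disruption_rate` a stride's left-limb phases are redrawn — uniformly on
the circle (decoupling) or shifted by a quarter cycle — sparing the
homolateral coupling, which mirrors the empirical phenotype (left-right
decoupling primary, homolateral intact). Phase noise is von Mises with
κ = 50 per pair by default (circular SD ≈ 0.023 cycles, a tight but
realistic control concentration).

Stride time follows t = 3.2·v^(−0.55) s (v in cm/s): 0.62–0.25 s strides
(1.6–3.9 Hz) and 12–25 cm stride lengths over the default speed range,
keeping control stepping below the 5 Hz transition as real overground data
are. (A steeper-scaled prefactor would push step frequencies to 6–16 Hz and
stride lengths to 3–6 cm, outside the physiological envelope.) The duty
cycle falls linearly from 0.70 at 20 cm/s to 0.45 at 120 cm/s. The body
marker advances at the pass speed; paw markers hold through stance and
advance through swing, so the recovered per-stride speed equals the pass
speed exactly. Angle traces are raised cosines with the proximal peak at
the end of stance (phase 0.6 of the stride by default) and the distal peak
lagging by a configurable fraction; amplitudes are half the peak-to-trough
excursion.

Determinism: each (animal, pass) draws from a substream seeded by
(scenario seed, animal index, pass index), so identical seeds give
byte-identical event tables and any pass can be regenerated independently.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real recordings: digitization noise and marker
dropout, within-pass acceleration, left/right asymmetries, autocorrelated
phase wander across strides, animal-specific preferred speeds, and any
biomechanical coupling between phase and stride timing. Results on real
data additionally depend on digitization quality and inclusion criteria.

Default scenario sizes (6 animals × 8 passes × 12 strides per condition,
scaled up to ~1,000 strides where convergence is being measured) were
chosen to match the scale of a typical silencing study while keeping the
full test suite and the acceptance script fast.

## Pipeline

`run_pipeline` composes read → cycles → phases → bands → classification →
statistics → reports, writing `phases.csv`, `comparisons.csv`, `gaits.csv`,
`polar.csv`, `counts.csv`, `u2_results.json`, `band.yaml` and `summary.md`.
Control/dox condition labels are disjoint sets of timepoint labels in the
run configuration. Any stage failure removes partial outputs and re-raises
naming the stage. Outputs are byte-identical across re-runs with identical
inputs, configuration and seed. A counts-only entry point reproduces
published proportion comparisons from tabulated counts without raw step
data.

## Known limitations

- U² p-values for specific published comparisons are not reproducible
  without the underlying per-step samples; the test is validated by oracle
  equivalence and null calibration instead.
- The published z = 7.47 for the diagonal hindlimb-forelimb comparison is
  not recoverable from its printed counts under either SE form (unpooled
  gives ≈ 7.40) and is treated as a typographical inconsistency.
- Continuous relative phase from angle traces is out of scope; coupling is
  event-based only.
- The gait category boundaries are heuristic defaults; analyses sensitive
  to them should sweep the band edges.
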