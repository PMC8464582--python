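# Methods

## The simulated case

The package models the primary survey of a single pelvic-trauma patient:
the lethal mechanism is uncontrolled pelvic hemorrhage, and the trainee's
task is the ABCDE sequence — secure the airway, oxygenate, control the
bleeding and restore volume, assess disability, and protect against
exposure (hypothermia, defined as body temperature ≤ 35 °C). No second
injury is modeled.

## Patient dynamics

Time advances in integer minutes. The engine's only hard contract is the
remaining-lifetime calibration: an untreated patient crosses a lethal bound
for the first time at the scenario's `remaining_lifetime` (± one tick).
Linear dynamics are the minimal model that satisfies this contract, so
every rate below is a constant slope unless an action changes it.

**Hemorrhage channel.** Blood volume `V` (fraction of normal, start 1.0,
clipped to [0, 1.2]) falls at `bleeding_rate` per minute. Circulatory
vitals are algebraic functions of the volume deficit:

    SBP = SBP₀ − k_SBP (1 − V),   DBP = DBP₀ − k_DBP (1 − V),
    HR  = HR₀  + k_HR  (1 − V)

with defaults `k_SBP = 120`, `k_DBP = 60`, `k_HR = 60` mmHg (bpm) per unit
volume fraction — a narrowing pulse pressure and compensatory tachycardia
as shock deepens. The bleeding rate is calibrated per scenario so SBP
reaches its lethal lower bound exactly at the remaining lifetime:
`bleeding_rate = (SBP₀ − SBP_lethal) / (k_SBP · T)`.

**Independent vitals.** SpO₂, respiratory rate, temperature and
consciousness deteriorate along their own linear slopes, calibrated to
cross their lethal bound at `deterioration_slack × T` (default 1.5 T), so
hemorrhage is always the proximate cause of an untreated death while the
other vitals still degrade visibly (the default patient drops below the
35 °C hypothermia threshold after ~33 min). Once bleeding is controlled,
these slopes are scaled by `controlled_deterioration_factor` (default 0:
stopping the hemorrhage arrests the secondary, shock-driven decline) —
without this, a perfectly treated patient would still die of untreated
drift in vitals no catalog action addresses.

**Actions.** Effects are additive deltas with physiological clipping
(SpO₂ ≤ 100, consciousness in [3, 15], …) plus multiplicative slope
modifiers (supplemental oxygen halts desaturation; warming halts heat
loss). A pelvic binder multiplies the bleeding rate by
`binder_bleeding_factor` (default 0.1). Bleeding counts as *controlled*
at or below `controlled_threshold_fraction` (default 0.25) of the
scenario's calibrated untreated rate — a relative threshold so the rule
behaves identically across scenarios with different lifetimes. Fluids
(crystalloids +0.10, blood +0.15 volume fraction) are retained at
`uncontrolled_fluid_efficiency` (default 0.2) while bleeding is
uncontrolled — volume infused against an open hemorrhage is mostly lost —
and at full efficiency afterwards. Consequences: fluids given after the
binder always beat identical fluids given before, and an earlier binder
never yields lower blood volume at any later time (both property-tested).

When an action and a tick coincide, the action applies first (trainee
input precedes passive deterioration at the same timestamp). Death is
absorbing. A session ends at death, at the last scripted action, or at an
explicit `session_end`; an empty script runs to death or the horizon
(default 480 min).

## The reference grammar

Guideline-consistent treatment sequences are generated by a slot grammar
in strict phase order A < B < C < D < E (no interleaving — the primary
survey is priority-ordered). Slot kinds: mandatory, alternative (choose
exactly one of m), optional (0/1), repeatable (1 to 1+r consecutive
occurrences). The default model:

| Phase | Slots |
|---|---|
| A | airway inspection (mandatory); airway clearing (optional) |
| B | oxygenation (mandatory); intubation (optional) |
| C | vascular access (alternative of 3 routes); pelvic binder (mandatory); crystalloids (repeatable ≤ 3); blood transfusion (repeatable ≤ 3) |
| D | disability assessment (alternative of 2: talk to patient / pupil response) |
| E | warming (alternative of 2: thermal blanket / hot liquids) |

The generating function for the sequence-length distribution is
`12 · x⁸ · (1+x)² · (1+x+x²)²` — 12 = 3·2·2 from the alternatives,
`(1+x)²` from the two optional slots, `(1+x+x²)²` from the two repeatable
slots — giving 432 sequences with counts 12, 48, 96, 120, 96, 48, 12 at
lengths 8–14. The concrete clinical labeling of the alternative and
optional slots is this package's design choice; any labeling with the same
slot structure yields the same combinatorics, and the grammar is ordinary
data that can be rebuilt with the exported slot constructors. Membership
(`is_reference`) is decided by backtracking slot matching, not by lookup
in the enumerated set, and the two are proven equivalent in tests.

## Scoring

The field tool's notions of "correct" and "sequential" actions are not
formally defined anywhere we can adopt them from, so they are
operationalized as:

- `n_correct` — max over reference sequences of the LCS length between
  the logged action sequence and the reference: right actions in the
  right relative order, tolerating interspersed extras;
- `n_sequential` — the longest contiguous block of the log occurring
  contiguously in some reference: uninterrupted guideline adherence.

Both reduce to the intuitive values on perfect and empty logs, and
`n_sequential ≤ n_correct ≤ n_actions` always (a common substring is a
common subsequence). Cohort tables use mean ± sample SD (n−1) and
half-up integer percentage rounding (`20/28 → 71%`). A single-session
group is flagged and its SD reported as 0 by convention.

## Statistics

The Wilcoxon rank-sum test uses midranks for ties. For tie-free pooled
samples with `n₁+n₂ ≤ 12` the null distribution of the rank sum W is
computed exactly by a subset-sum dynamic program over all `C(N, n₁)`
equally likely rank assignments; otherwise a normal approximation with the
standard tie-corrected variance and a 0.5 continuity correction. Two-sided
p-values are `min(1, 2·min(P(W≤w), P(W≥w)))`; significance is declared at
α = 0.05. A constant pooled sample is returned as p = 1 and flagged
(`method="degenerate"`) rather than raising. The exact path is validated
exhaustively against an independent permutation oracle for all tie-free
instances with `n₁+n₂ ≤ 10`, and both paths against an independent
library implementation.

Quartiles use linear interpolation between order statistics (the
convention implied by fractional quartiles like Q1 = 2.50 on integer
timing data). Likert responses are ordinal: medians only, per question,
per group and pooled; ratings outside 1–7 or unknown question ids are
rejected.

## Synthetic trainees

The generator replaces human participants so the full pipeline is testable
end to end. A behavior profile holds, per action: a performance
probability, a log-normal timing distribution (median minutes and
log-scale σ — positive support and right skew, matching how response-time
spreads look in practice), plus a scalar `adherence`.

Sampling: a reference sequence is realized slot by slot; the profile owns
each slot's single inclusion draw, so the marginal probability of
performing any mandatory, optional, repeatable or mutually exclusive
action equals its profile value exactly (verified by Monte-Carlo recovery
within 3 binomial SE at n = 10⁴). Members of a non-exclusive alternative
slot (the three access routes) recover their value divided by the number
of alternatives, because a trainee commits to one route. Thermal blanket
and hot liquids form the built-in mutually exclusive pair: the union fires
with the sum of the marginals and one measure is chosen proportionally —
chosen because the observed union percentages of the motivating cohort
equal the sums of the marginals. Inclusion is otherwise independent across
actions (only marginal proportions are observable; a correlation hook
would be speculation).

Ordering is built step-wise — follow the reference order with probability
`adherence`, else jump to a uniformly random remaining action — and one
timing draw per performed action is taken from its log-normal; the sorted
draws are assigned to the constructed order. The two requirements (times
drawn per action; order governed by adherence) cannot both bind the same
timestamps when they disagree, so order is adherence-driven and the time
multiset profile-driven; with adherence 1 the script is exactly a
reference sequence. Default profiles: 28 students (adherence 0.6, wider
timing dispersion) and 13 doctors (0.8, tighter), with per-action
probabilities set to the pilot cohort's observed fractions and timing
medians following the reported response times where available (airway
inspection ~4 vs ~1.5 min; pelvic binder 72 vs 157 min).

Cohort generation spawns one child RNG per trainee from a single seed
sequence, so cohorts are reproducible and insensitive to roster order.

## Problem sizes and numerical notes

The enumeration (432 sequences, ≤ 14 actions) and all scoring DPs are
exact integer computations; no tolerances are involved. Engine arithmetic
is double precision; the untreated death-time test allows ± 1 tick for the
boundary-crossing rounding. Property suites run at 15–60 random examples
each (derandomized), the Monte-Carlo recovery at n = 10⁴ scripts, and
synthetic cohorts at the study size of 28 + 13; the full suite completes
in seconds on one core.

## Limitations

- The vital-sign update rules reconstruct a plausible engine honoring the
  stated constraints (linear untreated decline, death at the remaining
  lifetime, binder/fluid coupling); they are not fitted to physiological
  data, and real trauma dynamics are neither linear nor deterministic.
- Scenario timings are pure simulated minutes; treatment times of ~230
  "minutes" are taken at face value.
- Synthetic trainees have no learning or cognitive model, and inter-action
  correlations beyond the warming exclusivity are absent, so passing
  pipeline tests demonstrates mechanical correctness of the analytics, not
  realism of human behavior; group-comparison p-values on synthetic
  cohorts reflect the assumed profiles only.
- Only the pelvic primary survey is covered: one injury, no secondary
  survey, no polytrauma.
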