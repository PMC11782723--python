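# Methods

This note documents the measurement model, the statistical layer, the
synthetic-data generator, and the numerical and design choices behind
`dyadtrack`, in enough detail to audit or re-derive any quantity the
package computes.

## Measurement model

**Grid.** All quantities are defined on a uniform 10 Hz grid
(`sample_interval = 0.1 s`). Raw tag streams at any rate are resampled
onto this grid by linear interpolation between the bracketing samples.
A grid step is valid for a tag when it lies within the tag's sampled
span and the bracketing samples are at most `max_gap` seconds apart
(default 1.0 s); steps strictly inside longer dropouts are marked
invalid rather than interpolated, to avoid fabricating motion across
long gaps. A person's timestep is valid only when *both* tags are valid
there.

**Position, velocity, heading.** Location is the midpoint of the left
and right tag positions. Linear velocity is the Euclidean displacement
of the midpoint over one grid step (meters per 0.1 s); it is undefined
(not zero) at the first step of each valid run. Heading is
`θ = atan2(x_R − x_L, y_L − y_R)`: the facing unit vector is the
left→right shoulder vector rotated 90° counterclockwise. Internally all
angles are radians in standard mathematical convention; degrees appear
only at the criterion boundaries. Heading is undefined when the two
tags coincide exactly (possible in synthetic or degraded data); such
steps cannot produce contact and contribute no orientation weight.
Positions are *not* smoothed before differencing — any filtering is the
caller's responsibility and none is applied by default.

**Approach distance.** For approacher A and partner B,
`Approach_{A→B}[t] = ‖A_{t−1} − B_{t−1}‖ − ‖A_t − B_{t−1}‖` under the
default `initial_partner_position` convention: approach is movement
toward *where the partner was* one tenth of a second ago. An
alternative `current_partner_position` convention
(`… − ‖A_t − B_t‖`) is retained behind a flag; the two differ only when
the partner moves, and the default was chosen because it isolates the
approacher's own action. Steps where the dyad's previous distance is
zero are excluded downstream.

**Weighted social approach velocity.** Per qualifying step,

```
w[t] = Approach_{A→B}[t] · cos²(θ_o[t−1]) · cos²(θ_m[t]) / ‖A_{t−1} − B_{t−1}‖
```

where θ_o is the angular deviation of A's heading at t−1 from the
bearing A→B at t−1, and θ_m the deviation of A's movement vector over
the step from that same bearing. A step qualifies when both partners
are valid at t−1 and t, the previous distance is positive, the approach
is positive, A's heading at t−1 is defined, and A moved (a zero
displacement leaves θ_m undefined and the step is skipped).
Negative-approach steps are excluded from the mean, not clipped to
zero. The summary statistic is the arithmetic mean of `w` over
qualifying steps — a dimensionless proportion of the initial dyad
distance closed per 0.1 s; a dyad with no qualifying step is missing,
never zero. Two notes on the cos² weights: (i) they are applied exactly
as defined, so a deviation above 90° still yields a positive weight
(cos²135° = 0.5); in practice positive-approach steps with large
deviations are rare, but the behavior at θ → 180° is a property of the
formula, not of this implementation. (ii) positive-approach steps with
θ = 90° (zero weight) still count in the mean's denominator, since they
satisfy the approach criterion.

**Social contact.** A timestep is in contact when the pair's
instantaneous distance lies in `[d_min, d_max]` (defaults 0.2 and
2.0 m, both inclusive) *and* each partner's heading deviates from the
bearing to the other by at most 45° (inclusive). Contact is symmetric
and instantaneous: no minimum episode duration, hysteresis, or
smoothing of the indicator is applied. Time in social contact is the
number of in-contact steps divided by the number of steps both partners
were jointly valid; it is missing when the dyad shares no time.

**Radial distribution function.** g(r) is the ratio of the observed
pair-distance density (pooled over all dyads and shared timesteps,
0.1 m bins from 0 to the room diagonal) to a null density in which each
person's trajectory is independently circularly time-shifted by a
uniform random offset (20 replicates by default, seeded). The circular
shift preserves each individual's speed profile and room occupancy
while destroying inter-person coupling. Bins where the null is empty
but the observed mass is positive are flagged rather than dropped. The
widest contiguous run of bins with g > 1 is reported as a diagnostic
alongside — never instead of — the fixed 0.2–2 m analysis band. This
null is one concrete instantiation of "random movement irrespective of
others"; alternatives (e.g., uniform position resampling) can be
swapped behind the same interface.

## Aggregation

Dyad summaries collapse to one row per child × observation: mean social
approach velocity toward and from teachers and peers, contact
proportion with teachers and peers, and the three preference indices
(teacher value minus peer value; positive = teacher preference). Within
a partner role, each dyad contributes equally by default
(`equal_per_partner`); weighting by shared seconds is available
(`shared_time_weighted`). A missing side (e.g., a session with no
teacher data) makes the preference missing, never zero. The observation
index is the session's rank within its classroom.

## Statistical layer

Each outcome is modeled with a three-level random-intercept linear
mixed model: observations (Level 1) nested in children (Level 2) nested
in classrooms (Level 3), estimated by REML via statsmodels' MixedLM
(classroom as the grouping factor, child as a variance component; this
parameterization was verified against lme4 to ~6 decimal places on a
common dataset, and that check is part of the test suite). Group is
entered as a TD-reference treatment coding, so the intercept is the TD
mean and the ASD/DD coefficients are contrasts. Continuous predictors
are mean-centered within child before entry, separating within-child
from between-child variation.

* **Wald tests**: t = B/SE with p from the standard normal. The normal
  reference is a documented simplification (no df convention is
  attached to the Wald t); at the study's size it is mildly
  anticonservative (measured type-I ≈ 0.018 at nominal 0.01 over 500
  null replicates — within the binomial CI of the nominal rate). A
  Satterthwaite approximation could be substituted without changing any
  interface.
* **Confidence intervals**: B ± 1.96·SE.
* **Effect size**: d = 2t/√df with df = n_obs − (number of fixed-effect
  parameters). This is one convention among several in the multilevel
  literature; it is applied uniformly to all contrasts.
* **ICCs**: each level's variance over the total
  (child + classroom + residual).
* **Random-effect tests**: REML deviance (−2·log-restricted-likelihood)
  difference between nested random structures referred to χ²(1). The
  usual caveat applies: testing a variance at its boundary makes this
  conservative.
* **Degenerate fits**: variance components estimated at (or near) zero
  are reported at the boundary with a flag, not raised as errors.
  Optimizer failures fall back through l-bfgs → Powell → CG.
* **Significance**: α = 0.01 throughout.

## Synthetic classroom generator

The generator emulates the *measurement conditions* of dual-tag
classroom tracking and provides programmable ground truth; it does not
attempt behavioral realism (no circle time, activities, or nap
transitions), and it does not try to match any empirical velocity
distribution.

Mechanics: agents move in a 9 × 9 m room (the emulated rooms are
~8.4–9.6 m per side). Each agent alternates between goals: with
probability `p_social = 0.7` it selects a partner — with probability
proportional to its affinity row — and walks toward them (pursuit of
the partner's current position) at a per-leg speed drawn from
U(0.3, 0.9) m/s, stopping at a face-to-face distance drawn from
U(0.35, 0.9) m and dwelling for U(4, 15) s while facing the partner;
otherwise it walks to a uniform waypoint and pauses U(0.5, 2) s. A
partner who is not walking reciprocates the dwell (turns to face the
approacher), so mutual-orientation contact episodes exist by
construction, inside the 0.2–2 m band. Headings follow the movement
direction while walking. Tags are emitted at ±0.15 m perpendicular to
the heading with isotropic Gaussian noise (0.15 m per axis — the
emulated spatial accuracy) and 2% per-tag per-step dropouts. Everything
is driven by one seeded generator: identical seeds give byte-identical
streams.

Affinities are the programmed study conditions, set once: ASD
teacher:peer = 3:1, DD = 1.5:1, TD = 1:2; teachers approach children.
These encode the qualitative contrast the pipeline must recover —
children with ASD preferring teachers, TD children preferring peers —
at a designed-in large effect appropriate for validation.

The study-shaped fixture has 8 classrooms sharing 24/23/30 children
with ASD/DD/TD and 3 teachers per room; each classroom is observed on 4
occasions and each child attends 3 or 4 of them. The `scale` parameter
shortens the ~121-minute sessions for desk-scale computation; tests and
the acceptance script use scale = 0.04 (~290 s per session), at which
the programmed contrasts are recovered with large margins while a full
50-replicate recovery experiment completes on one CPU in minutes.

**What the generator does not emulate — and what passing tests
therefore do not show.** Affinities are assigned at the group level:
there is no child-specific social trait and no classroom-level
heterogeneity beyond sampling. Consequently, in end-to-end runs, the
child and classroom variance components of the fitted models are
genuinely (and correctly) near zero — the generator contains no such
variance. Recovery of non-zero variance components, ICCs, and the
deviance tests is therefore validated against a second generator that
draws outcomes directly from the three-level linear model with known
components (`simulate_analysis_table`). Passing tests demonstrate the
pipeline measures what was programmed; they say nothing about
behavioral realism, vest compliance, localization artifacts, or
non-Gaussian noise in real deployments.

## Numerical choices

* Grid snapping tolerance 1e-9 s; a grid point coinciding with a raw
  sample is always valid regardless of the surrounding gap.
* Duplicate timestamps within a tag stream are collapsed to their mean
  reading before interpolation.
* The 45° and 0.2/2.0 m criteria are inclusive; ties at the boundary
  count as contact.
* The dyad-metric pipeline is vectorized over timesteps; agreement with
  a pure-Python per-step reference is asserted to 1e-12 on random
  dyads of up to 500 steps (both approach conventions).
* Densities in g(r) are normalized counts; binomial standard errors use
  the null density and the observed pooled count.
* χ² deviance differences that come out negative (possible with
  separate optimizations) are reported as computed with p = 1.

## Known limitations

* The Wald p-values use a normal reference; small-sample inference on
  fixed effects is slightly liberal (quantified above).
* The d = 2t/√df conversion depends on the df convention; with
  observation-level df it is not comparable across models with
  different observation counts per child.
* The circular time-shift null preserves marginal occupancy but also
  preserves within-person temporal autocorrelation exactly; nulls that
  resample positions would give a different (more liberal) reference.
* Teacher-teacher dyads are computed but not modeled; split-shift
  classrooms (different rosters morning/afternoon) are representable as
  separate sessions, and no pooling rule across shifts is imposed.
* No multiple-imputation or weighting for missing observations: a
  child's missing session is simply absent at Level 1.
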