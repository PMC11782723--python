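# dyadtrack

Objective measurement of social preference in preschool classrooms from
dual-tag indoor location tracking.

Inclusion classrooms place children with autism spectrum disorder (ASD)
and other developmental disabilities (DD) alongside typically developing
(TD) peers. Wearable ultra-wideband tags — one on each shoulder — record
every child's and teacher's position at 10 Hz with ~15 cm accuracy,
which makes it possible to measure *who approaches whom, how fast, and
who spends time face-to-face with whom* without human coders. This
package implements that measurement pipeline and the multilevel group
comparisons built on it, for developmental researchers working with
dual-tag positioning streams (and anyone who needs a tested reference
implementation of these social-affiliation metrics).

## What it computes

From per-tag coordinate streams, for each person at each 0.1 s step:
position `(x_t, y_t)` (the midpoint of the left/right tags), linear
velocity `‖(x_t, y_t) − (x_{t−1}, y_{t−1})‖`, and heading
`θ = atan2(x_R − x_L, y_L − y_R)` (the shoulder vector rotated 90°
counterclockwise).

For each ordered dyad (approacher A, partner B):

* **Approach distance**
  `Approach_{A→B}[t] = ‖A_{t−1} − B_{t−1}‖ − ‖A_t − B_{t−1}‖` — how much
  closer A moved to B's previous position (negative = moving away; such
  steps are excluded, not clipped).
* **Weighted social approach velocity**
  `Approach_{A→B}[t] · cos²θ_o · cos²θ_m / ‖A_{t−1} − B_{t−1}‖`, where
  θ_o is the deviation of A's heading from the bearing to B and θ_m the
  deviation of A's movement direction from that bearing. The session
  summary is the mean over positive-approach steps: a dimensionless
  proportion of the dyad gap closed per 0.1 s.
* **Social contact**: timesteps when the pair is 0.2–2 m apart and
  mutually oriented within |45°|; **time in social contact** is the
  in-contact fraction of the time both partners were present. The 0.2–2
  m band is diagnosed by a radial distribution function g(r) comparing
  observed pair distances to a circular time-shift null of independent
  movement.

Per child × observation these collapse to teacher- and peer-directed
means and three teacher-over-peer preference indices (teacher minus
peer). Group differences are estimated with three-level random-intercept
models (observations in children in classrooms; REML), parameterized as
a TD intercept with ASD and DD contrasts, Wald tests, `d = 2t/√df`
effect sizes, ICCs, and χ² deviance tests for the random effects.

A fully programmable agent-based classroom simulator (waypoint movement
plus face-to-face dwells, group-dependent teacher/peer affinities, tag
noise and dropouts) generates study-shaped synthetic data so every stage
is testable end-to-end.

## Worked example

```python
import pandas as pd
import dyadtrack as dt

# simulate a study-shaped dataset: 8 classrooms, 24/23/30 children with
# ASD/DD/TD, 3-4 observations per child (sessions shortened to ~290 s)
fixture = dt.make_study_fixture(scale=0.04, seed=0)

summaries = pd.concat(
    [dt.summarize_session(dt.states_for_session(r.session, r.tags), r.session)
     for r in fixture.sessions],
    ignore_index=True,
)
table = dt.build_analysis_table(summaries)

result = dt.fit_three_level(dt.ModelSpec("pref_contact"), table)
print(dt.models.format_fixed_effects(result))
```

```
Outcome: pref_contact   (n_obs=276, children=77, classrooms=8)
Group                        B          SE                    95% CI       t        p       d
TD (intercept)      -0.0023106   0.0012594    -0.004779 – 0.00015774   -1.83    0.067
ASD                   0.012627   0.0019019      0.0088987 – 0.016354    6.64   <0.001    0.80
DD                   0.0031648   0.0019419    -0.00064139 – 0.006971    1.63    0.103    0.20
Variance: child=8.831e-13  classroom=1.784e-14  residual=0.0001743   ICC child=0.000  classroom=0.000
```

Reading this: the contact-preference index for TD children leans toward
peers (negative intercept), while the ASD contrast (+0.0126, p < 0.001,
d = 0.80) shows children with ASD shifted toward teachers relative to
TD — exactly the teacher-over-peer preference the simulator programmed
in (ASD teacher:peer affinity 3:1 vs TD 1:2). The child and classroom
variance components sit at the boundary (zero) because the movement
simulator assigns affinities at the group level with no child- or
classroom-specific traits, so there is no stable between-child variance
to find; the variance-decomposition machinery is exercised against a
generator with known non-zero components in the test suite.

The same analysis runs from the shell:

```bash
dyadtrack run-all --seed 0 --out results/demo --scale 0.04
```

which writes dyad summaries, the g(r) diagnostic, the analysis table,
all nine group models (JSON + text tables) and a reproducibility
manifest.

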