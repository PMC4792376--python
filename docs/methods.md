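# Methods

## From beacon logs to contacts

A deployment is a set of motes on a shared clock, each broadcasting every
`tick_seconds` (default 20 s) and logging `(receiver, sender, timestamp,
rssi)` for every beacon heard.  Processing:

1. **RSSI threshold.**  Records with `rssi ≥ −80 dB` are kept.  −80 dB
   corresponds to ~3 m face-to-face separation.  The cut is applied per
   record, before directions are combined; the alternative (cutting after
   combining directions) differs only for pairs whose two directions
   straddle the threshold within one tick.
2. **Pair-ticks.**  A record at time t belongs to tick ⌊t/tick_seconds⌋.
   Under the default `union` rule, a pair-tick exists if either direction
   was heard in that tick.  One-sided records are common in real deployments
   (flash corruption, asymmetric loss), so union is the robust default;
   the stricter `mutual` rule (both directions required) is available.
3. **Encounters.**  Per pair, maximal runs of consecutive ticks
   (`max_gap_ticks = 0`, i.e. no bridging of missing ticks by default; a
   tolerance bridges gaps but duration always counts recorded ticks, not
   the bridged span).
4. **Contacts.**  Per pair, `total_recordings = Σ n_ticks` over the day and
   `cumulative_minutes = total_recordings × tick_seconds / 60` — exactly
   x/3 for 20-second ticks.

Records touching staff or stationary motes are dropped before the student
network is built.

## Network statistics

The contact network keeps student–student contacts whose cumulative minutes
are **strictly greater** than the threshold (default 5).  "Contacts below
five minutes are ignored" leaves the tie at exactly 5.0 minutes (15
recordings, a value the tick grid actually produces) ambiguous; strict
comparison makes the recording-count sweep `w > t` consistent at every
step.  Nodes are the students with at least one surviving edge, so isolated
students do not enter degree/clustering averages.

Summary rows report mean ± sd and the standard error sd/√n over students.
The per-contact duration column is the across-student mean of
strength/degree (each student's average minutes per contact), not total
strength; both are exposed.  Clustering is binary on the thresholded graph:
weights are deliberately ignored, as several of these measures have no
standard weighted form.  The overlap ratio of an edge is
`O_ij = n_ij/(k_i−1+k_j−1−n_ij)`, defined as 0 for a pendant pair (zero
denominator).  Contact matrices normalise edge counts per pair of students:
`M[g,h] = m_gh/(n_g n_h)` off-diagonal and `M[g,g] = m_gg/(n_g(n_g−1)/2)`.

Weighted Newman–Girvan modularity is evaluated against partitions that are
always externally given (the roster's grades or classrooms); community
*detection* is out of scope.  Both the weighted and the binarized variant
are exposed.  In the threshold sweep (default step 10 recordings = 3 min
20 s), nodes isolated at a step drop out together with their partition
entries; points where fewer than two communities or zero edges survive are
flagged unreliable rather than suppressed.

## Duration distributions and power-law fits

Four empirical samples: encounter durations (seconds), inter-encounter gaps
(seconds between the end of one encounter and the start of the next for the
same pair, exclusive on both sides), encounters per pair, and cumulative
contact durations (minutes).  Power-law fits follow the
Clauset–Shalizi–Newman recipe: maximum-likelihood exponent above x_min with
x_min chosen by minimal Kolmogorov–Smirnov distance (candidates thinned to
≤ 100 quantiles of the distinct values; a tail needs ≥ 50 points).
Tick-quantised samples use the discrete (Hurwitz-zeta) likelihood,
optionally upper-truncated when a hard ceiling (the school day) bounds the
support; contact minutes use the continuous closed form.  The exponent is
reported as the negative density exponent β.  Signal-strength magnitudes get
a one-parameter exponential-rate MLE, descriptive only.

## The synthetic school-day generator

The generator emulates a one-day deployment in a school of
`n_grades × classrooms_per_grade` classrooms of `class_size` students
(defaults 4 × 2 × 20 = 160 students, with 2 stationary motes), on an
08:30–15:00 day of seven ~45-minute class periods, three 10-minute breaks
and a 35-minute lunch, all boundaries on the 20-second tick grid.

Room assignment is the modularity dial.  `cohort` mode keeps each classroom
together every class period, sends grades to per-grade break rooms and
lunch-group rooms (grades eat in pairs by default, configurable via
`lunch_groups`).  `individualized` mode redraws every student's room
uniformly over all classrooms each class period and pools the whole school
at breaks.

Within a room, each pair follows a start-hazard/heavy-tail process:
an idle pair starts an encounter with probability `p_encounter = 0.02` per
tick, and the length in ticks is drawn from a discrete power law
pmf ∝ d^β_sim on [`min_encounter_ticks`, period length], clipped at the
period boundary (the bell ends interactions).  During breaks and lunch,
any pair *not* sharing a room additionally receives a minimum-length
background encounter with probability `p_background = 0.002` per tick —
hallway brushes between classrooms and grades.  Every planted pair-tick
emits two directed records with RSSI ~ N(−65, 3²) dB; optionally,
out-of-range pairs emit sparse far-field records (N(−92, 3²)), and an
independent per-record drop probability models asymmetric loss (default 0).
All randomness flows through one generator seeded from `seed`; identical
configurations give byte-identical logs.

Parameter choices, with reasoning:

* `duration_exponent β_sim = −1.2` sits at the centre of the exponent band
  reported for school contact-duration distributions (−0.9 to −1.4).  With
  it, the default cohort school lands where elementary-school deployments
  land: ~43 minutes mean per-contact duration, roughly half of all contacts
  at ≤ 5 minutes, just under a fifth above 30 minutes, grade modularity
  ~0.64, and a contact-duration exponent ≈ −1.0 over the 1–60 minute
  regime.
* `p_encounter = 0.02` per tick gives classmates a plausible in-class
  interaction budget (a busy fraction of ~20 % of class time per pair)
  without saturating the day.
* `p_background = 0.002` produces a thin mat of short cross-room contacts —
  enough that the unthresholded network is school-wide connected, few
  enough that the 5-minute threshold removes most of them.
* RSSI means ±3 dB place in-range and out-of-range pairs ~9 sd apart, so
  the −80 dB rule separates them essentially perfectly; deployments with
  obstructions would overlap more, which this generator does not model.

What the generator does **not** emulate: continuous movement and radio
propagation (co-location is binary per room), flash corruption and clock
drift (a shared exact clock is assumed; real deployments synchronised via
stationary motes), multi-day variation, teacher interaction patterns, and
room-capacity constraints in individualized mode.  Passing tests on this
generator therefore validate the *analysis chain* and the qualitative
schedule-regime contrasts, not quantitative predictions for any real
school; absolute densities in particular run higher than in large real
schools because the synthetic school is small (density falls with n at
comparable per-student contact counts).

## Numerical and design notes

* **Boundary clipping vs exponent recovery.**  Clipping encounter lengths at
  bells steepens the observed duration distribution relative to β_sim when
  periods are short relative to typical draws.  The generator-recovery test
  therefore uses a school day consisting of one long uninterrupted class
  period, where the truncated discrete MLE recovers β_sim to ~0.01; under
  the default bell schedule the fitted exponent is ~0.2 steeper, which is a
  property of the observation process, not an estimator defect.
* **Contact-duration exponent window.**  On synthetic data the KS-optimal
  x_min locks onto the steep upper bump created by classmates who share
  every period (a feature real schools show as medium-duration "bumps").
  The headline contact-duration exponent is therefore fitted over the
  1–60 minute window (x_min = 3 recordings, x_max = 180) with the truncated
  discrete likelihood — the regime where the distribution is actually
  power-law-like.
* **Ties and degenerate inputs.**  Density and summaries require n ≥ 2;
  modularity requires ≥ 1 edge and a partition covering every node; overlap
  of a pendant edge is 0 by convention; empty weight bins are flagged, not
  dropped; constant or short (< 50 tail points) samples make the power-law
  fit raise instead of returning noise.
* **Scale of shipped analyses.**  Tests and the acceptance script use the
  160-student default school (and a 320-student single-period school for
  exponent recovery); these sizes keep full runs fast while leaving every
  distributional check thousands of observations.
* **Node-count convention.**  n counts students with ≥ 1 surviving edge at
  the given threshold.  Published per-school tables count tagged students
  the same way to within one node; the real-data check tolerates ±1.
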