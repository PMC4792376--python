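# schoolnet

Contact-network analysis of proximity-sensor deployments in schools, built
for epidemiological modelling of respiratory-infection transmission among
students.

Wireless motes worn by students broadcast a beacon every 20 seconds and log
every beacon they hear together with its received signal strength (RSSI).
Records stronger than −80 dB correspond to roughly 3 m face-to-face
separation — the range relevant to droplet transmission.  `schoolnet` turns
such logs into the quantities school-mixing studies report:

* **pair-ticks → encounters → contacts.**  A pair-tick is evidence that a
  pair was in proximity during one beacon interval; a maximal run of
  consecutive pair-ticks is an *encounter*; a pair's accumulated recordings
  over the day form its *cumulative contact*, with x recordings = x/3
  minutes of contact time.
* **weighted contact network.**  Students are nodes; edge weight w_ij is the
  pair's cumulative contact minutes.  Contacts of at most 5 minutes are
  discarded by default.  Summary statistics: density δ = 2m/(n(n−1)),
  degree k_i, strength s_i = Σ_j w_ij, mean minutes per contact s_i/k_i,
  binary local clustering CC_i, and the edge overlap ratio
  O_ij = n_ij/(k_i−1+k_j−1−n_ij) with n_ij the number of common contacts.
* **modularity against school structure.**  Weighted Newman–Girvan
  modularity Q = (1/2W) Σ_ij (w_ij − s_i s_j/2W) 𝟙[c_i=c_j] against the
  *externally given* grade or classroom partition (never inferred), plus its
  behaviour under a sweep of contact-duration thresholds.
* **mixing matrices and duration distributions.**  Grade×grade contact
  matrices (edges per pair of students), degree histograms N_k, time-binned
  degree in 3-minute intervals, and maximum-likelihood power-law fits
  P(w) ~ w^β to the heavy-tailed encounter/contact duration distributions
  (Clauset–Shalizi–Newman x_min selection, continuous and discrete,
  optionally upper-truncated).
* **a synthetic school-day generator.**  Rosters, bell schedules and beacon
  logs with planted ground truth, in two regimes: `cohort` schedules keep a
  classroom together all day (elementary/middle style, high modularity);
  `individualized` schedules reassign every student to a grade-mixed room
  each period (high-school style, low modularity).

## Worked example

```python
import schoolnet as sn

config = sn.elementary_config(seed=1)          # 4 grades x 2 classrooms x 20
result = sn.simulate_school_day(config)
records = sn.filter_by_rssi(list(result.records))          # -80 dB cut
records = sn.filter_students(records, result.roster.student_ids())
ticks = sn.records_to_pair_ticks(records, config.tick_seconds)
encounters = sn.pair_ticks_to_encounters(ticks, config.tick_seconds)
contacts = sn.encounters_to_contacts(encounters)
net = sn.build_network(contacts, result.roster)            # > 5 min survives

print(sn.summarize(net))
part = sn.Partition.from_roster(result.roster, "grade").restricted_to(net.nodes)
print(sn.modularity(net, part))
```

Running `examples/simulate_and_summarize.py` (which does exactly this)
prints:

```
1033608 in-range records -> 516804 pair-ticks -> 41005 encounters -> 7993 contacts
n   = 160
δ   = 0.303
d   = 48.2 ± 3.5 (0.3)
s   = 43.4 ± 3.6 (0.3) minutes per contact
CC  = 0.63 ± 0.01 (0.00)
```

i.e. every tagged student keeps ≥ 1 contact after thresholding, each student
has about 48 contacts of 5+ minutes averaging ~43 minutes each, and
about 63 % of a student's contact pairs know each other.
`examples/modularity_contrast.py` adds the schedule-regime contrast:

```
grade modularity, cohort schedules:         Q = 0.641
grade modularity, individualized schedules: Q = 0.052
```

— grades are near-separate communities under cohort schedules and
indistinguishable from random mixing under individualized ones, which is
the property that decides whether homogeneous-mixing epidemic models are
appropriate for a school.

Other entry points: `examples/duration_distributions.py` (power-law fits and
duration fractions), `examples/full_pipeline.py` / the `schoolnet` command
(file-based runs over beacon-log/roster CSVs, prebuilt Pajek/GraphML/edge-CSV
networks, YAML configs).

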