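# choreoquant

Quantification of the choreography of the chromosomal replication origin
(*ori*) and terminus (*ter*) in slow-growing *Escherichia coli*, from
mother-machine time-lapse tracking data.

In slow-growing *E. coli* the terminus region starts the cell cycle near
the new pole and must migrate to mid-cell during replication so that the
daughter cells inherit the same arrangement. `choreoquant` implements the
single-cell analysis that quantifies this transition: it consumes tracked
per-cycle records (per-frame cell geometry, fluorescent focus positions
for *ori* and MatP-labelled *ter*, optional nucleoid line profiles,
lineage links and polarity) and produces per-cycle event times,
population kymographs/demographs, event-synchronised velocity curves and
chromosome-orientation statistics. A seeded synthetic-data generator with
full ground truth makes every stage testable without any microscopy data.

It is intended for microbiologists and biophysicists analysing
mother-machine experiments at the tens-of-thousands-of-cell-cycles scale.

## The quantities it computes

With frames every Δt = 5 min, pixel size 0.065 µm, long-axis coordinate
`x ∈ [0, L]` (new pole at 0), `u = x − L/2`, `r = u/L`, and cell age
`a = frame/(n−1)`:

* **T_ori** — first frame with two *ori* foci. If this happens within the
  first 4 frames, the mother cell is searched for the frame at which the
  focus count in the inherited half rose to two, and a *negative* frame
  number is reported.
* **T_MatP** — first frame of the first run of ≥ 3 consecutive frames
  (15 min) in which the MatP focus nearest mid-cell satisfies
  |u| ≤ 2.4 px (the central 4.8 px ≈ 0.31 µm of the cell).
* **T_Nucleoid** — earliest frame from which the nucleoid line profile
  stays constricted until division. A profile is constricted when the
  relative depth of its central dip, `(min(a,b) − m)/min(a,b)` with `m`
  the minimum over the middle third and `a, b` the flanking maxima,
  exceeds a threshold (0.13 by default, derivable as the 95th percentile
  of newborn dip depths).
* **T_terSep** — first persistent run of ≥ 2 MatP foci (sister *ter*
  separation).
* **Registration** — the lateral offset between the cell frame and a
  fluorescence channel is the shift that symmetrises the population-mean
  line profile in device coordinates (cells sit in the device in both
  orientations, so the true mean profile is symmetric).
* **Population statistics** — kymographs normalised per cell cycle at
  each age, demographs by cell length, event-synchronised kymographs,
  mean step-wise focus velocities toward the old/nearest pole, nucleoid
  kymographs with 50 %/80 % signal-mass contours, and arrangement
  patterns such as `NP-L-O-OP` (new pole — left-arm locus — *ori* — old
  pole).

## Worked example

Generate 2,000 synthetic cell cycles at the default (study) conditions,
detect the events and summarise the timings:

```python
from choreoquant import GeneratorParams, generate_dataset, PipelineConfig
from choreoquant.events import detect_events
from choreoquant.population import timing_summary

params = GeneratorParams(n_cycles=2000, seed=7)
ds, truth = generate_dataset(params)
config = PipelineConfig()
events = detect_events(ds, config)
subjects = events[events.cell_id.isin(truth.table.cell_id)]
s = timing_summary(subjects, config)
print(s.events.round(1).to_string(index=False))
print(s.pairs.round(1).to_string(index=False))
print(f"ordered fraction: {s.ordered_fraction:.3f}")
```

prints

```
   event    n  mean_min  sd_min  median_min
   t_ori 2000      25.3    26.5        25.0
  t_matp 1995      53.7    24.3        50.0
   t_nuc 2000      99.6    36.3        95.0
t_tersep 1674     123.1    27.0       125.0
         event    n  mean_min  sd_min  median_min
t_matp - t_ori 1995      28.4    24.3        30.0
t_nuc - t_matp 1995      46.0    29.0        40.0
ordered fraction: 0.995
```

Read: *ori* duplicates a median 25 min after birth; MatP/*ter* arrives
stably at mid-cell a median 50 min after birth and a median 30 min after
*ori* duplication; stable nucleoid constriction follows a median 40 min
later still; and the three events occur in that order in 99.5 % of
cycles. Negative `t_ori` values (cycles born with two foci) are included
via mother backtracking.

The same pipeline is available from the shell:

```sh
choreoquant simulate --out data --seed 7 --n 2000
choreoquant run --in data --out results
```

which writes `events.csv`, `summary.csv`, per-channel kymograph TSVs,
`velocity_matp.csv` and a `report.json` echoing the configuration,
estimated channel offsets and filter counts. Identical inputs, config
and seed give byte-identical outputs.

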