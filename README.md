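# hsckinetics

Division kinetics and pool homeostasis of human hematopoietic stem cell
(HSC) subsets.

Human long-term (LT) and short-term (ST) HSCs are both deeply quiescent,
yet LT-HSCs divide far less often. `hsckinetics` implements the
computational side of the argument that the **duration of quiescence (G0)
exit is an independently regulated kinetic parameter**: it estimates
division kinetics from single-cell tracking data, fits BrdU labelling
curves and limiting-dilution assays, and simulates what independent control
of G0 exit does to HSC pool homeostasis.

## What it computes

**Kinetic triplet from single-cell tracking.** Single HSCs are stimulated
at t = 0 and wells are inspected twice a day over ~140 hr. From the
cumulative fraction of divided wells (dead wells excluded) a least-squares
log-logistic sigmoid

&nbsp;&nbsp;&nbsp;&nbsp;F(t) = plateau / (1 + 10^(slope · (logEC50 − log10 t)))

gives t_FirstDiv = EC50 of the first-division curve, t_SecondDiv = EC50 of
the curve of intervals between first and second division (the cell-cycle
transit time t_G1-S-G2-M), and

&nbsp;&nbsp;&nbsp;&nbsp;t_G0exit = t_FirstDiv − t_SecondDiv,

the latency specific to leaving quiescence. Paired t tests compare subtypes
across samples; an extra-sum-of-squares F test compares whole curves.

**BrdU incorporation.** F(t) = plateau · (1 − 2^(−t/Td)) fitted per
subtype; the half-time of the fit is the population doubling time Td, and
Td(LT)/Td(ST) quantifies how much less frequently LT-HSCs divide.

**Limiting-dilution analysis.** Single-hit Poisson model
P(engraft | dose d) = 1 − e^(−f·d); maximum-likelihood frequency f with
95% profile-likelihood confidence limits and likelihood-ratio group
comparisons (an ELDA-style estimator).

**Agent-based homeostasis model.** LT-HSC, ST-HSC and progenitor pools are
held near target sizes by a closed demand loop (deficit-driven activation
with 5% signal noise; a differentiation flux of 24 cells/day out of the
HSC pool at homeostasis). Three control schemes for a division are
compared: one lumped kinetic parameter with commitment at signal reception
(HYP1); independent G0-exit and cycle-transit phases with commitment only
after G0 exit completes (HYP2.1); and additionally the measured 5.8 hr
LT-specific G0-exit delay (HYP2.2). The model measures LT divisions per
year, the effect of scanning the delay, and recovery after eliminating 1%
of the progenitor compartment.

A synthetic-data module generates all three kinds of input at the
study's design (288 wells per subtype, 12-hr inspections, 140-hr horizon;
12-day BrdU courses; four-dose transplant tables), so the whole pipeline is
testable without any external data.

## Worked example

```bash
hsckinetics generate --kind tracks --seed 1 --out tracks.csv
hsckinetics fit-kinetics --tracks tracks.csv --out kinetics.csv
```

prints

```
subtype  t_first_div  t_second_div  t_g0_exit  negative_g0_flag  r_squared_first  r_squared_second  n_wells
     LT    49.613494     23.352439  26.261055             False         0.999491          0.996222      288
     ST    39.959671     21.121480  18.838191             False         0.998789          0.996344      288
```

LT-HSCs take ~9.7 hr longer than ST-HSCs to complete a first division in
this sample, and ~7.4 hr of that difference is in G0 exit (the generating
design uses 9 hr and 5.8 hr; single experiments scatter around those
values, and the absolute transit estimates carry a half-interval
censoring offset that cancels in between-subtype differences — see
`docs/methods.md`). Both fits have R² > 0.99.

```bash
hsckinetics abm run --seed 1 --out abm_out/
# LT interdivision interval: 277 days
```

A year of simulated homeostasis at the calibrated defaults reproduces the
~280-day LT-HSC interdivision interval reported for humans.

Other entry points: `hsckinetics fit-brdu`, `hsckinetics lda`,
`hsckinetics abm compare|delay-scan|perturb`, and
`hsckinetics reproduce kinetics|hypotheses|delay-scan|injury` for end-to-end,
manifest-logged protocol runs.

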