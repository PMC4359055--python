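# Methods

## Synthetic division-tracking data

Each well holds one cell of a given subtype (LT or ST). Its latent history
is built from truncated-Gaussian durations (floor 0.1 hr): a quiescence-exit
duration G ~ N(mean_g0_exit, sd_g0_exit) and two independent cycle-transit
draws C1, C2 ~ N(mean_cycle_transit, sd_cycle_transit). The first division
occurs at G + C1 and the second at G + C1 + C2. The Gaussian family is a
modelling choice: the experiments this emulates report only means and
significance, never a distribution family, and Gaussians keep the moments
interpretable. The second transit draw is independent of the first; no
correlation structure is claimed.

Wells die with probability `death_probability` (default 0.1) before their
first division and contribute nothing downstream. Events are
interval-censored: a division is first seen at the next scheduled
inspection (every 12 hr by default, i.e. twice a day), so observed times
are snapped **up** to the grid, and events after the 140-hr horizon are
right-censored. Defaults: 288 wells per subtype (576 cells total).

Shipped timing defaults (hours):

| parameter          | LT   | ST   | rationale                                  |
|--------------------|------|------|--------------------------------------------|
| mean_g0_exit       | 20.0 | 14.2 | gap 5.8 hr = the measured LT−ST G0-exit gap |
| mean_cycle_transit | 30.0 | 26.8 | gap 3.2 hr so the first-division gap is 9 hr |
| sd (both phases)   | 5.0 / 6.0 | 5.0 / 6.0 | chosen, not measured: per-subtype SDs of single-cell durations are not published for these cells |

Only the between-subtype gaps are measured quantities; the absolute
anchors and SDs are this package's choices and are documented as such.

## Kinetic estimation

The cumulative curve at observation time t is the fraction of non-dead
wells whose event time is ≤ t. For the first division the event time is
the observed division time; for the second division it is the **interval**
between the observed first and second divisions, so that the second-curve
EC50 estimates the cell-cycle transit time and
t_G0exit = EC50(first) − EC50(second) isolates the exit latency.

The sigmoid F(t) = plateau / (1 + 10^(slope·(log_ec50 − log10 t))) is fit
by bounded least squares (plateau ∈ (0, 1], slope ∈ [0.05, 50]), initialised
at plateau = max observed fraction, log_ec50 = log10 of the first time at
half-max, slope = 2. The t = 0 point is excluded (the model is defined on
log time). Curves that do not bracket their half-maximum, or are all zero,
raise explicit errors rather than fitting garbage.

**Censoring bias.** Snap-up censoring leaves the first-division EC50
essentially unbiased (the observed curve at a grid time equals the latent
CDF there), but the interval between two snapped times is effectively
rounded to the grid, which shifts the transit EC50 down by about half an
observation interval (~6 hr at the default design). The same offset
applies to both subtypes, so between-subtype differences — the quantities
of scientific interest here — are unaffected. Absolute t_G0exit values
carry the corresponding upward offset and should be read with that in
mind.

A negative t_G0exit is returned and flagged, never clipped: clipping would
bias the estimator in the group comparisons. Paired subtype comparisons
use the paired t test; whole-curve comparisons use the
extra-sum-of-squares F test with a pooled shared-parameter fit as the null.

## BrdU labelling

The labelled fraction follows plateau·(1 − 2^(−t/Td)); base-2 saturation
makes the half-time of the fit equal the doubling time Td by construction.
The plateau is left free (a forced plateau of 1 is not assumed). Days are
converted to hours internally. The default generator uses Td = 102 hr (LT)
vs 60 hr (ST) — a 1.7-fold ratio inside the reported 1.5–1.9 band —
plateau 0.95, 13 daily time points, 3 replicates, noise SD 0.05 (clipped
to [0, 1]). Subtype comparison is an F test against a shared-Td,
separate-plateau null.

## Limiting dilution

Single-hit Poisson: P(engraft | dose d) = 1 − e^(−f d). The MLE of f is
found on the log scale; 95% confidence limits come from the profile
likelihood at the χ²(1) cutoff (drop of 1.92 log-units). This is
deliberately an ELDA-style implementation, not a bit-identical port: the
complementary log-log GLM route is asymptotically equivalent but less
stable at the small recipient counts typical of these assays. All-negative
and all-positive tables put the MLE on the boundary; they are flagged and
only the informative limit is reported. Group ratios use a
likelihood-ratio test against a shared-frequency null.

## Agent-based homeostasis model

Three compartments: LT-HSC, ST-HSC (agents) and progenitors (a passive
buffer; progenitor self-renewal is not modelled). Quiescent cells are
exchangeable and stored as counts; only cells in the exit or cycling
pipelines carry individual remaining times. Time advances in 0.5-hr steps.

**Demand loop.** Downstream blood production consumes progenitors at a
constant 24 cells/day. HSCs differentiate into progenitors at a per-cell
rate calibrated so the flux equals 24 cells/day when pools are at target
("the HSC pool exit rate"); only quiescent cells differentiate, and the
flux is split between LT and ST in proportion to pool sizes. The
activation signal of a compartment sums the fractional deficits it can
relieve by dividing: its own pool plus everything downstream (progenitor
deficit drives both HSC subtypes, the ST deficit additionally drives LT).
The own-deficit term is essential: with purely downstream signals the
LT signal always dominates the ST signal and nothing limits LT growth, so
the subtype split is unregulated and the LT pool grows without bound.
Signals get multiplicative uniform noise of ±5% and are clamped to [0, 1];
quiescent cells activate with probability signal × activation_rate × dt.

**Hypotheses.** Under HYP1 an activated cell is committed immediately and
divides after one lumped Gaussian duration (mean = exit + transit means,
variance summed). Under HYP2.x activation starts a G0-exit phase; the cell
commits to the cycle-transit phase only when that completes, and while
still exiting it aborts back to quiescence (full reset) whenever its
compartment's signal is zero. HYP2.2 adds the measured 5.8-hr delay to the
LT exit mean. Completed divisions yield two quiescent daughters.
Eliminated or exported cells and divisions balance exactly (a tested
invariant).

**Calibration.** Noise (5%) and the homeostatic exit rate (24 cells/day)
are fixed at their reported values. The remaining free parameters were
scanned until the simulated LT-HSC interdivision interval matched the
~280 days reported for human HSCs: because divisions balance exits at
steady state, the interval is pinned by (LT+ST target)/(exit rate), giving
targets LT 3360 / ST 3360 / progenitors 10000. The interval is insensitive
to the activation scaling (0.03–0.3 /hr all give 272–280 days); the
shipped value 0.1/hr keeps pools within ~2% of target over a simulated
year. An optional `flux_gain` amplifies the differentiation flux with the
progenitor deficit; it defaults to 0 (see below).

**Measurements.** Divisions per cell per year = cumulative divisions /
mean pool size, annualised; the interdivision interval is its inverse in
days. Replicate sets use independent spawned seeds; hypothesis and delay
comparisons use Mann-Whitney rank tests over runs (α = 0.05; the delay
scan is one-sided, fewer divisions). Recovery after injury (elimination of
1% of progenitors) is the first time the pool stays within
tolerance × target of target for 24 consecutive hours.

**Model behaviour worth knowing.** (1) The LT-division sparing by the
exit delay is near-linear (~0.5% fewer LT divisions per year per 1.3 hr
of delay at the defaults), saturating beyond roughly 5 hr, so with 64
runs per grid point the
smallest statistically significant delay can land one 1.3-hr grid step
below the 2.6-hr reference value; the delay-scan report prints and flags
the measured threshold. (2) With `flux_gain > 0` progenitor refill after
injury becomes flux-limited and recovery times stop discriminating the
hypotheses; at the default (0) recovery is division-limited. (3) The
robust recovery prediction is that the LT-specific delay (HYP2.2) settles
the LT pool fastest after injury (~4 SE, reproducible across seed sets).
The strict full ordering of recovery times across all three hypotheses is
not reproduced at the 1% injury size: the HYP1-vs-HYP2.1 difference is
indistinguishable from zero in both compartments, and progenitor-pool
settle times are heavy-tailed enough that their ordering flips between
seed sets.

## Problem sizes

The shipped analyses use 20 replicate tracking/BrdU experiments, 32
one-year runs for the homeostatic interval, 64 runs per delay-scan grid
point and 16 runs per hypothesis for injury recovery — sizes chosen so a
full reproduction completes in minutes on one CPU while keeping standard
errors well inside the comparison bands.

## What the synthetic data do not capture

Gaussian, independent phase durations; death uniform before the first
division; no well-to-well culture heterogeneity, no imaging/counting
errors, no return to quiescence in vitro. The limiting-dilution generator
assumes perfect single-hit behaviour. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to every artefact of real tracking data. The
simulator has no spatial structure, niche, aging or clonal tracking, and
progenitors neither divide nor die stochastically beyond the constant
demand.
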