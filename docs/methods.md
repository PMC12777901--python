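# Methods

## Model structure

`afsim` is a discrete-time (annual-cycle) individual-patient stochastic
simulation. A replication generates the full cohort, then advances every
patient one year at a time until nobody is left alive, accumulating event
counts, costs and DALYs, with snapshots taken after simulated years 1, 5 and
10 and at extinction. The one-year step matches the resolution of the input
parameters (annual stroke probabilities, annual life-table risks, annual drug
costs); nothing in the engine assumes a finer clock.

Within a patient-year the draw order is fixed and documented: (1) other-cause
death from the life table, (2) at most one stroke — the ischaemic draw first,
then, if it misses, the haemorrhagic draw — and (3) case fatality given a
stroke. Death-first prevents a patient from both dying of other causes and
stroking in the same cycle; one-stroke-per-year is a deliberate
simplification at an annual resolution. Recurrent strokes in later years are
allowed by default (`recurrent_strokes=False` restricts output counts to
first-ever in-simulation strokes). An incident stroke sets the prior-stroke
flag; with `dynamic_score=True` (default) the CHADS₂ score is recomputed every
year from its components, so both incident strokes (+2) and crossing age 75
(+1) raise subsequent ischaemic risk. A `max_age` guard (default 110 years)
forces other-cause death beyond the life table's range, so every replication
terminates; activations are logged.

## Population synthesis

The cohort is defined by a CHADS₂ (0–6) × treatment (none/warfarin/NOAC)
allocation table plus marginal demographics. In `table_exact` mode the
generated cross-tabulation equals the table cell for cell; `sampled` mode
draws a given cohort size multinomially from the table's proportions.

* **Ages** follow a normal distribution truncated to [0, 103] by rejection,
  with the location calibrated numerically (Brent root-finding on the
  truncated-normal mean) so the truncated mean equals the 75.60-year target;
  an uncalibrated location would undershoot by ≈0.3 years because the upper
  truncation clips more mass than the lower. Only summary moments are
  honoured — the empirical age histogram of any particular dataset is not.
  The full age marginal is sampled first and then assigned to patients
  through feasibility pools: score-0 patients must be under 75 and score-6
  patients at least 75 (their flags cannot otherwise reach the score), other
  scores draw from the shuffled remainder. The cohort-level age distribution
  therefore stays exactly the calibrated truncated normal, at the price of a
  mild, epidemiologically sensible age–score correlation.
* **Sex** is Bernoulli (default male fraction 0.5768), independent of score —
  no joint distribution is assumed.
* **Comorbidity flags** are back-filled uniformly at random among the flag
  combinations consistent with the assigned score after the age point is
  fixed (prior stroke/TIA counting 2). The flags only matter for score
  dynamics; no marginal prevalence targets are imposed.
* **HAS-BLED** exists as an optional field with no generator or default — the
  bleeding pathway is a structural hook, disabled unless risk parameters are
  supplied.

## Scenarios

Scenario transforms act on the allocation table. Untreated patients at scores
at or above the eligibility threshold (default CHADS₂ ≥ 2) are shifted onto
warfarin only, NOACs only, or split between the two in proportion to that
score's existing warfarin:NOAC ratio (warfarin share rounded half-up,
remainder to NOAC; a score with no treated patients falls back to a logged
50:50 split). The per-score count of patients who remain untreated —
presumed contraindicated — is explicit input data, not a derived rule; a
convenience constructor accepts a uniform retained fraction. Row totals are
conserved exactly by construction, and `conservation_check` verifies two
tables against each other with a default tolerance of one patient per row to
absorb rounding in externally produced tables. Allocations are fixed at
cohort creation; treatment switching over time is out of scope.

## Default parameters (all configuration, never hard-coded truth)

| Parameter | Default | Why |
|---|---|---|
| Ischaemic stroke/yr, untreated, by CHADS₂ 0–6 | 1.9, 2.8, 4.0, 5.9, 8.5, 12.5, 18.2 % | classic registry-derived gradient |
| RR ischaemic vs none | warfarin 0.36, NOAC 0.31 | meta-analytic ~64% RRR for warfarin; NOACs modestly better |
| Haemorrhagic stroke/yr | 0.2% base; RR warfarin 2.5, NOAC 1.25 | intracranial bleeding commoner on anticoagulation |
| Case fatality | ischaemic 20%, haemorrhagic 45% | typical 30-day fatality estimates |
| Life table | Gompertz q(a) = A·e^(0.095a), calibrated to q(75) = 3.0% (M) / 2.0% (F), 5-year bands, q = 1 at 110+ | UK-like other-cause mortality |
| Treatment cost/yr | none £0; warfarin £290 (drug + INR monitoring); NOAC triangular(£603, £670, £737) | NOAC list price with ±10% spread |
| Acute cost/stroke | ischaemic £11,600; haemorrhagic £13,800 | UK acute-care cost estimates |
| Stroke-death cost | £150 | in-hospital death following stroke is negligible |
| Disability weights | ischaemic 0.27, haemorrhagic 0.52 | long-term stroke sequela weights |
| Reference life expectancy | computed from the sex-averaged life table | keeps YLL consistent with the mortality model |

Effective probabilities RR × p are clipped to [0, 1] with a runtime warning.
Probabilities outside [0, 1], malformed triangles and missing tables are
rejected at load time with named, field-path-bearing errors.

## Costs and DALYs

Treatment cost accrues at the start of every year a patient begins alive
(including the year of death); acute cost per stroke event; the stroke-death
cost once. The NOAC triangular price is sampled **once per patient** —
representing price heterogeneity across patients while keeping within-run
variance interpretable — rather than per year (`sample_once_per_patient=False`
resamples annually). DALYs are undiscounted and un-age-weighted,
DALY = YLL + YLD: YLL is the residual reference life expectancy at the age of
stroke death (other-cause deaths are excluded by default since the outputs
centre on stroke burden; `yll_all_cause=True` switches this), and YLD adds,
for every completed year lived after the first stroke, the maximum disability
weight among stroke types suffered so far (maximum, not sum, following
standard practice for sequelae of one cause). Per-patient accrual functions
(`accrue_costs`, `compute_dalys`) reproduce the engine's vectorised
accounting exactly, and a test enforces that equality.

## Random numbers and paired comparison

Streams derive from `SeedSequence([base_seed, replication, purpose])`. The
event stream consumes exactly four uniforms per patient per year, in patient
order, regardless of vital status or treatment, so the stream position never
depends on what happened earlier. Scenarios are compared under common random
numbers: each replication generates one cohort from the baseline table and
relabels treatments within each CHADS₂ stratum in a fixed
warfarin | none | noac layout, so a scenario shift changes only previously
untreated patients, and identical draws flow through both arms. Paired
comparison then differences per-replication outputs; an unpaired Welch
interval is available when pairing is inappropriate. A scenario compared with
itself is exactly zero.

## Replication sizing

The precision rule returns the first n ≥ 3 at which the upper bound of the
t-based confidence interval (95% default) of the running mean lies within 1%
(relative) of the previous running mean. The running mean is the denominator;
when it is zero the relative criterion is undefined and the function signals
this (an absolute-difference fallback is available). On the packaged baseline
experiment the rule terminates on year-10 cumulative strokes in roughly 10–30
replications across seeds, comfortably below the conventional 50.

## Sensitivity analysis

One-way sweeps rerun the full experiment at relative increments of a single
parameter (default −20%…+20% in 5% steps, nine points including 0) under the
same base seed, so the 0% increment reproduces the unperturbed run exactly
and differences across increments are not confounded by sampling noise.
Dotted paths address scalars or cost distributions; a triangular cost scales
all three of (min, mode, max). Sweeping a parameter with no structural effect
(e.g. the price of a treatment nobody receives) provably changes nothing.

## Problem sizes used in tests and the acceptance script

The test suite exercises the full 10,195-patient reference cohort for
generation, allocation algebra and replication sizing (55 replications), and
uses cohorts of 100–400 patients for engine-level distributional checks: the
Markov cohort-expectation oracle comparisons run 80–120 replications of a few
hundred patients, enough for 4–4.5 SE agreement bands to be meaningful. The
acceptance script generates the 10,300-patient cohort once and runs up to 80
baseline replications when probing the precision rule.

## What the synthetic data does and does not show

The generator reproduces the marginal demographics and the exact
score × treatment allocation of the reference population, but real cohorts
have joint structure this model does not claim: sex–score dependence,
empirical (non-normal) age histograms, comorbidity prevalences beyond what
the score implies, and secular trends in treatment uptake. Passing tests
demonstrate internal correctness of the algebra, the event engine and the
experiment machinery under the stated assumptions — not calibration of the
default risk parameters to any particular region's observed stroke rates,
which would require local data through the configuration interface.

## Known limitations

Annual resolution (no within-year ordering of competing strokes); no INR
control, adherence or treatment switching; aspirin monotherapy is not
modelled; bleeding events beyond haemorrhagic stroke are a disabled hook; no
discounting or cost-effectiveness layer (raw accumulations only); DALYs use a
single weight per stroke type with no severity distribution.
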