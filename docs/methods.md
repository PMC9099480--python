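# Methods

## Model structure

The model is a discrete-time Markov cohort model with five health states —
WARD, COMPLICATION, ICU, DISCHARGED, DEAD — and a one-day cycle over a
180-day base-case horizon. The whole cohort starts on the normal ward.
Occupancy is recorded at the start of each day and one full day of time
(and cost) accrues to the occupied state; no half-cycle correction is
applied, because the costing arithmetic the model reproduces is plain
`days × daily rate` and a half-cycle correction would break those
identities. The 180-row trace therefore covers days 0–179, and the
"mortality at the end of the horizon" is the DEAD occupancy of the final
row; calibration, microsimulation and reporting all use this same
convention, so it cancels everywhere two quantities are compared.

Transitions are time-homogeneous: one matrix per arm for the whole
horizon, including the 365-day extrapolation. Nothing in the available
evidence supports a time-varying structure, but this is the model's single
strongest assumption — in reality daily hospital-discharge and death
hazards are strongly duration-dependent, so the calibrated matrices should
be read as "the time-constant chain whose 180-day tallies match the
trial", not as daily hazard estimates.

### Transition mask

The published state diagram names the transitions qualitatively but does
not enumerate the arrow set, so the structural mask is an explicit,
configurable input. The default:

| from \ to     | WARD | COMPLICATION | ICU | DISCHARGED | DEAD |
|---------------|------|--------------|-----|------------|------|
| WARD          | ✓    | ✓            | ✓   | ✓          | ✓    |
| COMPLICATION  | ✓    | ✓            | ✓   | ✓          | ✓    |
| ICU           | ✓    | ✓            | ✓   | —          | ✓    |
| DISCHARGED    | ✓    | —            | —   | ✓          | ✓    |
| DEAD          | —    | —            | —   | —          | ✓    |

ICU patients are assumed to step down to the ward (or complication state)
before discharge; readmission is modeled as DISCHARGED→WARD. Every
structural claim in the code validates against the mask, so alternative
readings of the diagram need only a different mask file.

## Costing

Per-state daily unit costs (Swiss francs): ward 1650, ICU 4654,
complication 1513, nutritional support 5 in either setting; death accrues
nothing and nothing is discounted. The intervention arm accrues the
inpatient supplement price on *every* in-hospital day (ward +
complication + ICU); this is the reading that reconciles the per-day price
with the reported per-stay support cost of 679 SF (135.81 in-hospital days
× 5 SF). Outpatient supplements accrue on `fraction × discharged days`,
default fraction 0.2. Monetary outputs are kept unrounded internally and
rounded only at render time (costs to whole SF, days and utilities to two
decimals); the optional euro display uses the fixed factor 1 SF = 0.95 EUR.

Utility weights: the published per-state quality-adjusted life days imply
a single daily weight of about 0.002 for alive states (0.25 ward QALDs /
123.84 ward days), so that is the default for all four alive states,
configurable per state. Whether the source values are daily utilities on a
0–1 scale or rescaled QALYs is not documented; utilities are therefore
reported but never enter any ICER, which are all per life day or per
life-year.

### Incremental table conventions

Components follow the published layout: ward, ICU, complication and
post-discharge rows pair each state's cost delta with its life-day delta
(outpatient nutrition folds into the post-discharge row); inpatient
nutrition is a cost-only row. Component ICERs are computed on the raw
deltas — which makes the ward and complication rows' ratios equal their
daily rates exactly — but the complication row's *dominance quadrant* is
judged on avoided complication days, since days spent with a complication
are a harm: a strategy that is cheaper with fewer complication days is
dominant, not "less effective".

## Calibration

The arm-specific matrices were never published, so they are recovered by
fitting. Free parameters are the masked entries of the four alive rows
(17 under the default mask), reparameterized row-wise through a softmax so
every candidate is automatically row-stochastic, non-negative and
mask-respecting. The objective is

    Σ_k  w_k ((achieved_k − target_k) / max(target_k, floor_k))²

over five targets per arm: four per-state life-day tallies (weight 1,
floor 1 day) and the 180-day dead fraction (weight 5 — mortality is the
trial's primary significant endpoint — floor 0.01). Relative errors keep
the objective scale-free across day counts and proportions; the floors
keep zero-valued targets well-scaled. L-BFGS-B with numerical gradients
runs from 10 starts (one structured start with heavy self-persistence and
a mortality-sized daily death hazard, nine seeded random draws); the best
solution wins, and identical seeds reproduce identical fits. With 17 free
parameters and 5 targets the problem is under-determined: many matrices
achieve the same tallies, so everything downstream asserts *target
recovery* (observed fits reach relative errors around 1e-7; feasibility is
declared only below 10% worst-case error), never matrix identity. Results
that depend on behavior beyond day 180 — extrapolation and the threshold
analysis — inherit this non-identifiability and are reported as model
outputs, not as reproductions of published figures.

## Microsimulation and synthetic trials

`simulate_individuals` runs the identical chain at patient level
(inverse-CDF sampling of each row, vectorized across patients) as a
Monte-Carlo cross-check: sample-mean life days and mortality converge to
the cohort tallies, which the test suite verifies at n = 100,000 within
three standard errors. The synthetic-trial generator emits a long-format
patient-day table (arm sizes default to the trial's 321/324) with per-arm
RNG substreams spawned from the master seed, so one arm's trajectories
never depend on the other arm's matrix. `estimate_matrix` inverts the
generator by maximum likelihood (transition counts row-normalized under
the mask), closing the generate → estimate → re-run round trip that
validates the whole estimation path without external data.

What the generator does *not* emulate: patient covariates (age, ejection
fraction, nutritional-risk score), duration-dependent hazards, informative
censoring, or patient-level cost variation. Passing tests therefore show
the pipeline is internally consistent under the model's own assumptions,
not that those assumptions hold in real CHF admissions data.

## Sensitivity analyses

* **Deterministic:** a grid over supplement price {5, 100, 1000} SF/day
  (applied to both settings) and outpatient continuation {0.2, 0.5, 1.0},
  holding life days fixed.
* **Probabilistic:** the five unit costs draw independently from Gamma
  distributions moment-matched to their published means and standard
  deviations (shape = (mean/sd)², scale = sd²/mean); life days and
  transition probabilities are deliberately not varied, since the input
  uncertainty specification covers costs only (a hook exists for adding
  Beta/Dirichlet draws). Intervals are 2.5/97.5 percentiles because the
  ward and complication cost distributions (coefficient of variation near
  1) are strongly skewed. Accrual is linear in unit costs and Gamma
  sampling is mean-preserving, so the PSA mean converges to the base case
  — a standing test.
* **Extrapolation:** both arms run to 365 days with unchanged matrices;
  the ICER denominator becomes incremental life days / 365.
* **Threshold:** the largest total inpatient nutrition cost whose
  cost-effectiveness ratio stays at a willingness-to-pay of 100,000 SF per
  life-year, solved by bisection to within 1 SF/life-year. Outpatient
  supplements stay at their configured price and scale with the
  continuation fraction, so the admissible inpatient budget strictly
  decreases as continuation grows — reproducing the published *ordering*
  of the three maxima. The default "nutrition-only" mode judges nutrition
  costs alone against the threshold; "full-incremental" subtracts all
  other incremental costs first. The published maxima themselves depend on
  the unpublished 365-day trajectories and are not reproducible from the
  available targets, so only the ordering and monotonicity are asserted.

## Numerical choices and problem sizes

Row-stochasticity is validated to 1e-12 and trace mass conservation to
1e-10. Monte-Carlo checks use 100,000 patients (three-standard-error
acceptance bands); the round-trip estimation check uses 50,000 patients ×
180 days; the default PSA uses 10,000 draws. Calibration runs 10 starts ×
(≤500 L-BFGS-B iterations) per arm, about 15 seconds per arm on one core.
Degenerate inputs are handled explicitly: a zero effect delta flags the
ICER undefined rather than dividing; infeasible calibration targets raise
a typed error carrying the best achieved fit; states never visited in a
trajectory table get flagged self-loop rows rather than silent guesses.

## Known limitations

Time-homogeneity (above) is the dominant one. Costs are Swiss payer
tariffs and transfer poorly to other systems; no indirect or societal
costs; no QALY-based ICERs (utility weights are back-solved, not
instrument-based); PSA ignores correlation between unit costs; calibration
matches five aggregate targets and cannot distinguish matrices with
different within-horizon dynamics that happen to share those tallies.
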