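# Methods

## Model structure

A cohort-level state-transition (Markov) model with three states —
progression-free (PFS), progressed disease (PD), death — and a 1-month
cycle. The whole cohort starts in PFS. Death is absorbing; PD→PFS
recovery is structurally excluded. The transition matrix is constant
over time (no tunnel states, no time-varying hazards), which is the
standard simplification when probabilities are derived from exponential
fits to trial survival curves.

The lifetime horizon is implemented as 600 monthly cycles. Under every
packaged matrix this leaves live occupancy far below 1e-4 (the engine
warns if a supplied scenario has not converged), so the horizon
truncation is numerically irrelevant; 600 cycles keeps every
deterministic run far under a second on one core.

## Transition probabilities

Base-case matrices are fixed published inputs. The survival module
provides the supporting conversions for checking or re-deriving them
under an exponential (constant-hazard) assumption:

* median m months → monthly probability `P = 1 − 0.5^(1/m)`;
* hazard/probability conversions `P = 1 − e^(−R)`, `R = −ln(1 − P)`;
* a least-squares exponential fit of `−ln S(t) = R·t` through the origin
  to Kaplan–Meier points (the stand-in for digitized-curve parametric
  fitting; no Weibull/log-logistic alternatives are offered);
* `derive_transitions`: PFS-exit from the PFS median, PFS→death from the
  OS median (pre-progression deaths are assumed to track the marginal OS
  hazard; the difference, floored at zero, goes to PD). Because no
  post-progression survival summary is published, PD→death is calibrated
  by bisection (tolerance 1e-6 on the probability) so that the cohort's
  simulated median OS — the cycle where survival crosses 0.5, linearly
  interpolated between cycles — hits the published OS median.

`validate_transitions` reports the absolute discrepancy between a
matrix's PFS-exit / PFS→death entries and the closed-form conversions
of the medians. Defaults flag discrepancies above 0.02 (exit) and 0.001
(death). Note the source tables print the chemotherapy PFS median as
both 3.2 and 3.8 months; the fixtures carry 3.8 (the tabulated input
set), and with that value the pMMR chemotherapy PFS-exit discrepancy is
0.024 — consistent instead with the 3.2-month reading. The validator
surfaces this rather than hiding it.

## Costs

All costs are 2021 U.S. dollars taken as given (no price-database lookup
or CPI adjustment is performed here). Per state and arm, the monthly
total is

    drug acquisition + Σ(AE rate × AE unit cost) + disease management
                     [+ acceptance rate × (other arm PFS total − disease management)]

the last term only in PD: patients failing an arm cross over to the
other regimen with arm-specific acceptance (28.0% LP, 48.1%
chemotherapy). The AE attribution follows the published cost table: the
LP arm prices hypertension and diarrhea; the chemotherapy arm anemia,
neutropenia, decreased neutrophil count and decreased WBC; AE rows with
no unit cost (decreased appetite, weight decrease) are excluded. AE
management is a recurring monthly PFS cost, which is what the published
cumulative state costs imply.

Each arm's published monthly acquisition total is treated as
authoritative; individual drug and administration-time components
contribute *deviations* from their base values. At base this reproduces
the published totals to the cent (the LP components sum one cent away
from the printed total; the chemotherapy total includes a $395.95
component that is not broken out at all), while component-level
uncertainty still propagates in the sensitivity analyses. Biomarker
testing ($666.40) is charged once at entry in both arms — it cancels
from the increment, and a test asserts the ICER is invariant to it.
Palliative care ($11,266.07) is charged on each cycle's death inflow,
discounted at the arriving cycle, and attributed to the bucket of the
state the patient died from; that attribution best reproduces the
published per-state cost decompositions.

Internal arithmetic is full double precision; currency is rounded
half-up to cents only at presentation.

## Accumulation, discounting, half-cycle correction

Occupancy is counted at cycle starts over T cycles. The half-cycle
correction is trapezoidal: weight 0.5 on cycle 0, 1 on cycles 1..T−1,
0.5 on cycle T, applied identically to costs and QALYs. One-time entry
and transition costs are exempt (they attach to events, not occupancy).
The original analysis was built in a commercial tool whose exact
correction scheme is not documented; the scheme here is configurable
(`half_cycle=False` gives plain cycle-start counting) and a test pins
the corrected total between the cycle-start- and cycle-end-weighted
sums, which bounds the ambiguity at half a cycle's accrual.

Discounting is 3%/year with monthly compounding, factor
`1.03^(−t/12)` at cycle t. QALYs are occupancy × utility × 1/12 year
per cycle, with utilities 0.817 (PFS), 0.779 (PD), 0 (death).

Against the published results these conventions land within 0.3%:
LP discounted cost $432,346 vs $432,785.93, ICER $377,505 vs
$378,251.44/QALY, pMMR ICER $412,440 vs $413,256.68/QALY. The residual
(well within the 5% reproduction tolerance used by the acceptance
tests) is attributable to the unknowable correction/discount stepping
of the original tool; the published per-state cost and QALY
decompositions themselves imply slightly inconsistent mean state
durations, so exact agreement is not achievable from the printed
inputs.

## Sensitivity analyses

**One-way (tornado).** Each parameter is set to its published low and
high (±25% of base; the PFS-utility upper bound is capped at 1.0),
everything else at base, and the full deterministic model is re-run;
bars are sorted by ICER swing. Per-arm drug acquisition is varied as a
single combined parameter — the published tornado treats "cost of
lenvatinib and pembrolizumab" as one factor — while the PSA samples the
component drugs individually. The dominant factors are the PFS utility,
the combined LP acquisition cost and the PD utility, and no endpoint of
any range brings the ICER below $100,000/QALY.

**Probabilistic (PSA).** 10,000 second-order parameter-set draws (not a
patient-level microsimulation: that is what matches the acceptability-
curve construction and the reported arm-level mean ± SD). Every cost
row with a published range is sampled from a Gamma distribution and the
two live-state utilities from Beta distributions, fitted by the method
of moments with mean = base and SD = (high − low)/(2·1.96), i.e. the
range read as a 95% interval. That reading is conventional but not
stated in the source; `range_z` makes it configurable, and reading the
range as mean ± 1 SD instead reproduces the published outcome
dispersion (LP QALY SD ≈ 0.25) while leaving the means — the quantities
the acceptance checks compare — essentially unchanged. Parameters are
sampled independently (no correlation information exists); transition
probabilities are Fixed inputs and excluded, so each arm's cohort trace
is computed once and re-priced per draw, which is algebraically
identical to re-running the cohort and keeps the full PSA under a few
seconds. Beta draws cannot leave [0,1]; any clipped value would be
counted and logged. One seed (default 20220510) governs the whole run;
identical seeds give bit-identical results. The acceptability curve
reports, per WTP value, the fraction of draws with positive incremental
net monetary benefit `WTP·ΔQALY − ΔCost`.

## Synthetic data

`simulate_ipd` emulates the trial's survival experience, not its
patients: progression times are exponential at the published PFS
median; overall survival adds an exponential post-progression time
whose rate is solved (Brent's method on the two-phase survival
function) so the *marginal* OS median matches the published one;
censoring is an independent exponential (default rate 0 — the engine
consumes summaries, censoring exists to stress the Kaplan–Meier
stand-in). Kaplan–Meier curves are estimated with lifelines and emitted
as (time, survival) points. None of this reproduces real trial features
— no covariates, no accrual pattern, no informative censoring, no
non-proportional hazards such as delayed immunotherapy effect — so
passing the recovery tests shows the fitting pathway is correct under
its own exponential assumptions, not that the exponential family fits
the actual trial curves.

`random_scenario` generates fully valid random two-arm configurations
(row-stochastic matrices with absorbing death, non-negative costs,
utilities in [0,1], PD no better than PFS) for property-based tests of
conservation, absorption and end-to-end runnability.

## Numerical conventions and edge cases

* Transition-matrix rows must sum to 1 within 1e-9 at configuration
  load; built matrices are exact by construction.
* `derive_transitions` floors PFS→PD at zero (with a warning) if the OS
  median implies more death than total PFS exit; calibration raises if
  the target median cannot be bracketed within the horizon.
* Kaplan–Meier points at S=0 (infinite log) and S=1 (uninformative) are
  dropped by the exponential fitter; a curve with no events is an
  error, a plateau after the last event is fine.
* `compare` returns a dominance flag instead of an ICER when the signs
  make the ratio meaningless; ΔQALY = 0 yields no ICER but still a net
  monetary benefit.
* Problem sizes used by the shipped tests and the acceptance script:
  600-cycle cohorts, 10,000 PSA draws, 100 seeds × 500 patients for the
  rate-recovery study — together a few seconds on one core.

## Known limitations

Fixed-in-time transition probabilities understate tail uncertainty
relative to flexible parametric extrapolation; utilities come from an
earlier published model rather than the trial's own quality-of-life
instrument, and AE disutilities are ignored (as in the source
analysis); the crossover subsequent-therapy assumption is a coarse
stand-in for unrecorded third-line therapy; and the PSA inherits the
independence and range-interpretation conventions above.
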