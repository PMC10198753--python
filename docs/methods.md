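# Methods

## The decision problem

The package evaluates whether a hybrid cardiac telerehabilitation program
(a centre-based phase followed by a remotely coached tele-based phase) is
cost-effective relative to standard centre-based cardiac rehabilitation
for Australian patients with coronary artery disease, from a healthcare
payer perspective in 2022 Australian dollars.

## Model structure

A Markov cohort model with four health states:

* **stable** — stable cardiac disease after the initial event (entry state);
* **cardiac_hosp** — hospitalised for a cardiac cause;
* **noncardiac_hosp** — hospitalised for a non-cardiac cause;
* **dead** — absorbing.

Cycles are monthly; the default horizon is 60 cycles (5 years), chosen
because trial evidence for the intervention's effect does not extend
further.  From stable, a patient may be hospitalised for a cardiac cause
(monthly probability P1, arm-specific), hospitalised for a non-cardiac
cause (P2), die (P5), or remain stable.  A hospital stay lasts exactly one
cycle and resolves to stable or to dead (P3 from cardiac, P4 from
non-cardiac hospitalisation); there are no direct hospital-to-hospital
transitions.  The transition matrix for the stable row is therefore
`[1 - P1(t) - P2 - P5, P1(t), P2, P5]`.

P1 declines over time: the annual cardiac-hospitalisation probability of
*both* arms is multiplied by `(1 - d)^y` in model year `y`, with `d = 0.10`
per year by default, and converted back to a monthly probability.  The
text behind this assumption is ambiguous about whether the multiplier acts
on the annual or the monthly probability; both are implemented
(`ModelSettings.decay_on_annual_scale`, default annual).  The difference
is below 0.1% of any reported quantity.  P2 is constant over time.

## Parameters

All Table-style inputs are `UncertainValue`s (mean, SEM, distribution
family) stored on frozen dataclasses and shipped as a flat YAML file
(`telerehab_cea/data/telerehab3.yaml`).  Monthly probabilities are the
authoritative stored values; annual source probabilities are recorded as
comments and reproduced by the constant-hazard conversion
`p_m = 1 - (1 - p_a)^(1/12)`, which matches every published annual/monthly
pair at 4 decimal places (division by 12 does not, for the larger
probabilities).

Key defaults:

| parameter | value | units |
|---|---|---|
| P1 intervention / control | 0.0089 / 0.0214 | per month |
| P2 (non-cardiac hosp) | 0.038 | per month |
| P3 / P4 / P5 (death) | 0.0032 / 0.0006 / 0.0018 | per month |
| utilities stable / hosp | 0.86 / 0.75 (both hosp states) | QALY weight |
| stable management | 122 | $AU per month |
| cardiac / non-cardiac admission | 6,961 / 1,956 | $AU per admission |
| control program | 235.94 x 1.45 x 7 = 2,394.79 | $AU per patient |
| intervention program | 6,255.46 | $AU per patient |
| discount rate | 5% | per year |
| WTP threshold | 28,000 | $AU per QALY |
| completion rate | 80% (90% scenario) | fraction |
| cardiac-hosp decay | 10% | per year, both arms |

The control program cost is the product of the session cost
(activity-based-funding price weight 0.0407 x national efficient price
$5,797 = $235.94), the sessions per week (1.45, SD 0.5) and the program
duration in weeks (7, SD 1.11).  The source text also quotes a narrative
figure of $2,359 (ten sessions); the package uses the tabulated C x N x D
form, which is the one wired into the uncertainty analysis.  A second
known source discrepancy: the narrative derivation of the annual
probability of death after non-cardiac hospitalisation (78,688/10,372,469
= 0.0076) does not equal the printed 0.0071; the stored monthly value
0.0006 is consistent with 0.0071 and is used as printed.

## Reward accrual and discounting

Rewards for cycle `t` accrue on the state occupied at the start of the
cycle (after `t` transitions), for `t = 0 .. 59`; with zero event
probabilities, zero discounting and utility 1 this yields exactly 5
QALYs/patient over the horizon.  The program cost is charged once per
patient at cycle 0.  Stable-management cost accrues per person-month;
admission costs are event costs charged on entry to a hospital state
(hospital occupancy equals inflow because stays last one cycle).  QALYs
accrue as occupancy x utility / 12 per monthly cycle.  Cycle-`t` accruals
are discounted by `(1 + r)^(-t/12)`.  No half-cycle correction is applied
by default (the common decision-software default); a switch exists
(`ModelSettings.half_cycle_correction`) that averages start- and
end-of-cycle occupancy for state rewards while leaving event costs
uncorrected.

## Completion-rate semantics

The published analysis states only that 80% of intervention patients were
assumed to complete the program.  Here the intervention cohort is an exact
two-part mixture: a fraction `c` (completers) follows the intervention
cardiac-hospitalisation probability, `1 - c` (non-completers) follows the
control probability, and *all* intervention patients incur the full
intervention program cost at cycle 0.  Because the cohort process is
linear in occupancy, the mixture equals the weighted sum of the two
sub-cohorts exactly, which is both tested and exploited by the PSA.
The control strategy has completion 1.0 by construction.

## Incremental analysis

For totals `C` and `Q` per strategy: `ICER = dC/dQ`, reported with
explicit `dominant` / `dominated` / `undefined` flags instead of signed
ratios; `iNMB = WTP x dQ - dC`, positive exactly when the intervention is
cost-effective at the threshold.  All arithmetic is full precision;
rounding to the published presentation style (costs in $M at 1 dp, QALYs
at 1 dp) happens only in `CEAResult.summary()`.  The cumulative cost
decomposition reports three series per strategy — cardiac admissions,
non-cardiac admissions, and program + stable management — which partition
total cost.

## Probabilistic sensitivity analysis

Transition probabilities and utilities receive beta distributions, costs
gamma distributions, parameterised by the method of moments
(`alpha = m*nu, beta = (1-m)*nu` with `nu = m(1-m)/s^2 - 1`;
`k = (m/s)^2, theta = s^2/m`).  Parameters with SEM 0 or family `fixed`
are never sampled.  Draws are independent across parameters and across
the two arms' P1 values (no truncation of effect-direction inversions);
the completion rate and decay are scenario settings, not sampled.  The
control program cost is resampled component-wise (C fixed, N and D gamma);
a single aggregate gamma on the product — with the product SD implied by
independent N and D — is available behind a flag because the source is
ambiguous about which was done.  Each draw re-runs the deterministic
cohort engine (second-order uncertainty only).  A root `SeedSequence` is
spawned into one substream per draw, so results are reproducible and
independent of evaluation order.  Default 10,000 draws run in a few
seconds on one CPU.

## Validation against an independent oracle

`fixtures.microsimulate` is an individual-level Monte Carlo implementation
that shares only the per-cycle transition matrices and reward definitions
with the cohort engine: each patient-cycle is a categorical draw, and
per-patient discounted costs/QALYs are averaged.  A bug in either the
matrix-propagation path or the sampling path would break the agreement
test, which requires cohort expectations to lie within 3 Monte Carlo
standard errors at 200,000 patients (per-patient QALY SE ~ 0.0015, i.e. a
~0.1% relative check) for the packaged parameter set and ten randomised
valid sets, per strategy.  The default oracle size keeps that test under
a minute on one CPU.  The synthetic `random_parameter_set` generator
draws structurally valid inputs (positive stable self-loop, feasible beta
moments) and is used for conservation/monotonicity sweeps; it emulates
parameter-file variety, not any real patient population, so those tests
establish structural correctness, not clinical realism.

## Reproduction status and known inconsistencies of the published results

The published deterministic tables and the published PSA summaries are
not jointly reproducible under any single set of modelling conventions,
and the package makes no attempt to force them to be:

* Under the stated study conditions (80% completion, 10% decay on both
  arms, 5% discounting) the model yields incremental cost ~$1.29M,
  incremental QALYs ~4.5 and ICER ~$284k per 1,000 patients — not the
  published $0.65M / 5.7 / $114,536.  The same model at **100%**
  completion yields $0.64M / 5.66 / ~$113k, matching the published
  base-case table to ~1–2%, which suggests the original base-case rollup
  did not apply its completion assumption.
* The published PSA summaries (18% cost-effective, 15% cost-saving, 100%
  effective at 80% completion; 30% at 90%; iNMB extremes ~ ±$5M) *are*
  reproduced by this implementation under the stated conditions — a mean
  incremental cost of ~$1.3M is in fact required for a 15% cost-saving
  probability given the published spread, corroborating that the original
  PSA honoured the completion mixture while the deterministic table did
  not.
* The published five-year cumulative cardiac-admission saving (~$3.4M)
  implies an undecayed between-arm gap; with 10% decay on both arms the
  model gives ~$2.7M (the first-year figure, ~$0.7M, reproduces).
* The published 90%-completion scenario (ICER $38,638, dQALY 6.4) is not
  attainable at any completion rate ≤ 1 under these dynamics and is
  internally inconsistent with its own printed increments
  (0.2M/6.4 = 31,250 ≠ 38,638).

The acceptance tests encode the published values at their stated
tolerances, so the base-case, scenario and five-year-decomposition checks
fail by design honesty rather than being relaxed; the parameter
derivations, first-year decomposition, PSA probabilities and all
structural property tests pass.  Defaults deliberately remain at the
stated study conditions rather than at whichever variant best matches any
single published table.

## Limitations

Homogeneous cohort (no age/sex structure, no separate heart-failure
stratum), no background-mortality table, no tunnel states, no correlation
structure in the PSA, no half-cycle correction by default, and no
currency/inflation machinery.  The model inherits the source's 5-year
evidence horizon; conclusions beyond it are extrapolation.
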