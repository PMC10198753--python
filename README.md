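# telerehab-cea

A decision-analytic cost-effectiveness model of **hybrid cardiac
telerehabilitation** (a centre-based phase followed by a remotely coached
tele-based phase) versus standard **centre-based cardiac rehabilitation**
in Australia, for health economists and health-services researchers who
want a tested, scriptable re-implementation of the analysis rather than a
spreadsheet or decision-tree-software model.

## The model

A Markov cohort model with four health states — stable cardiac disease
(entry), cardiac-related hospitalisation, non-cardiac-related
hospitalisation, and death (absorbing) — advanced in monthly cycles over a
5-year horizon.  Hospital stays last one cycle and resolve to stable or
dead.  Monthly transition probabilities (P1 cardiac hospitalisation,
arm-specific; P2 non-cardiac hospitalisation; P3–P5 deaths) are converted
from annual values at constant hazard, `p_m = 1 − (1 − p_a)^{1/12}`, and
the cardiac-hospitalisation risk of both arms decays 10% per model year.
Each cycle accrues costs (2022 $AU: program, stable management,
admissions) and QALYs (occupancy × utility / 12), discounted at 5%/year
via `(1 + r)^{−t/12}`.  Strategies are compared through

    ICER = ΔC / ΔQ          iNMB = λ·ΔQ − ΔC,   λ = $28,000/QALY,

and parameter uncertainty is propagated by a probabilistic sensitivity
analysis: beta distributions for probabilities and utilities, gamma for
costs, parameterised by the method of moments from each input's mean and
SEM, with the cohort model re-run per draw.  The intervention cohort is a
completion mixture: completers (80% base case, 90% scenario) receive the
intervention's hospitalisation risk, non-completers the control risk, and
all intervention patients pay the program cost.  Full details, including
reward-timing conventions and known inconsistencies of the published
source results, are in [docs/methods.md](docs/methods.md).

## Worked example

The packaged base case (`telerehab_cea/data/telerehab3.yaml`: 1,000
patients, 60 monthly cycles, 80% completion, 5% discounting):

```python
import telerehab_cea as tc

params, settings = tc.packaged_parameters()
result = tc.run_base_case(params, settings)
print(result.summary())
```

or equivalently `telerehab-cea run`, which prints

```json
{
  "control": "centre_based",
  "intervention": "telerehab",
  "completion_rate": 0.8,
  "cohort_size": 1000,
  "cost_control_millions": 17.5,
  "cost_intervention_millions": 18.8,
  "incremental_cost_millions": 1.29,
  "qaly_control": 3613.0,
  "qaly_intervention": 3617.5,
  "incremental_qalys": 4.5,
  "icer_per_qaly": 283968,
  "icer_status": "well_defined",
  "inmb": -1158583,
  "wtp_per_qaly": 28000
}
```

Reading: over five years the telerehabilitation strategy costs $1.29M
more and gains 4.5 QALYs per 1,000 patients, an ICER of ~$284,000 per
QALY — far above the $28,000 threshold, hence the negative incremental
net monetary benefit.  (At 100% completion the same model gives
$0.64M / 5.66 QALYs / ~$113,000 per QALY; see the methods note for how
the published tables relate to these two runs.)

The PSA (`telerehab-cea psa --draws 2000 --seed 42`) prints

```json
{
  "n_draws": 2000,
  "seed": 42,
  "wtp": 28000,
  "completion_rate": 0.8,
  "p_cost_effective": 0.2065,
  "p_cost_saving": 0.184,
  "p_effective": 1.0,
  "delta_cost_min": -5136611.163055196,
  "delta_cost_max": 5444679.697777057,
  "delta_qaly_min": 1.7915014694731326,
  "delta_qaly_max": 8.777304938135785,
  "inmb_min": -5349165.803259249,
  "inmb_max": 5343184.149012748
}
```

i.e. the intervention is cost-effective at $28,000/QALY in ~21% of
draws, cost-saving in ~18%, and gains QALYs in every draw.  Useful
extras: `--table draws.csv` (per-draw table), `--ceac-csv ceac.csv`
(acceptability curve), `--plots dir/` (scatter panels), and on the `run`
command `--completion 0.9` (scenario), `--decomposition-csv`
(cumulative cost by category) and `--trace-csv` (tidy per-cycle traces).

The library surface mirrors the analysis: `parameters` (inputs,
probability conversions, moment fits, YAML I/O), `cohort_engine`
(transition matrices, cohort traces, completion mixing), `cea_analysis`
(ICER/iNMB, scenarios, cost decomposition), `psa` (sampling, Monte Carlo,
CEAC) and `fixtures` (packaged inputs, random valid parameter sets, and
an independent patient-level microsimulation oracle used to validate the
cohort engine).

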