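# Base-case parameter set: hybrid cardiac telerehabilitation vs centre-based
# cardiac rehabilitation in Australia.  All probabilities are monthly, all
# costs 2022 $AU.  Annual-scale source values behind the monthly entries:
#   cardiac hospitalisation   intervention 0.1014/yr, control 0.2285/yr
#   death in cardiac hosp     0.038/yr  (6,051 / 160,787)
#   death in non-cardiac hosp 0.0071/yr (78,688 / 10,372,469 as published)
#   death while stable        0.0214/yr (12,193 / 571,000)
horizon_cycles: 60
cycle_length_months: 1
annual_discount_rate: 0.05
wtp_threshold_aud_per_qaly: 28000
cohort_size: 1000
completion_rate: 0.8
random_seed: null

p_cardiac_hosp_intervention_monthly: {mean: 0.0089, sem: 0.0009, family: beta}
p_cardiac_hosp_control_monthly: {mean: 0.0214, sem: 0.0022, family: beta}
p_noncardiac_hosp_monthly: {mean: 0.038, sem: 0.0039, family: beta}
p_death_cardiac_hosp_monthly: {mean: 0.0032, sem: 0.0003, family: beta}
p_death_noncardiac_hosp_monthly: {mean: 0.0006, sem: 0.0001, family: beta}
p_death_stable_monthly: {mean: 0.0018, sem: 0.0002, family: beta}
annual_cardiac_hosp_decay: 0.10

u_stable_per_year: {mean: 0.86, sem: 0.011, family: beta}
u_cardiac_hosp_per_year: {mean: 0.75, sem: 0.009, family: beta}
u_noncardiac_hosp_per_year: {mean: 0.75, sem: 0.009, family: beta}

c_stable_monthly_aud: {mean: 122, sem: 19, family: gamma}
c_cardiac_per_admission_aud: {mean: 6961, sem: 945, family: gamma}
c_noncardiac_per_admission_aud: {mean: 1956, sem: 299, family: gamma}
# control program cost = session_cost x sessions_per_week x program_weeks
session_cost_aud: 235.94          # price_weight x NEP
price_weight: 0.0407
nep_aud: 5797
sessions_per_week: {mean: 1.45, sem: 0.5, family: gamma}
program_weeks: {mean: 7, sem: 1.11, family: gamma}
c_program_intervention_per_patient_aud: {mean: 6255.46, sem: 957.47, family: gamma}
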