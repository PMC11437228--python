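# Synthetic cohort specification encoding the matched-cohort margins of the
# motivating study: arm sizes of 11,645 evaluations each, matched covariate
# prevalences, matched service-utilization rates and 30-day outcome rates.
# Covariates are marginal (independent); confounding_strength adds a mild
# covariate-period association so that propensity matching has work to do.
name: table1_matched
n_pre: 11645
n_post: 11645
seed: 20210701
age_quantiles: {0.0: 18, 0.25: 53, 0.5: 64, 0.75: 72, 1.0: 95}
sex_female: {pre: 0.561, post: 0.564}
race:
  Asian: 0.012
  African American: 0.079
  White: 0.793
  American Indian: 0.004
  Others: 0.112
hispanic: {pre: 0.118, post: 0.119}
comorbidities:
  atrial_fibrillation: {pre: 0.080, post: 0.081}
  cad: {pre: 0.103, post: 0.104}
  chf: {pre: 0.033, post: 0.033}
  cva_tia: {pre: 0.039, post: 0.040}
  ckd: {pre: 0.101, post: 0.102}
  diabetes: {pre: 0.200, post: 0.202}
mets_lt4: {pre: 0.145, post: 0.148}
asa_34: {pre: 0.346, post: 0.353}
# per-component prevalence giving P(RCRI score >= 2) ~ 5.5% under
# independence, matching the matched-cohort "2 or more" margin
rcri_component_p: 0.066
# lognormal MICA percent: median 0.27%, sigma 0.8 -> P(>1%) ~ 5%
mica_median_pct: 0.27
mica_sigma: 0.8
surgical_risk: {low: 0.232, moderate: 0.559, high: 0.209}
flags:
  active_cardiac_condition: 0.005
  cardiac_disease_unclear_status: 0.15
  ischemia_concern: 0.08
  ecg_flag: 0.10
  testing_may_change_management: 0.5
confounding_strength: 0.05
service_rates:
  consult: {pre: 0.232, post: 0.179}
  echo: {pre: 0.069, post: 0.051}
  stress: {pre: 0.017, post: 0.016}
  cath: {pre: 0.0045, post: 0.0038}
outcome_rates:
  mi: {pre: 0.0012, post: 0.0012}
  revasc: {pre: 0.00017, post: 0.00043}
  chf_acute: {pre: 0.0019, post: 0.0021}
  death: {pre: 0.0014, post: 0.0014}
  icu: {pre: 0.0145, post: 0.0157}
  ed_visit: {pre: 0.058, post: 0.054}
  readmission: {pre: 0.064, post: 0.065}
out_of_window_service_rate: 0.01
study:
  study_start: 2021-07-01
  cutover: 2022-07-01
  study_end: 2023-06-30
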