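# East-Asian biobank-style cohort: modest lifestyle confounding of the
# inverse 25(OH)D association, null causal effects on every endpoint.
n_subjects: 20000
seed: 0
exposure_mean: 63.7      # nmol/L
noise_sd: 24.0           # nmol/L residual variation
season_amplitude: 10.0   # nmol/L summer-winter sinusoid
confounder_exposure: -4.0   # nmol/L per SD of latent lifestyle U
ld_r2: 0.0
admin_censor_years: 12.0
random_censor_rate: 0.005
snps:
  - snp_id: rs12785878
    raising_allele: T
    allele_freq: 0.45
    beta_exposure: 1.49
    role: synthesis
  - snp_id: rs10741657
    raising_allele: A
    allele_freq: 0.40
    beta_exposure: 0.34
    role: synthesis
  - snp_id: rs2282679
    raising_allele: T
    allele_freq: 0.28
    beta_exposure: 5.10
    role: transport
  - snp_id: rs6013897
    raising_allele: T
    allele_freq: 0.21
    beta_exposure: 0.80
    role: metabolism
endpoints:
  all_cause_mortality:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.25
    baseline_shape: 1.0
    baseline_scale: 110.0
  major_vascular_event:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.20
    baseline_shape: 1.0
    baseline_scale: 250.0
  intracerebral_haemorrhage:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.15
    baseline_shape: 1.0
    baseline_scale: 600.0
  ischaemic_stroke:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.20
    baseline_shape: 1.0
    baseline_scale: 450.0
lipids:
  tc:   {mean: 4.65, sd: 0.85, causal_per_25: 0.0, confounder_per_sd: 0.12}
  ldl:  {mean: 2.32, sd: 0.70, causal_per_25: 0.0, confounder_per_sd: 0.10}
  hdl:  {mean: 1.22, sd: 0.30, causal_per_25: 0.0, confounder_per_sd: -0.04}
  tg:   {mean: 2.00, sd: 1.00, causal_per_25: 0.0, confounder_per_sd: 0.25}
  apoa: {mean: 129.5, sd: 20.0, causal_per_25: 0.0, confounder_per_sd: -2.0}
  apob: {mean: 84.0, sd: 20.0, causal_per_25: 0.0, confounder_per_sd: 3.0}
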