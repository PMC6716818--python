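# European population-study-style cohort: strong inverse lifestyle
# confounding (observational hazard ratios well below 1 despite null
# causal effects) and a DHCR7 tag SNP generated in LD (r^2 = 0.87) with
# the causal synthesis variant.
n_subjects: 20000
seed: 0
exposure_mean: 55.3
noise_sd: 24.0
season_amplitude: 12.0
confounder_exposure: -10.0
ld_r2: 0.87
proxy_pair: [rs12785878, rs7944926]
admin_censor_years: 14.0
random_censor_rate: 0.004
snps:
  - snp_id: rs12785878
    raising_allele: T
    allele_freq: 0.72
    beta_exposure: 2.40
    role: synthesis
  - snp_id: rs7944926          # tag SNP: association flows through LD only
    raising_allele: A
    allele_freq: 0.72
    beta_exposure: 0.0
    role: synthesis
  - snp_id: rs10741657
    raising_allele: A
    allele_freq: 0.40
    beta_exposure: 1.90
    role: synthesis
  - snp_id: rs12794714
    raising_allele: A
    allele_freq: 0.45
    beta_exposure: 1.60
    role: synthesis
endpoints:
  all_cause_mortality:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.45
    baseline_shape: 1.0
    baseline_scale: 110.0
  cardiovascular_disease:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.45
    baseline_shape: 1.0
    baseline_scale: 160.0
  myocardial_infarction:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.40
    baseline_shape: 1.0
    baseline_scale: 400.0
  intracerebral_haemorrhage:
    causal_log_hr_per_25: 0.0
    confounder_log_hr_per_sd: 0.10
    baseline_shape: 1.0
    baseline_scale: 900.0
lipids:
  tc:   {mean: 5.70, sd: 1.10, causal_per_25: 0.0, confounder_per_sd: 0.18}
  ldl:  {mean: 3.30, sd: 0.95, causal_per_25: 0.0, confounder_per_sd: 0.15}
  hdl:  {mean: 1.48, sd: 0.50, causal_per_25: 0.0, confounder_per_sd: -0.08}
  tg:   {mean: 1.70, sd: 1.00, causal_per_25: 0.0, confounder_per_sd: 0.30}
  apoa: {mean: 162.0, sd: 30.0, causal_per_25: 0.0, confounder_per_sd: -3.0}
  apob: {mean: 115.0, sd: 35.0, causal_per_25: 0.0, confounder_per_sd: 5.0}
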