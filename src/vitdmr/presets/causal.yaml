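# Recovery-test scenario: same architecture and confounding as the
# East-Asian preset but with known nonzero causal effects of 25(OH)D.
# Override causal_log_hr_per_25 / causal_per_25 to set the truth theta.
n_subjects: 20000
seed: 0
exposure_mean: 63.7
noise_sd: 24.0
season_amplitude: 10.0
confounder_exposure: -4.0
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
    causal_log_hr_per_25: -0.0202   # HR 0.98 per 25 nmol/L
    confounder_log_hr_per_sd: 0.25
    baseline_shape: 1.0
    baseline_scale: 110.0
lipids:
  tc:  {mean: 4.65, sd: 0.85, causal_per_25: -0.058, confounder_per_sd: 0.12}
  ldl: {mean: 2.32, sd: 0.70, causal_per_25: -0.034, confounder_per_sd: 0.10}
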