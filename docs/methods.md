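# Methods

## Synthetic cohort model

Each cohort is generated from a `ScenarioConfig`; one integer seed
determines every column.

**Genotypes.** Each instrument SNP is drawn as Binomial(2, p) —
Hardy–Weinberg proportions p², 2pq, q² — with dosage counted on the
25(OH)D-raising allele. An optional proxy pair emulates an LD tag SNP:
each of the tag's two haplotype alleles copies the partner's allele
with probability √r² and is otherwise redrawn at its own frequency.
When the pair shares an allele frequency this yields haplotype
correlation √r², hence dosage r² at the target (default 0.87, the
reported value for the *DHCR7* tag pair). The tag SNP carries no direct
exposure effect; its observed association flows through LD only.

**Covariates.** Age N(51.4, 10.6) truncated to [30, 79]; 61% female;
37% current smokers; 54% current drinkers; day of year uniform, mapped
to a 4-level season; 5 regions; SBP N(131, 21); 18% low physical
activity; BMI N(23.7, 3.4). These match the descriptive profile of a
middle-aged East-Asian biobank; the European preset changes only the
exposure mean and confounding strength.

**Exposure.** 25(OH)D = mean + Σⱼ βⱼ(Gⱼ − 2pⱼ) + A·cos(2π(day −
205)/365.25) + γ·U + ε, ε ~ N(0, σ²). Genetic and seasonal terms are
centred so the cohort mean equals the configured mean. Defaults: mean
63.7 nmol/L (the overall East-Asian cohort mean; the corresponding
baseline table prints 83.7, an internal inconsistency of the source
data — we use the overall mean), σ = 24 nmol/L and season amplitude
10 nmol/L so the marginal SD is ≈ 26 nmol/L, matching the reported
SD. Per-allele defaults are the reported raising-allele effects: 1.49
(*DHCR7*), 0.34 (*CYP2R1*), 5.10 (*GC/DBP*), and 0.80 (*CYP24A1*,
chosen so the four-SNP-score coefficient lands near the reported 1.84
nmol/L; no per-allele value is printed for this SNP).

**Confounding.** A single latent standard-normal U ("unhealthy
lifestyle") lowers 25(OH)D (−4 nmol/L per SD in the East-Asian preset,
−10 in the European preset) and raises the log hazard (+0.25 / +0.45
per SD for mortality). This induces the observational inverse
association while leaving the genetic instrument clean — U has no
genotype dependence, so instrument validity holds by construction.

**Survival.** Event times follow a Weibull proportional-hazards model:
T = scale · (E · e^(−lp))^(1/shape), E ~ Exp(1); shape defaults to 1
(exponential baseline), chosen for closed-form inverse-CDF sampling.
The linear predictor is θ·X/25 + hazard-confounding + fixed covariate
effects (age 0.085/yr, male +0.45, smoking +0.35, SBP 0.008/mmHg, low
activity +0.20), centred at its sample mean so the baseline scale sets
the marginal event rate (≈ 14% for the 12-year mortality endpoint,
1.5–4% for disease endpoints). Censoring is the minimum of the
administrative horizon (12–14 y) and an Exp(rate) random-censoring
time (0.004–0.005 /yr). θ is the causal log HR per 25 nmol/L — zero in
both observational presets.

**Lipids.** lipid = mean + θ_lip·(X − X̄)/25 + confounder term + noise,
with means/SDs at typical cohort values (e.g. TC 4.65 ± 0.85 mmol/L
East-Asian, 5.70 ± 1.10 European) and U raising TC/LDL/TG and lowering
HDL.

What the generator does **not** emulate: realistic minor-allele-
frequency spectra, population stratification, genotyping error,
missing data (all complete-case), assay bias, non-proportional
hazards, or nonlinear exposure effects. Passing recovery tests
therefore shows the estimators are correct under the assumed model,
not that real-data analyses are unbiased.

## Analysis conventions

* Continuous exposure is scaled ×1/25 before Cox fits so coefficients
  read "per 25 nmol/L higher 25(OH)D".
* Covariate profiles: East-Asian observational = age, sex, smoking,
  drinking, season, region, SBP, low physical activity; European
  observational = age, sex, season, SBP, activity, smoking, drinking;
  genetic/IV = age, sex, season, region. Season and region enter as
  indicator contrasts; region enters as a fixed covariate rather than
  a stratification variable (stratified Cox is out of scope; with 5
  balanced synthetic regions the two coincide closely).
* Quartile analyses bin at sample quartiles with quartile 1 as
  reference; the trend test uses a single ordinal index (1,2,3,4), not
  quartile medians.
* The default allele score is unweighted (raising-allele count); a
  beta-weighted variant exists but is off by default.
* Wald-ratio CIs use the first-order delta method. The gene–outcome
  Cox fit uses the score with the genetic covariate profile; the
  gene–exposure fit uses the same profile.
* 2SLS standard errors use residuals evaluated at the observed (not
  fitted) exposure — the correct generated-regressor variance.
* MR-Egger weights are inverse outcome variances (1/se²); the
  intercept is tested against t with k−2 df; k ≥ 3 required.
* DerSimonian–Laird is the random-effects τ² estimator; hazard ratios
  pool on the log scale; random effects are used when I² > 0.25.
* Survival outcomes get Wald ratios, continuous outcomes 2SLS: with a
  hazard-ratio outcome a literal second-stage least squares is not
  defined, so the ratio estimator is the survival analogue. This
  mapping is fixed throughout the package.

## Numerical choices

* Cox: Newton–Raphson with step-halving on the partial likelihood;
  Efron ties by default (Breslow available); tie-free data take a
  fully vectorised path (suffix cumulative sums over the risk sets).
  Convergence: max-norm of the score < 1e-8 scaled by the number of
  events (the score is a sum over events, so the attainable norm grows
  with the data), or a step/log-likelihood stall at float64 precision.
  Monotone likelihoods (perfect separation) are flagged via
  `converged=False` when a coefficient exceeds 15 in absolute value.
* Schoenfeld test: correlation of Schoenfeld residuals with event-time
  rank; the score statistic uses the average information matrix in
  place of per-event variances (Grambsch–Therneau approximation); the
  global test is the corresponding quadratic form with p df. Null
  calibration is verified by simulation in the test suite.
* OLS through statsmodels (exact least squares, classical SEs); rank
  deficiency raises rather than pseudo-inverting.
* HWE: 1-df chi-square at the sample allele frequency; monomorphic
  sites return p = 1.
* Unit table: 25(OH)D 1 ng/ml = 2.496 nmol/L; cholesterol fractions
  38.67 mg/dL per mmol/L; triglycerides 88.57. (Printed parenthetical
  conversions in the source tables are internally inconsistent with
  any single factor; the standard factors are used.)

## Replicate recovery studies (`vitdmr.studies`)

Problem sizes are chosen so each study resolves its truth well inside
the replicate scatter:

| study | truth | n per cohort | replicates |
|---|---|---|---|
| per-allele OLS recovery | 1.49 / 5.10 nmol/L | 20,000 | 50 |
| score-level OLS recovery | 0.95 / 1.84 nmol/L | 20,000 | 50 |
| lipid 2SLS recovery | −0.058 / −0.034 mmol/L per 25 | 50,000 | 100–120 |
| Wald-ratio HR recovery | HR 0.98 per 25 | 100,000 | 100–120 |
| observational Cox recovery | HR 1.09 per 25 | 50,000 | 100 |
| Wald CI coverage | 95% nominal | 4,000 | 500 |

Score recoveries rescale the component per-allele effects (preserving
their ratios) so the analytic unweighted-score coefficient
Σβⱼvⱼ/Σvⱼ (vⱼ = 2pⱼ(1−pⱼ)) equals the target. Ratio (HR) recoveries
are summarised by the geometric mean of replicate HRs — the natural
summary for a ratio estimate (the arithmetic mean of exponentials is
upward-biased by Jensen's inequality at realistic per-replicate
spread). In the observational Cox recovery the latent lifestyle
variable is given no hazard effect, so the adjusted model's estimand
equals the configured truth; elsewhere confounding is active and the
IV estimators must remove it. The CI-coverage study uses the strong
transport SNP as a single-SNP instrument so the first stage stays
strong (F ≈ 70) at the per-replicate sample size.

A bias property for the Wald estimator (true log HR ±0.05 recovered
with mean bias within Monte-Carlo resolution) is tested at n = 50,000
with the four-SNP score; larger designs resolve finer bias but add
nothing qualitative.

## Known limitations

* Stratified Cox, time-varying covariates and frailty are not
  implemented; region stratification is approximated by adjustment.
* Non-linear MR and median/mode MR estimators are out of scope.
* The Egger intercept test with 3–4 instruments has low power for a
  single pleiotropic outlier; it reliably detects *directional*
  pleiotropy shared across instruments.
* VCF ingestion covers biallelic GT records only (no imputed dosages,
  no liftover, alleles must match as given).
* First-stage F is the squared Wald t of the score term; published
  F-statistics in this literature are sometimes inconsistent with
  (β/SE)², and no attempt is made to reproduce any particular printed
  F value.
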