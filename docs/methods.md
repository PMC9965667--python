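# Methods

This note documents the models, numerical conventions, and design choices
behind `metamed`, and what the synthetic-data generator does and does not
emulate.

## Synthetic cohort model

The generator emulates a population-based adult cohort with targeted
serum metabolomics. Defaults (all overridable in `SimulationConfig`):

| parameter | default | units / rationale |
| --- | --- | --- |
| `n_participants` | 1715 | analysis-sample size of the emulated study |
| `n_metabolites` | 146 | post-QC panel size of a targeted kit assay |
| `n_plates` | 22 | ~80 participant wells per 96-well kit plate |
| age | Normal(59, 12), clipped to [25, 95] | years |
| BMI | log-normal, mean 27.5, SD 4.7, floor 16 | kg/m² |
| `direct_effect` | 0.04 | mmol/L fasting glucose per kg/m², bypassing mediators |
| `glucose_noise_sd` | 0.9 | mmol/L |
| `mediation_truths` | a ∈ {0.05, 0.04}, b ∈ {0.06–0.10} | a: SD log-metabolite per kg/m²; b: mmol/L per SD |
| `t2d_intercept`, `t2d_coefficients` | −10.2; 1.1·glucose + 0.08·BMI | logistic link, prevalence ≈ 0.17 |
| `censor_fraction` | 0.05 | share of each metabolite left-censored |
| `metabolite_log_sd` | 0.4 | biological spread on the log scale |
| `reference_cv` | 0.05 | analytical CV of reference wells |
| `plate_batch_sd` | 0.1 | log-normal multiplicative batch factor SD |

Fasting glucose is built structurally: each planted mediator has a latent
standardized log-abundance `z = a·(BMI − 27.5) + ε`, ε ~ N(0, 1), and
glucose is `5.5 + direct·(BMI − 27.5) + Σ b·z + noise`. HbA1c tracks
glucose with its own noise. The latent `z` is reused by the plate
generator, so the metabolite concentrations and the glycemia they
"caused" are mutually consistent. T2D is a Bernoulli draw from a logistic
link on glucose and BMI: the minimal generative structure the downstream
analyses assume. The BMI floor of 16 kg/m² means the underweight
exclusion class is exactly the set planted through `class_counts` /
`class_fractions`, keeping exclusion bookkeeping exact.

Covariates (blood pressure, HDL-C, triglycerides, physical inactivity)
are drawn with mild BMI dependence so covariate adjustment has something
to do; the exact joint distribution of a real cohort is not modelled.

Plate structure: participants are chunked into plates in id order; each
plate carries three zero (blank) wells and reference wells (at least five
reference measurements per run). The multiplicative batch factor applies
to **every** well of a plate — sample, reference and zero alike — which
is precisely what makes reference-sample bridging able to remove it.
Censoring marks values below the per-metabolite empirical
`censor_fraction` quantile as non-detectable (value withheld, flag set).
QC-violation plants: high-CV metabolites alternate reference wells ±60 %
around target; below-LOD plants raise the zero wells to 40–60 % of the
base concentration; non-detectable plants raise the censoring fraction to
0.6.

GWAS summary pairs: exposure betas are drawn positive (instruments
oriented to the trait-increasing allele, as published instrument lists
are), with |z| between 7 and 18 so all instruments are genome-wide
significant. Outcome betas are `causal·β_exp + pleiotropy intercept +
N(0, heterogeneity SD)` plus estimation noise. A configurable fraction of
outcome rows is emitted with swapped allele labels (sign and EAF flipped)
and a fraction of SNPs is palindromic, to exercise harmonization. The
positive-beta orientation is what makes a planted directional-pleiotropy
intercept recoverable under the Egger β_exp ≥ 0 convention.

One RNG stream per artifact (cohort / plates / GWAS), derived from the
master seed with fixed offsets: regenerating one artifact never perturbs
another, and identical config + seed is bit-reproducible.

**What passing tests do and do not show.** The generator produces clean
Gaussian/log-normal data with linear effects and no missingness beyond
what is planted. Passing recovery and calibration tests demonstrates that
the estimators are implemented correctly and behave as their theory
predicts under their own assumptions — not that the pipeline is robust to
the skewness, nonlinearity, informative missingness, drift within plates,
or LD complexity of real cohort data.

## Preprocessing conventions

- Participant exclusion order: (1) BMI < 15 kg/m² or any missing model
  covariate, (2) prediabetes, (3) T1D, (4) unclear diabetes type;
  first-match-wins tallying.
- Plate LOD = 3 × median of the plate's three zero samples. The CV
  criterion uses the sample (n − 1) SD over all reference measurements;
  all three thresholds are applied with ≥, not >. An undefined CV
  (reference mean 0) excludes the metabolite rather than raising.
- Detectable-but-below-LOD cells are retained as measured (they count
  only toward criterion 2); only non-detectable cells are imputed, as
  Uniform[0.75, 1.25] × (half the plate minimum measured value), seeded.
  Measured values pass through bit-exact.
- Plate normalization factor NF(plate, metabolite) = across-plate
  reference median / plate reference median, per metabolite (the
  reference-bridging convention of targeted kit assays). Whether real
  pipelines use per-metabolite or per-plate-global factors varies; the
  per-metabolite choice is flagged for sensitivity analysis.
- Log/scale transform uses the sample (n − 1) SD computed on the analysis
  sample (after participant filtering), and stores per-column mean/SD so
  it is invertible.

## Association

OLS (BMI outcome) and maximum-likelihood logistic fits (T2D outcome) via
statsmodels, one metabolite at a time, with Wald 95 % CIs; logistic
results are reported on both the log-odds and odds-ratio scales, since
published tables sometimes mix the two labels. Covariate codings:
sex → man dummy; smoking → smoker and ex-smoker dummies (reference
never); activity → inactive dummy. Complete-case analysis per tier.
Bonferroni q = min(1, p·m) with m defaulting to the retained panel size;
at m = 146 and α = 0.05 the threshold is 0.05/146 ≈ 0.00034. Perfect
separation or non-convergence yields a flagged row, not a crash.

## Mediation

Only the mediator is residualized (on age, sex, physical activity,
smoking, systolic BP, HDL-C, triglycerides); exposure and outcome enter
the Sobel model unadjusted. This deliberately replicates the
residualize-then-test construction rather than full covariate-adjusted
mediation. First-order Sobel SE (not Aroian/Goodman), normal reference;
`a` from mediator ~ exposure, `b` from outcome ~ exposure + mediator.
Significance is the Bonferroni q < 0.05 rule. The test is conservative
under the complete null (a = b = 0), which the calibration suite
verifies. Metabolites significant against both fasting glucose and HbA1c
are reported as the robust-mediator intersection.

## Mendelian randomization

- Instrument selection: p strictly below 1×10⁻⁸ (as configured; exposed
  as a knob since conventions differ).
- Clumping: greedy by ascending p on an explicit r² matrix with no
  distance window — synthetic LD is explicit, so genomic coordinates are
  unnecessary.
- Harmonization: label-swapped SNPs flip the outcome beta and EAF.
  Palindromic SNPs are kept only when both EAFs are on the same side of
  0.5 and both outside [0.42, 0.58]; otherwise dropped (the dominant
  two-sample-MR convention).
- IVW: fixed-effect estimate Σ(β_x β_y/se_y²)/Σ(β_x²/se_y²), SE
  √(1/Σ(β_x²/se_y²)); Cochran Q with weights (β_x/se_y)², df = n − 1.
  When p_Het < 0.05 the multiplicative random-effects SE
  (fixed × √(max(1, Q/df))) is reported as primary. One SNP reduces
  exactly to the Wald ratio.
- Wald ratio: β_y/β_x with first-order delta-method SE se_y/|β_x|
  (exposure uncertainty ignored — the single-instrument convention).
- MR-Egger: exposure betas oriented non-negative (outcome sign flipped
  accordingly), weighted free-intercept regression with weights 1/se_y²,
  multiplicative overdispersion bounded below by 1, t-distribution
  inference on n − 2 df. Requires ≥ 3 instruments; with a single
  instrument no sensitivity analysis is attempted.

## Numerical choices and degenerate inputs

Closed-form least squares (QR via `lstsq`) backs the Sobel and MR
estimators and the Monte-Carlo loops; statsmodels backs the user-facing
association fits and serves as the independent oracle for the closed-form
estimators in tests. Rank-deficient designs raise a model error naming a
collinear column. Zero-variance mediators/exposures, zero exposure betas,
empty instrument sets, zero reference medians, and nonpositive values at
the log step all raise typed errors naming the offending object. Ties in
clumping are broken by the stable ascending-p order.

## Problem sizes

The test and acceptance runs use deliberately modest sizes — cohorts of
300–5000, panels of 5–146 metabolites, 500 calibration and 200 recovery
replicates at 50 instruments — chosen so the whole suite completes in
well under a minute while keeping Monte-Carlo standard errors small
relative to the tolerances tested (3 SE bounds, ±3 MC SE on rates).

## Known limitations

- No within-plate drift correction, cross-kit harmonization, or
  class-specific calibration chemistry.
- No bootstrap mediation CIs or counterfactual mediation estimands; no
  multiple-mediator joint models.
- No genotype-level simulation, reference-panel LD, weighted-median/mode
  MR estimators, Steiger filtering, or multivariable MR.
- The stratified summarizer's chi-square is the textbook (uncorrected)
  statistic; software that applies a Yates correction to 2×2 tables will
  differ slightly.
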