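# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the places where a genuinely open design decision was made.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The score

The genomic risk score is a weighted allele count,
GRS_i = Σ_j w_j g_ij, with weights w_j interpreted as per-allele log odds
from an external GWAS and dosages g_ij ∈ [0, 2] counting the effect allele.
Reported effects are always per standard deviation of the score within the
evaluation cohort (sample SD, denominator n − 1), which makes them invariant
to linear rescaling of the raw weights.

**Harmonization.**  SNPs are matched by identifier.  Where the cohort's
counted allele is the statistics' *other* allele, the dosage is reflected
(g ← 2 − g) rather than the weight negated; the standardized score is
identical either way (the raw score shifts by the constant 2w).
Strand-ambiguous SNPs (A/T, C/G) cannot be oriented from alleles alone; they
are dropped unless |EAF − 0.5| exceeds a margin (default 0.08) and the
cohort frequency is concordant, in which case frequency decides the
orientation.  All drop/flip counts are logged.  The margin is a conservative
convention; there is no principled universal value.

**LD thinning.**  Greedy p-value-priority clumping: SNPs are visited in
ascending p-value (ties broken by chromosome, then position, making the
procedure fully deterministic); a SNP is kept unless its dosage r² with an
already-kept SNP within a 1 Mb window exceeds the threshold.  r² is the
squared Pearson correlation over pairwise-complete samples; degenerate
(zero-variance) columns contribute r² = 0 rather than blocking a keep.
LD is always computed from the supplied genotypes, never a reference panel.
Which ordering real-world clumping tools use varies; p-value priority is the
dominant convention and is what is implemented (the visit order is a single
function, `grslife.score._thin_order`, if a variant is needed).

**Threshold selection.**  For each threshold in a grid (default
1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.3, 0.1) the kept set is scored and the
binary-outcome AUC computed; the maximizer is returned, with exact AUC ties
broken toward the *larger* threshold (fewer SNPs removed).  Per-threshold
per-SD logistic odds ratios are reported alongside.

**Missing dosages** are mean-imputed as 2·EAF so that scores remain
comparable across subjects with different missingness; subjects are never
dropped for missing genotypes.  Monomorphic SNPs get missing weights and are
excluded from scores, counted against coverage.

## Survival models

All estimators put **attained age on the time axis with delayed entry** at
baseline age: the risk set at age a is {entry < a ≤ exit}.  Age-matched risk
sets are the point of the construction; calendar follow-up time is used only
for the 10-year horizon definitions below.

* **Cox fits** are sex-stratified, cause-specific (competing events are
  censored — by construction the cause-specific hazard ratio equals the
  ordinary one computed after relabelling competing events as censoring),
  and use the Efron tie correction.  Maximization is delegated to
  `lifelines.CoxPHFitter`; the package's own tests pin the estimate to the
  root of a hand-written partial-likelihood score equation on a fixture.
  Hard errors are raised for constant covariates, strata without events of
  the target cause, and non-convergence.
* **Baseline cumulative hazard** is the Breslow estimator,
  ΔH₀(a) = d(a) / Σ_{risk set} exp(lp), computed directly from its formula
  per stratum (not taken from lifelines, whose baseline is defined at
  centred covariates).  Model-based 10-year risk from entry age a₀ is
  1 − exp(−[H₀(a₀+10) − H₀(a₀)]·e^lp), with flat extrapolation (logged)
  beyond the last observed event age.
* **Kaplan–Meier** uses the product-limit form on the age axis with delayed
  entry and a Greenwood variance on the log scale.  **Aalen–Johansen**
  cumulative incidence is CIF(t) = Σ_{a≤t} S(a−)·d_cause(a)/n(a) with S the
  all-cause KM; its pointwise band uses the standard counting-process
  variance (Klein–Moeschberger form), clipped to [0, 1].  With no competing
  events CIF ≡ 1 − KM (asserted to 1e−12; the sum and product forms are
  algebraically identical but not bitwise in floating point).
* **Risk-crossing age** is the smallest jump age at which cumulative
  incidence reaches a level (default 10%); groups that never reach it
  return "not attained" rather than an extrapolated age.

## Discrimination and reclassification

* **Truncated C-index**: pair (i, j) is comparable iff i has the event at
  follow-up time t_i ≤ 10 years and t_i < t_j; concordance counts
  score_i > score_j, ties 0.5.  Follow-up time (not attained age) defines
  the horizon; an attained-age variant would age-match pairs instead and is
  deliberately not the default, matching the "events within 10 years"
  framing.  ΔC between two models on the same subjects uses leave-one-out
  jackknife pseudo-values, variance ((n−1)/n)·Σ(ΔC₍₋ᵢ₎ − mean)², normal
  two-sided p; ΔC exactly 0 reports p = 1.  The leave-one-out quantities are
  obtained from per-subject pair sums, so the whole computation is O(n²)
  rather than O(n³).
* **C-index model comparison uses nested fitted models.**  "Clinical" and
  "clinical + GRS" are both age-scale Cox fits (on the logit of the
  published-equation risk, the latter adding the standardized GRS), so a
  null GRS yields ΔC centred on zero.  Binning the *published-equation* risk
  against a refitted model instead would fold recalibration of the clinical
  score into ΔC (measured at ≈ +0.02 under a null score during development),
  which is a different and misleading quantity.
* **Reclassification** bins the published-equation clinical risk against the
  fitted combined-model risk, in the 0–7.5 / 7.5–10 / 10–20 / 20–100 %
  categories, half-open [lo, hi) with the last bin closed (exactly 7.5%
  falls in the second category).  A subject is a 10-year event iff CHD
  occurs within 10 years of entry; subjects censored earlier count as
  non-events.  No inverse-probability-of-censoring correction is applied —
  this matches how printed cross-tab margins are constructed and is a known
  limitation under heavy early censoring.  Categorical NRI components use
  the standard binomial-difference (Pencina-style) variance; continuous NRI
  uses unweighted sign proportions with ties contributing zero; IDI is the
  change in discrimination slope with a two-sample paired-mean variance.
  Because the bundled clinical equations are calibrated to real source
  populations, their absolute risks differ from any synthetic cohort's;
  synthetic-cohort categorical NRI therefore mixes calibration offset with
  discrimination and can be negative even when the GRS adds information —
  the continuous NRI and ΔC are the calibration-free readouts there.

## Clinical risk engines

Both bundled scores share the Cox-equation form
risk = 1 − S₀^exp(LP − L̄P) with sex-specific coefficient tables shipped as
versioned data files (JSON manifest + TSV term table), each term a
coefficient times a product of transformed, optionally scaled covariates
(identity, log, complement; cholesterol scaled mmol/L → mg/dL inside the
terms).  Treated and untreated systolic blood pressure enter as separate
product terms with the treatment indicator and its complement.  The engine
is variant-agnostic: any score of this family can be supplied as data.
Cohorts without a race variable are mapped to the pooled-cohort equations'
white stratum (logged).  Tests assert structure, hand-recomputed linear
predictors, probability range, monotonicity in each risk factor (age within
40–79, where the pooled-cohort quadratic age term is monotone) and stratum
separation — not published magnitudes, which belong to the source
publications.

## Meta-analysis

Fixed-effect inverse-variance pooling on an additive scale (log HR, ΔC,
NRI, IDI): weights 1/SE², pooled SE (Σw)^(−1/2), Q = Σw(θ−pooled)²,
I² = max(0, (Q−df)/Q)·100, p from χ²(k−1).  Where only printed CIs are
available, SE is recovered as (log hi − log lo)/(2·1.96).  No random-effects
model is provided.

## The synthetic cohort generator

The generator's defaults define the study conditions; they are fixed, not
tuning knobs.

* **Genotypes**: two haplotypes per person, each from a latent AR(1)
  Gaussian (parameter ρ, default 0.8, blocks of 20 SNPs) thresholded at
  Φ⁻¹(1 − MAF), MAF uniform on (0.05, 0.5).  This yields exact {0,1,2}
  dosages, tunable within-block LD and independence across blocks.  It does
  not emulate recombination maps, MAF-dependent LD decay, or imputation
  uncertainty — dosages are always hard calls.
* **Summary statistics**: weight_j = β_j + SE_j·ε,
  SE_j = (2p_j(1−p_j)·N)^(−1/2), N = 200,000 (large-consortium scale).  10%
  of SNPs are causal with β ~ N(0, 0.08²).  With these defaults the noise
  variance in the score is ≈ 2% of the signal variance (M/N = 0.01 against
  Σ2p(1−p)β² ≈ 0.5), so the per-SD hazard ratio of the constructed score is
  attenuated by well under its sampling SE at n = 5,000 — the premise of the
  parameter-recovery check.  Null SNPs' Wald z are exactly standard normal
  by construction.
* **Survival**: CHD event ages follow a Weibull proportional-hazards model
  on the age scale, log-hazard log(1.74)·z + covariate terms (smoking 0.6,
  diabetes 0.6, male 0.7, and ±0.25–0.3 per SD of SBP/total/HDL
  cholesterol), sampled conditionally on surviving to the entry age so left
  truncation is always exercised.  Baseline shape 6, scale 110 were
  calibrated once by quadrature/simulation so that ≈6% of subjects have an
  incident CHD event within the 15-year administrative follow-up before age
  75; competing non-CHD death (shape 8, scale 90.5) gives ≈20% lifetime
  mortality by 75, enough for Aalen–Johansen to visibly separate from
  1 − KM.  Entry ages are truncated-normal 45.97 (SD 12.7) on [25, 74];
  covariate means/prevalences follow population-register-style values
  (SBP 134.9 (19.7) mmHg, total cholesterol 5.58 (1.11) mmol/L, HDL 1.45
  (0.38), smoking 26%, diabetes 5%).  Family history is Bernoulli with
  logit linear in the standardized true score (slope 0.3, baseline
  prevalence 15%) — a stand-in for first-degree-relative history without
  pedigree simulation.  The Weibull baseline is a convenience, not an
  estimate of any real cohort's hazard.
* **Filters**: prevalent-CVD subjects (3% by default) are excluded, events
  after attained age 75 are recoded as censoring at 75, and an optional
  minimum baseline age (30, for cohorts that need it) drops young entrants.
  Filtering is idempotent and never mutates its input.

What passing tests on this generator do **not** show: behaviour under
population stratification, imputation error, miscalibrated summary
statistics, informative censoring, or real LD architecture.  The generator
is a correctness harness for the statistical machinery, not a simulator of
any particular population.

## Reproducibility and problem sizes

Every stochastic operation draws from `numpy` Generators seeded as
(seed, stream) pairs, one stream per stage, so identical configs give
bit-identical outputs and the pipeline's `report.json` is byte-identical
across runs.  The test suite uses n ≤ 5,000 × M ≤ 2,000 for recovery checks
(50 replicates), n ≈ 1,200–1,500 for the null-calibration checks (40–200
replicates), and ≤ 6-SNP/≤ 50-subject fixtures for exhaustive oracles;
`scripts/acceptance.py` runs one full pipeline at 5,000 × 2,000.  These
sizes give Monte-Carlo error comfortably inside the asserted tolerances
while keeping a full run in minutes on one CPU.

## Known limitations

* No IPCW-corrected NRI or C-statistic (Uno-type); estimates inherit the
  usual censoring caveats.
* No reference-panel LD, no penalized score training, no cross-chromosome
  LD handling (positions are the only locality notion).
* No time-varying covariates, frailty, or Fine–Gray subdistribution
  hazards; competing risks are handled via cause-specific models and
  Aalen–Johansen estimation only.
* Clinical equations are applied, never recalibrated, to the cohort at
  hand; see the calibration remark under reclassification.
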