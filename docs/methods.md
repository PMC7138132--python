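# Methods

This note records the models, defaults and numerical choices behind
`twinmet`, and what the simulation-based tests do and do not establish.

## The synthetic cohort generator

The generator emulates a twin register enriched by design for aggression
concordance/discordance, plus a clinically referred case group.

**Liability.** Each twin's aggression liability follows the ACE model:
MZ pairs share the full additive-genetic component, DZ pairs half of its
variance, so within-pair correlations are a²+c² (MZ) and ½a²+c² (DZ) with
unit total variance.  Defaults a²=0.63, c²=0.14, e²=0.23.  T-scores are
10·z+50.

**Selection.** Pairs are drawn and screened against T-score thresholds —
both ≥ 65 gives concordant-high, both ≤ 55 concordant-low, one of each
discordant — until per-group pair quotas are filled (302 concordant-low,
182 concordant-high and 189 discordant complete pairs; 92 further
low-scoring pairs are reserved as validation controls).  This is a
rejection sampler: conditional on selection, the liabilities retain the
joint distribution a register-based selection would produce.  The
low-score threshold has no canonical T-score equivalent, so it is a
configurable parameter rather than a claimed-faithful constant.  Cases
(n=183 by default) are drawn from the upper tail of the same liability
scale, T ≈ N(66, 11), with 25.7% females; twins get Bernoulli(½) sex (MZ
pairs share sex) and pair-shared ages uniform on 6–13 years.

**Metabolome.** For feature *m* and subject *i*,

```
log excretion = log baseline_m + b_m z_i + s_m,sex female_i + s_m,age age*_i
                + u_family + ε
measured      = β_m (d_i − d_w) · excretion · exp(technical noise)
```

with urine density d_i ~ Uniform(1.005, 1.035) and d_w = 1, so the
control-anchored density normalization is exactly recoverable by
construction.  Defaults: 89 features (64 amines, 20 organic acids, 5 other
biomarkers — counts a targeted two-platform urinary panel would produce);
total biological log-SD 0.30, of which 10% of variance is a family-shared
random effect; per-feature sex/age coefficients ~ N(0, 0.1²); 6 associated
features with `effect_size_sd = 0.30`, parameterized as the standardized
outcome shift for the high-vs-low status contrast (the selection thresholds
separate the groups by ≈2 liability SDs, so the per-liability-SD slope is
`effect_size_sd · log_noise_sd / 2`).  This puts simulated discovery
effects in the small-effect regime (|β| ≈ 0.2–0.5 SD with SEs near 0.07)
that such biomarker panels report.  Because effects are defined on the
standardized scale, a zero-noise configuration has no planted effects by
construction.

**Measurement layer.** Pooled-QC replicates (30 by default) are lognormal
with per-feature target RSD drawn from Uniform(3, 19)%; the neurotransmitter
metabolites used in ratios draw from Uniform(3, 12)% (targeted assays are
precise), which keeps the ratio panel intact through QC filtering while
generic features still exercise the removal rule.  Values below the 5%
quantile of each feature are censored; the detection limit is recorded for
half the features and left unknown for the rest.

**Optional confounders.** `confounder_effect` adds a family-level shift
proportional to the family's mean liability (used to demonstrate that
between-family contrasts are biased while within-pair differences are not);
`exclusion_shift` shifts flagged (medicated) subjects, whose flag
probability rises with liability — used to test that sensitivity exclusions
remove the induced bias.  Both default to 0.

**What the simulation does not emulate:** batch/instrument drift across
runs, correlated metabolite blocks or pathway structure, non-lognormal
measurement error, longitudinal or multi-rater phenotype structure, and
assortative mating or sex-limitation in the twin model.  Passing tests
therefore establish the pipeline's statistical contracts under the stated
generative model, not robustness to those real-data features.

## Preprocessing

Order is fixed and enforced through a stage marker on the matrix:
below-LOD imputation → percent-of-median scaling → density model fit/apply
→ verification → inverse normal transform (INT).  Out-of-order calls raise.

- **RSDqc.** 100·SD/mean of pooled-QC replicates.  Interpretability status:
  pass ≤ 15%, caution 15–30%, fail > 30% (or degenerate QC); *removal* from
  analysis is a separate, stricter rule: strictly above 20%.  Caution
  features that survive removal stay flagged in every downstream report.
- **LOD imputation.** Censored cells get half the detection limit; when the
  limit is unknown, half the lowest observed level.  A feature entirely
  censored with unknown limit is an error, not a guess.
- **Density models.** Fitted per feature by least squares (with intercept)
  of the percent-of-median concentration on (d_i − d_w), in a designated
  control group only (default: concordant-low and control twins; the choice
  is an explicit argument because it is genuinely open).  Control values
  beyond 2.5 SD from the feature mean are replaced by the mean *inside the
  fit only* — the analysis matrix is never modified.  Concentrations enter
  on the percent-of-median scale; densities stay on the raw specific-gravity
  scale, where d_w = 1 is meaningful.
- **β_m guard.** A slope ≤ 1e-8 would make the division unstable or flip
  signs; such features are scaled by (d_i − d_w) alone and flagged.
- **Verification.** After normalization, the residual slope of each
  normalized feature on density is computed from points within 3 SDs of the
  feature mean.  A feature is *verified* when density explains at most 5%
  of its remaining variance.  The bound is on the variance fraction (R²)
  rather than the raw slope because a slope tolerance is scale- and
  sample-size-dependent: under the generative model the residual slope is
  pure sampling noise of order n^(−1/2) times the noise-to-density-SD
  ratio, so no fixed slope bound can hold across designs, while the
  variance fraction is scale-free and exactly zero for noiseless data.
- **INT.** Rank-based mapping to Φ⁻¹((r − 3/8)/(n + 1/4)) (Blom offset,
  average ranks for ties, missing values preserved).  Output depends only
  on ranks, hence is invariant to strictly monotone input transforms.

## Neurotransmitter ratios

Seven precursor/product ratios proxy pathway flux: L-tryptophan:5HTP and
5HTP:serotonin (serotonergic anabolism), L-phenylalanine:L-tyrosine
(dopaminergic anabolism), 3MT:HVA (dopaminergic catabolism),
L-glutamine:L-glutamic acid and L-glutamic acid:GABA (GABA synthesis),
GABA:succinic acid (GABA degradation).  Ratios are formed on the
density-normalized, pre-INT scale — INT output can be non-positive, which
would make ratios meaningless — and INT-transformed afterwards for
analysis.  Non-positive or missing denominators yield missing ratios, never
infinities.

## The association cascade

- **Discovery** (concordant-low vs concordant-high twins): linear GEE per
  outcome with identity link, exchangeable working correlation within
  family, sandwich SEs and normal-reference Wald p-values.  Identity link
  because INT makes the outcomes Gaussian; normal reference is standard
  sandwich practice (at the design's ~480 clusters the small-sample df
  correction is immaterial — the null-calibration test runs at that scale
  for exactly this reason).  BH-FDR within the biomarker family and,
  separately, the ratio family.
- **Selection**: "most strongly associated" = smallest discovery p, with
  deterministic tie-breaks (|β| descending, then id).  Explicit per-panel
  counts (16 amines / 5 organic acids / 2 other; 3 of 7 ratios) take
  precedence over the global ceil(0.25·m) rule — the two are not mutually
  consistent, and the per-panel counts are the reproducible specification.
- **Replication**: outcomes residualized on sex and age over the
  replication subjects, then paired t-tests of high-minus-low within-pair
  differences (df = pairs − 1; zero-variance differences give t = 0,
  p = 1).  This contrast is algebraically invariant to any family-level
  additive confounder.
- **Validation**: candidates must have congruent effect direction in
  discovery and replication; the best five biomarkers by discovery p plus
  the single best congruent ratio go into a case-vs-control GEE with the
  same contract.  BH spans the five biomarkers; the single pre-registered
  ratio is reported unadjusted.
- **Sensitivity**: within-pair tests are repeated per exclusion scenario
  (chronic condition, medication, vitamins), dropping whole pairs when
  either twin is flagged; BH pools records across scenarios (scenarios ×
  candidates declared as one family).
- Missing data are complete-case per outcome with n reported per record;
  the three phase samples must come from disjoint families or the run
  aborts.  The whole cascade is deterministic given cohort, matrix and
  configuration; reports carry seed and config hash and rewrite
  byte-identically.

The GEE solver is implemented in-package: with exchangeable correlation the
cluster-inverse is affine in two α-free matrices, so one pass of sufficient
statistics serves every outcome column and every candidate α — which makes
replicate-heavy calibration studies cheap.  It reduces exactly to robust
(HC0) OLS for singleton clusters and is tested against statsmodels' GEE to
1e-8 on clustered designs.

## ACE estimation

Direct MLE over the three variance components (bounded below at zero; the
unique-environment component bounded away from zero for positive
definiteness) plus the mean; the total variance is profiled implicitly.
Starting values come from the Falconer moment estimates a² = 2(rMZ − rDZ),
c² = 2rDZ − rMZ (double-entry correlations, clipped to the simplex), with
two fallback starts against boundary attraction; the fit is flagged
non-converged if the optimizer fails or ends below the Falconer-start
likelihood.  The likelihood is evaluated from per-zygosity sufficient
statistics (exchange-invariant pair sums), so fits cost microseconds and
profile scans are cheap.  90% confidence intervals are profile-likelihood
intervals (χ²₁ cutoff 2.706) obtained by bisection on each standardized
fraction; a bootstrap alternative was considered and rejected as strictly
slower with no accuracy gain at these sample sizes.  Incomplete pairs are
excluded; no sex-limitation or ADE variants are modeled.

Simulation scales used by the tests, chosen to keep the full suite in a
few minutes while leaving Monte-Carlo error well inside the asserted
tolerances: ACE recovery averages 20 replicates at 751+1,149 pairs;
profile-CI coverage uses 120 replicates at 250+250 pairs (3-MC-SE band
around 90%); discovery FDR calibration uses 500 replicates at the design's
discovery scale; confounder-immunity uses 100 replicates of a reduced
11-feature design.

## Known limitations

- The normal-reference GEE p-values are anti-conservative below roughly
  150 clusters; a df-corrected reference would be needed for small designs.
- The density normalization assumes a multiplicative dilution acting
  through β_m(d_i − d_w); additive backgrounds or saturation are not
  modeled.
- BH is applied within declared families; no hierarchical or cross-phase
  error control is attempted.
- The profile CIs assume the usual χ² asymptotics, which are conservative
  when an estimate sits on the a² = 0 or c² = 0 boundary.
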