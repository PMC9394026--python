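# Methods

## Scope and model

The package stages cognitively unimpaired (CU) older adults on two axes of
subtle, pre-MCI cognitive change and relates them to tau PET burden.  The
staging cascade is strictly ordered: dementia diagnosis → actuarial MCI
exclusion → CU with SMC and Obj-SCD flags.  Because MCI screens first, MCI
and Obj-SCD are mutually exclusive by construction, a property asserted by
an exhaustive 2⁹-pattern oracle test over every impaired/unimpaired
combination of the nine scores.

### Normative adjustment

The adjustment for age, education and sex is implemented as regression-based
norms: per measure, OLS of the raw score on age (years), education (years)
and a female indicator (female = 1), with residual SD computed with
denominator n − 4 (four estimated parameters).  Regression norms were chosen
over stratified age-band lookup tables because they are reproducible from
any supplied reference sample, use the data efficiently at modest n, and are
the standard approach for actuarial classification batteries.  A consequence
of the n − 4 denominator is that self-standardizing the reference sample
gives z-scores with mean exactly 0 and SD √((n−4)/(n−1)) ≈ 0.999 at
n = 800, within the calibration tolerance asserted in tests (mean ±0.01,
SD ±0.02).

z-scores are impairment-oriented: timed and error measures (Trail Making
times, intrusions) are sign-flipped so z < −1 always means "worse than 1
adjusted SD below expectation".  The impairment boundary is strict —
z = −1.000 exactly is unimpaired — matching a "more than 1 SD below"
definition.

### Classification rules

* **Actuarial MCI**: both total scores impaired within at least one domain.
  The rule sits behind a single function so alternative MCI definitions
  (e.g. ones that add functional measures) can be swapped in; no functional
  data are in scope here.
* **Obj-SCD**: criteria evaluated in fixed order a → b → c for reporting
  which fired; the boolean outcome is an order-independent OR.
* **SMC**: 12-item CCI sum ≥ 16, inclusive.  Items are ordinal 1–5, so the
  sum floor is 12.
* **Missing scores** standardize to a missing z and count as *unimpaired*
  during rule evaluation; labels carry a completeness flag so analyses can
  filter.  This is deliberately conservative — an absent test never creates
  impairment.
* **Intrusions** are summed over all seven list-A recall trials (learning
  trials 1–5, short-delay trial 6, long-delay free recall).

### Biomarker thresholds

All positivity calls are strict inequalities (boundary value negative):
tau Braak III/IV SUVR > 1.51; amyloid SUVR > 1.11 (florbetapir) / > 1.08
(florbetaben).  Centiloid conversion is a per-tracer linear map; the shipped
coefficients are **placeholders** flagged as unconfirmed — centiloid
calibration depends on the exact image-processing pipeline, which is outside
this package's scope — and the analysis logs a warning when they are used.

### Statistics

* **Cohen's κ** is authored in-package because the inferential variant
  matters: the test of κ = 0 uses the large-sample null variance
  var₀(κ) = [p_e + p_e² − Σᵢ p_{i·} p_{·i}(p_{i·} + p_{·i})] / [n(1 − p_e)²]
  with a two-sided normal reference.  The implementation is cross-checked
  against scikit-learn's κ on label vectors in tests.
* **Pearson χ²** delegates to `scipy.stats.chi2_contingency` with
  `correction=False`; no continuity correction anywhere, matching the
  convention of the analyses this pipeline reproduces.  Tests cross-check
  the statistic against a brute-force Σ(O−E)²/E, exhaustively for all 2×2
  tables with total ≤ 12, and verify 5% type-I error over 10,000 simulated
  independence tables at n = 236 with study-like margins.
* **ANCOVA** is fitted as OLS (statsmodels) with dummy-coded groups and
  numeric covariates.  The group effect is the extra-sum-of-squares F
  comparing the model with vs. without group terms — Type III with respect
  to the group factor.  Partial η² = SS_group/(SS_group + SS_resid).
  Adjusted means are model predictions with covariates at their sample
  means.  Pairwise contrasts are t tests on adjusted-mean differences using
  the model covariance, uncorrected for multiplicity (read against α = .05).
  With no covariates the ANCOVA F reduces to the one-way ANOVA F (asserted
  at 1e−10), and with two groups F equals the squared contrast t (1e−8).
* **Outcome transform**: tau SUVR is analysed raw by default; a log
  toggle (`AnalysisConfig(log_transform_outcome=True)`) exists because
  skewed SUVR distributions are sometimes analysed on both scales to check
  robustness.
* **Missingness**: complete-case deletion per analysis, not globally, so a
  missing amyloid scan drops a participant only from the amyloid-adjusted
  sensitivity model.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes — it
is a study-conditions simulator, not a cognitive model.

* **Latent classes**: four SMC × Obj-SCD cells with probabilities
  57/116/20/43 out of 236; optional MCI/dementia contamination (default 0,
  since the emulated cohort is post-exclusion).
* **Marginals**: age 70.82 (6.24), education 16.86 (2.21), 57.2% female,
  36% APOE ε4 carriers, pulse pressure 55.40 (15.76); CCI sums from normals
  truncated at the SMC threshold — 13.56 (1.23) on [12, 15] for SMC−,
  22.60 (6.94) on [16, 60] for SMC+; class-specific tau SUVR normals
  1.42/1.42/1.49/1.45 (SD 0.13/0.13/0.28/0.13) truncated below at 0.5
  (SUVRs are positive ratios); class-specific amyloid positivity
  probabilities 26.3/37.9/40.0/33.3%.
* **Label enforcement by rejection**: for each participant a 9-dimensional
  z-profile is drawn from an equicorrelated normal (pairwise r = 0.3,
  implemented via a shared latent cognition factor in the reference sample),
  realized as raw scores, re-standardized with the fitted norms, and
  re-classified with the real classifier; the draw is accepted only when the
  classifier reproduces the latent Obj-SCD label (and no accidental MCI).
  This guarantees exact generator/classifier round-trip through every
  rounding and clipping step, and doubles as a continuous stress test of the
  classifier.  The cap is 10,000 attempts per participant; typical
  acceptance needs ~2 draws.
* **AVLT back-solving**: trial 1 is drawn near the typical first-trial
  recall (≈5.5 words), trial 5 set to hit the target learning slope,
  trial 6 = round(RI·trial 5), intrusions spread multinomially over the
  seven recall trials; trials 2–4 are cosmetic interpolations.  This is a
  data-plumbing convenience so that trial-level records are arithmetically
  consistent with the drawn process scores.
* **Streams**: participant *i* draws from `default_rng([seed, 0, i])`, so
  growing n never reshuffles earlier participants; the reference sample uses
  a separate substream.
* **Truncation bias**: the pulse-pressure floor is set at 5 mmHg (only
  needed to keep systolic > diastolic) so the truncation bias on the mean is
  well below one standard error at n = 10,000, where marginal calibration is
  asserted within 3.5 SE.

### What the generator does not emulate

Real cohorts have right-skewed tau SUVR distributions; the generator draws
truncated normals with the configured means/SDs, so its tau-positivity
*rates* (share above 1.51) exceed those observed in skewed real data with
the same mean and SD.  Passing tests therefore demonstrate correctness of
the classification and statistical machinery and calibration of the
configured moments — not distributional realism of PET data, nor the true
dependence structure between self-report, cognition and tau, which is
encoded as independence except where class means differ.

## Problem sizes used in the test suite

Reference samples of 600–2,000 for normative fits (coefficient recovery is
judged against the analytic sampling SE, since high-noise measures like
Trail Making B have coefficient SEs near 0.1 at n = 2,000); cohorts of
n = 236 for label-recovery runs over 10 seeds; one n = 10,000 cohort for
marginal calibration; 10,000 replicates for the chi-squared type-I check;
12 replicates of the full pipeline for the qualitative effect-size ordering
(Obj-SCD tau contrast > SMC tau contrast on average).

## Known limitations

* The regression-normative scheme is this package's documented choice; other
  actuarial pipelines may use different reference samples or stratified
  norms, so absolute classification rates are comparable only when the same
  norms are used.
* The MCI rule implements the two-impaired-totals-within-a-domain pattern
  only; consensus-diagnosis or functional-impairment variants are out of
  scope.
* Centiloid coefficients must be supplied by the user for substantive use.
* Pairwise contrasts are intentionally uncorrected; users testing many
  contrasts should apply their own multiplicity policy.
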