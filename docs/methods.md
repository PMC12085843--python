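# Methods

`gidiet` implements a prospective gene–diet survival analysis for
gastrointestinal (GI) cancer — esophageal (EC), gastric (GC) and colorectal
(CRC) — together with a synthetic cohort generator that supplies data with
the statistical structure the analysis assumes. This note documents the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic data can and cannot demonstrate.

## Exposures

### Dietary index for gut microbiota (DI-GM)

Habitual intake is the arithmetic mean over a participant's available
24-hour recalls. The index sums binary component scores over a component
registry:

- **default** (13 components): beneficial — avocado, broccoli, coffee,
  cranberries, fermented dairy, fiber, green tea, soybean, whole grains;
  adverse — high-fat diet, red meat, processed meat, refined grains. The
  chickpea component of the originally proposed 14-item index is absent
  because the emulated data source does not record chickpea-specific
  consumption.
- **pulses** (14): broader pulses intake substituted for chickpeas.
- **no_cranberries** (12): cranberries dropped (dried-fruit types not
  distinguished at source).

Scoring: beneficial components earn 1 point when mean consumption is **at
or above** the sex-specific population median (ties take the ≥ branch, as
the rule is stated); adverse components earn 1 point when **below** it. The
high-fat-diet component alone uses a fixed cutoff — 1 point when less than
40% of energy comes from fat — because it is defined as a cutoff, not a
median split. Medians are plain empirical medians (midpoint of the two
central order statistics for even counts); no interpolated quantile
definition is used, so scoring is exactly reproducible. Medians and the
standardization mean/SD are learned on the analytic (post-exclusion)
population by `DietaryIndexScorer.fit`; whether the original analysis
computed medians before or after exclusions is not documented, and fitting
the scorer on a different table is the supported alternative.

Totals are grouped low (0–4), moderate (5–6), high (≥ 7), and standardized
per SD of the fitted population.

### Composite polygenic risk score (CPRS)

Per-cancer scores are weighted dosage sums `PRS_i = Σ_k β_k · dosage_ik`
over fixed genome-wide-significant SNP panels (no clumping/thresholding:
scoring reduces to the stated weighted sum). The composite is
`CPRS_i = Σ_k h_k · PRS*_ik`, where `h_k` is the age-standardized incidence
of cancer k and `PRS*` is the z-standardized per-cancer score.
Standardize-first is the default because raw PRS scales depend on panel
size and effect-size distribution; weighting raw sums would let scale
artifacts, not incidence, dominate the composite. Setting
`standardize_first=False` recovers the literal weighted sum of raw scores.
The shipped `h` values (EC 14, GC 11, CRC 70 per 100,000 person-years) are
illustrative round UK-scale incidence figures, supplied through
configuration — the composite's quintile grouping is invariant to their
common scale. Risk groups: lowest CPRS quintile = low, quintiles 2–4 =
moderate, top quintile = high; quantile cutpoints are empirical with ties
assigned to the lower group (right-closed intervals), which makes
assignment deterministic and order-invariant.

## Cohort construction

Sequential exclusions, each participant counted at the first matching rule:
prevalent cancer at baseline → implausible mean energy intake (strictly
below 800 or above 5000 kcal/day for males; 500/4000 for females; the
boundary itself is retained) → withdrawal → unusable genetic data. Energy
plausibility is evaluated on the mean across recalls — the
exposure-relevant quantity. Permuting the rule order changes per-reason
counts but never the retained set.

Covariates: age, sex, BMI (= weight kg / height m²), total energy intake,
income, education, Townsend deprivation index, smoking, alcohol, physical
activity, family history of cancer. Missing continuous values are
mean-imputed; missing categorical values become an explicit
`unknown/missing` level; an imputation flag supports the
complete-covariate sensitivity analysis. Energy is stored in kcal/day and
converted at 4.184 kJ/kcal only for display.

Follow-up runs from baseline to the earliest of first GI diagnosis
(ICD-10 C15 → EC, C16 → GC, C18–C20 → CRC), death from any cause, or the
administrative end of follow-up (default 2022-05-31); years = days/365.25.
Site-specific analyses are cause-specific: other-site GI cancers and death
are censoring events at their dates (no competing-risks decomposition —
the per-site hazard ratios are cause-specific by construction).

Five sensitivity variants: pulses registry, cranberry-free registry, a
2-year landmark excluding early events (reverse-causality guard),
multi-recall-only (≥ 2 recalls, thresholds re-learned on the survivors),
and complete-covariate-only.

## Statistical models

All association models are multivariable Cox proportional-hazards fits
(lifelines; Efron tie handling; Wald 95% CIs), adjusted for the covariate
set above. Exposures enter either categorically (low group as reference)
or per SD. Numerical safeguards: constant or collinear design columns
raise an error naming the columns rather than being dropped silently; an
optional small ridge penalizer (used only by the orchestrated pipeline,
0.005) stabilizes Newton steps when rare covariate levels carry very few
events and is negligible at cohort scale.

- **Proportional hazards**: scaled-Schoenfeld score test per term
  (Kaplan–Meier time transform by default; identity/rank/log available).
  The global statistic sums per-term chi-squares with summed df, which
  reduces exactly to the single test in one-term models.
- **Trend**: the ordered group variable recoded as integer scores 0,1,2 in
  the same adjusted model; the Wald p is invariant to affine rescoring.
  Median-of-group scoring is available as an option.
- **Dose–response**: restricted cubic splines in Harrell's truncated-power
  parameterization with 4 knots at the 5th/35th/65th/95th exposure
  percentiles; linear beyond the boundary knots, continuous second
  derivatives. Nonlinearity is a likelihood-ratio test of the nonlinear
  basis columns against the linear-only model (df = knots − 2). The
  hazard-ratio curve is referenced to the exposure median (HR = 1 there)
  with pointwise Wald bands from the basis-contrast covariance.
- **Subgroups**: per-stratum refits (strata without events are skipped
  with a warning) plus a pooled exposure×stratum product-term
  likelihood-ratio test for heterogeneity.

### Joint classification and interaction

The 9-cell DI-GM × genetic-risk factor uses **low diet / high genetic
risk** as the reference. Additive interaction for a chosen 2×2 corner of
the grid (defaults: doubly-favorable `high:low`, diet-only `high:high`,
genetics-only `low:low`; configurable and logged) is quantified on the
hazard-ratio scale, treating HRs as rate-ratio analogues — standard
practice for cohort Cox models:

    RERI = HR11 − HR10 − HR01 + 1        AP = RERI / HR11

with delta-method standard errors propagating the fitted covariance of
(log HR11, log HR10, log HR01) through each functional's gradient, and
95% CIs as estimate ± 1.96·SE. `compute_reri_ap` consumes only the fitted
model object and never refits. When both exposures are protective relative
to the reference and the joint cell sits below the additive expectation,
RERI is negative. Note that AP = RERI/HR11 (attributable proportion in the
doubly-exposed cell) is the conventional definition; published analyses
occasionally report AP values that cannot be reconciled with their RERI
under this formula, so the definition here is explicit and fixed.
Multiplicative interaction is a likelihood-ratio test of product terms —
by default the single product of integer-scored group levels (1 df); the
full dummy-by-dummy factor product (4 df for two 3-level factors) is
available.

## Synthetic cohort generator

The generator emulates a UK-style prospective cohort so every stage is
testable without restricted data. One global seed drives independent
per-stage substreams (`default_rng([seed, stage])`); identical
configurations reproduce byte-identical tables.

- **Registry**: ~54% female; age ≈ N(56.5, 8) years; baseline dates over
  2006–2010; covariate distributions shaped like a UK cohort's baseline
  table, with planted missingness in both continuous (Townsend) and
  categorical fields. Exclusion flags are planted on mutually disjoint
  sets with exactly the configured counts, so the cascade recovers each
  count exactly; the `paper-scale` scenario plants the documented
  full-scale counts (17,502 / 1,795 / 65 / 3,621 of 201,131).
- **Intake**: 1–5 recalls per participant (probabilities 0.35/0.25/0.20/
  0.12/0.08); component amounts are zero-inflated gamma — the standard
  shape for semicontinuous single-day food records — with a lognormal
  participant-level habit multiplier and sex-specific location shifts.
  Consumer fractions are chosen so component medians are positive and the
  three diet groups and all nine joint cells are populated; a median of
  zero would award that component's point to everyone (a real hazard of
  median-split scoring that the degenerate-distribution tests exercise
  deliberately). Total energy is normal around sex-specific means with
  per-recall lognormal variation; fat energy is a Beta fraction of total
  (mean 0.33), so fat energy never exceeds total. Implausible-energy
  plants rescale a participant's whole record outside the sex-specific
  band (preserving fat-fraction consistency); all other records are kept
  inside the band so the planted count is recovered exactly.
- **Genotypes**: independent loci, dosage ~ Binomial(2, MAF) with MAF ~
  U(0.05, 0.5); panels of 50/30/125 SNPs for EC/GC/CRC (205 total) with
  small per-allele log-scale effects of either sign. No linkage structure,
  genotyping error or imputation uncertainty is modeled.
- **Outcomes**: Weibull proportional hazards, cumulative baseline hazard
  (t/scale)^shape, log hazard linear in the standardized exposures with an
  optional planted product term. Defaults: shape 1.1, scale 600 years
  (≈1.5% cumulative incidence over the follow-up window, matching the
  emulated study's event rate), per-SD log-HRs −0.05 (diet) and +0.39
  (genetics), no interaction. Censoring: exponential all-cause death
  (0.004/year) and the administrative calendar date. Event sites are
  multinomial with probabilities proportional to the incidence weights,
  independent of which per-cancer PRS is elevated — this keeps the base
  simulator simple; site-specific power studies can planted-couple sites
  by running per-site configurations.

### What passing tests do and do not show

The generator plants exactly the model the analysis fits (proportional
hazards, linear per-SD effects, independent censoring, no confounding
between exposures and covariates). Passing recovery and calibration tests
therefore demonstrates the correctness of the estimation machinery — not
robustness to confounding, measurement error, linkage disequilibrium,
competing risks, or model misspecification in real cohort data.

## Verification design and problem sizes

- Scoring and PRS computations are checked exactly against independent
  per-participant loop oracles; medians against sort-and-pick.
- The spline basis is verified against its defining properties (linear
  tails, interior curvature) and against an independent natural-spline
  construction (identical Cox log-likelihood on the same knots).
- Delta-method SEs are checked against a 2,000-draw parametric bootstrap
  from the fitted coefficient covariance (within 10% relative error).
- Calibration suites: planted per-SD log-HR recovery over 200 replicates
  of n = 20,000 at ≈15% event rate (95% CI coverage ≥ 90% required for
  each exposure); RERI under an exactly additive null over 500 replicates
  of n = 2,000 in a 2×2 design (mean within 3 Monte-Carlo SEs of 0; CI
  coverage within 93–97%); multiplicative LRT type-I error over 200
  replicates (within [0.03, 0.07] at α = 0.05); spline nonlinearity
  p-values uniform under a linear truth over 200 replicates (KS test).
  Replicate sample sizes were chosen as the smallest at which the Wald
  and likelihood-ratio asymptotics these checks rely on are comfortably
  valid (several hundred events per fit).

## Known limitations

- Effect-allele harmonization between dosage and weights tables is a
  string match; strand flips and allele recoding are out of scope.
- The global proportional-hazards statistic assumes approximately
  independent per-term score tests.
- Site assignment in the simulator is independent of the site-specific
  PRSs by default, so cross-site discrimination power cannot be studied
  without per-site configurations.
- Death is treated as independent censoring everywhere; no Fine–Gray
  subdistribution hazards.
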