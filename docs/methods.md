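# Methods

This note documents the models, rules and numerical choices behind the
package, and what the synthetic data do and do not establish.

## Study design being implemented

A population-based matched cohort: prevalent users of blood-pressure-,
lipid- or glucose-lowering agents at an index date (2017-01-01) are
split into an exposed cohort (severe mental illness in active care at
index: an open registry episode of depression, schizophrenia, bipolar
disorder or personality disorder) and a reference pool (no
mental-health registry record at all). Each exposed patient receives
up to three comparators matched on gender, age at index (± 1 year) and
contact volume with the health service in the two pre-index years.
Outcomes over the one-year follow-up are high drug adherence
(PDC ≥ 75%) and, for the glucose cohort, high adherence to the
diabetes clinical-control bundle (≥ 4 of 5 recommendations).
Association is estimated by exact conditional logistic regression on
the matched sets and presented as (OR − 1) × 100. The three
drug-class cohorts are built independently; a patient on several
therapies may appear in several cohorts (never twice within one).

## Drug eras and prevalent use

* Duration of a dispensation = dispensed amount ÷ defined daily dose.
  Durations are floored to whole days at ingestion, so era chaining,
  gap comparisons and covered-day counts are exact integer-day
  arithmetic; this makes the interval algebra provably equivalent to a
  one-day-at-a-time supply-counter simulation, which the tests exploit
  as an oracle. The sub-day remainder a fractional DDD amount loses is
  at most one day per dispensation.
* Stockpiling: a refill dispensed before the current supply is
  exhausted extends the coverage end by its full duration. Coverage
  intervals are half-open `[start, end)`; a dispensation exactly
  `gap_days` (default 60) after a coverage end still chains.
* Prevalent user: some single era contains ≥ 3 dispensations all dated
  in `[index − 730 d, index)`. Whether the chain must also still be
  active at the index is genuinely ambiguous; the default is
  existence-only (the literal reading), with
  `EraConfig.require_active_at_index` restoring the stricter variant
  (coverage end within `gap_days` of the index).

## PDC measurement

* Denominator fixed at 365 days: patients dying or emigrating within
  follow-up are excluded upstream, so no censoring arises.
* Numerator: union of coverage days and bridged hospital days,
  intersected with the window. Supply dispensed before the window that
  spills into it counts by default (`include_spillover`); the cohort
  consists of prevalent users, so pre-index supply is part of the
  regimen being measured.
* Hospital bridging (immeasurable time): a stay is counted as covered
  when the patient had **any** era of the class starting before the
  admission (permissive reading of "regimen observed before
  admission"); `AdherenceConfig.bridging = "overlapping_era"` requires
  an era whose span contains the admission date instead. Bridging can
  only add days, never remove them.
* Categories on the continuous scale: very low `pdc ≤ 0.25`, low
  `(0.25, 0.50]`, intermediate `(0.50, 0.75)`, high `pdc ≥ 0.75`; the
  published integer-percent labels (26–50 etc.) are read as interval
  shorthand. High-adherence flags at 70/75/80% are computed in integer
  arithmetic (`covered × 100 ≥ t × 365`), so threshold comparisons are
  exact.
* Clinical controls: HbA1c satisfied with ≥ 2 assays in the year, the
  other four (lipid profile — any of total/HDL cholesterol or
  triglycerides counts as the one recommendation — serum creatinine,
  urine albumin, eye exam) with ≥ 1. Service-code → control mapping is
  configuration, not hard-coded vocabulary; codes mapped to `None` are
  recognised non-controls, unmapped codes are skipped with a warning.

## Cohort construction

* Eligibility screen, in order: birth date present; age ≥ 18;
  residency started ≥ 730 days before index; prevalent user of the
  class; no death/emigration within 365 days post-index. Each record
  is charged to the first criterion it fails, so the flow ledger
  reconciles exactly (input = retained + Σ removals).
* Contact volume = pre-index dispensations + hospital admissions +
  out-patient services in the 2-year lookback, recounted from the raw
  tables (the generator's precomputed column exists only so the
  recount can be verified).
* Matching: exposed patients processed in seeded random order;
  comparators drawn without replacement from same gender, age ± 1
  year, same decile of the pool's contact distribution. Decile
  equality is this package's choice — the tolerance for "matched on
  number of contacts" is not published; a caliper variant and an
  unconstrained variant are exposed in `MatchingConfig`. Sets with one
  or two comparators are retained ("up to three"); exposed patients
  with no eligible comparator are dropped and logged.
* Concurrent open psychiatric episodes are resolved by a fixed
  severity order (schizophrenia > bipolar > personality disorder >
  depression) — a package convention where the source design is
  silent.
* The Multisource Comorbidity Score is treated as a supplied numeric
  score binned at configurable cut-points (default 1/3/5) into
  clinical-profile categories; a score exactly at a cut-point falls in
  the lower category. The score's internal weighting scheme is out of
  scope.

## Conditional logistic regression

* Exact conditional likelihood with full subset enumeration per set
  (set sizes ≤ 1 + ratio, so at most C(4,2) = 6 terms); no
  Breslow/Efron tie approximation is ever needed.
* Newton–Raphson from β = 0, step-halving on likelihood decrease,
  convergence at gradient max-norm < 1e-8, max 100 iterations.
  Standard errors from the inverse observed information; Wald 95% CIs
  on the log-odds scale mapped through exp and then x ↦ (x − 1) × 100.
* Degenerate inputs: concordant sets are dropped (logged and counted);
  covariates with zero within-set variance are dropped because the
  conditional likelihood is invariant to them; an exposure with no
  within-set contrast raises an error, as does separation (detected by
  |β| exceeding 15 — an OR above 3 × 10⁶ — or a singular information
  matrix), naming the offending covariate.
* Stratified analyses refit per stratum, the stratum of a set being
  the exposed member's label. Homogeneity across strata: inverse-
  variance Q on K−1 df. Trend along ordered strata: inverse-variance-
  weighted regression of stratum log-ORs on category scores with a
  Wald test of the slope (the "recoded variable" description admits
  several readings; meta-regression of stratum estimates is the one
  implemented). Two independent trend slopes are compared with a
  z-test. Significance is 0.05 throughout, no multiplicity correction.

## Synthetic claims generator

The generator emulates the registry schema (demographics with
death/emigration, dispensations in DDD units, hospital stays,
out-patient services, mental-health episodes) with the statistical
features the pipeline must confront, not the full richness of real
claims:

* Exposure prevalence ≈ 2% by default, confounded with gender, age and
  contact volume through a shared set of log-odds contributions
  (defaults −0.2 female, +0.15 per decade, +0.30 per unit
  log-contacts), so crude and conditional contrasts differ and
  matching has real work to do.
* Latent adherence: logit p = logit(baseline 0.5) + β·SMI +
  confounder terms, with β = `true_log_or` the planted conditional
  log-OR. The latent draw is expressed through the same era machinery
  the pipeline tests: a target covered fraction is drawn from a
  category-conditional Beta mixture (high: 0.75 + 0.25·Beta(2,2);
  otherwise 0.74·Beta(1.3,1.3)) and realised as 30-DDD packs tiling
  the follow-up, so measured PDC ≥ 0.75 if and only if the latent draw
  was "high". Where a hospital stay would bridge a borderline
  non-high patient over the threshold, the pack count is shrunk so the
  measured outcome still expresses the latent draw.
* Everyone carries a four-pack pre-index chain ending at the index
  (2% only two packs, failing the prevalent-user rule); fixed small
  fractions of minors (0.5%), short residency (0.5%), death/emigration
  in follow-up (2% default) and closed historical psychiatric episodes
  (1% of unexposed) exercise every exclusion path.
* Diabetics receive the five control services from an analogous latent
  propensity with its own planted log-OR for the ≥ 4-of-5 outcome;
  satisfied controls emit exactly qualifying counts (HbA1c ≥ 2 etc.).
* Contact volume is negative-binomial (mean ≈ 24 visits over two
  years) plus admissions and pre-index dispensations; cotreatment
  flags (NSAID, antithrombotic) and a Poisson comorbidity score depend
  on demographics only, so their imbalance across cohorts flows
  entirely through the shared confounders.
* Identical config + seed reproduce the tables byte for byte; all
  draws are vectorised from one `numpy` Generator.

What the generator does **not** emulate: real ATC/ICD vocabularies,
dose titration and switching, seasonal dispensing, informative
hospitalisation or death, socioeconomic gradients, regional variation.
Passing recovery tests therefore establish that the *pipeline*
measures and estimates correctly under the declared model — not that
the model captures every bias structure of real claims data.

## Problem sizes and published-value recovery

The reference estimates this package is checked against are the
study's adjusted percentage variations: −24% (blood-pressure-), −10%
(lipid-), −25% (glucose-lowering) and −18% (diabetes controls). The
acceptance script plants the corresponding ORs as ground truth and
recovers them through the full pipeline over ~20 000 matched sets per
drug class (~10 000 for the control bundle). Because the conditional
estimand does not depend on exposure prevalence, the recovery
scenarios oversample exposure (20% instead of 2%) so those set counts
arise from ~10⁵ simulated patients instead of ~10⁶; at that size the
Monte-Carlo SE of the recovered percentage is ≈ 1.3 points (≈ 1.9 for
the control bundle). The test suite runs the same recovery at a
quarter of the size, averaged over four replicate cohorts, and
compares against the planted value at 2 Monte-Carlo standard errors;
a 500-replicate null study checks the Wald test's 5% size.

## Known limitations

* Era durations ignore prescribed daily dose adjustments; class-level
  pooling only (no within-class switching logic).
* Wald intervals only (profile likelihood not implemented); exact
  conditional inference is used for estimation, not for p-values.
* The trend test treats stratum estimates as independent, which
  matched-variable strata are; for non-matched stratifiers residual
  cross-stratum correlation is ignored.
* Matching uses decile equality for contacts; with very skewed contact
  distributions the top decile is wide, and residual within-decile
  confounding — while negligible under default effect sizes — is not
  exactly zero.
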