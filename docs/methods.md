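# Methods

This note documents the statistical procedures `mspanel` implements,
the synthetic-cohort model used to validate them, the numerical
choices, and the limits of what the package's passing tests show.

## The analysis pipeline

### Preprocessing

Measurements arrive as a long table of (subject, analyte, compartment)
concentrations with two distinct non-value states: *missing* (the
assay was not run or sample was exhausted) and *below LOD* (the assay
ran but the analyte was not quantifiable). The pipeline order is
fixed and enforced at run time:

1. **Detectability filter.** An (analyte, compartment) pair is dropped
   when fewer than `min_detect_frac` (default 0.5) of its measurements
   are non-missing and above the LOD. The filter is per compartment:
   an analyte unusable in CSF can survive in serum.
2. **Half-LOD imputation.** Each below-LOD cell is set to 0.5 × the
   minimum detectable value. By default that minimum is the smallest
   *observed above-LOD* concentration of the analyte in the cohort —
   reproducible from the data alone — and an explicit per-assay LOD
   supplied in config takes precedence.
3. **CSF total-protein adjustment.** Every CSF concentration is
   divided by the subject's CSF total protein (mg/mL), expressing CSF
   analytes per unit total protein so that between-group differences
   in blood–brain-barrier permeability do not masquerade as analyte
   effects. The operation refuses to run twice and can be switched
   off. Subjects with CSF data but no protein value have their CSF
   cells set missing (logged), not silently kept.
4. **Z-standardisation.** Per analyte, Z = (x − mean)/SD with the mean
   and sample SD (n−1) pooled over *all* valid data from both groups,
   so model coefficients are directly comparable across analytes.
   Constant analytes are dropped with an explicit reason.
5. **Control-anchored residualisation (sensitivity analysis).** Per
   analyte, OLS `Z ~ intercept + age + sex` is fitted on controls only
   (sex coded F=0, M=1) and the fitted values are subtracted from all
   subjects, removing the physiological age/sex component so that
   remaining variation reflects disease. It operates on Z-scores, not
   raw concentrations, so downstream models keep their scale; the raw
   order would differ only by the per-analyte affine transform.

### Univariate screen

Each retained pair is compared between groups with a two-sided
Mann–Whitney test. The exact null distribution is used when
n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections; a statistic exactly
at the null centre n₁n₂/2 reports p = 1 by symmetry. Fold changes are
ratios of group medians on the post-imputation concentration scale —
medians, because the test is rank-based and medians are the matching
location summary. BH correction is applied within each compartment by
default (the two compartments' hit lists are reported separately); a
pooled option exists. A Fisher-exact missingness check per analyte
guards the MCAR assumption the complete-case models rely on.

### Diagnostic combination search

Candidate models are logistic regressions of case status on a marker
subset's Z-scores with age and sex always included. Fitting is IRLS
(Newton) to tolerance 1e-8, at most 100 iterations. On
quasi-separation — non-convergence or runaway coefficients — the fit
falls back to a small ridge penalty (λ = 1e-4, intercept unpenalised)
and flags a warning rather than failing: small CV folds with strong
markers separate routinely and a finite scorer remains well defined.

Subjects are partitioned into k = 4 folds, stratified by case status,
by a seeded RNG. Each candidate subset is scored on its complete
cases (subjects with every subset marker non-missing — hence the
per-model N): for each fold, fit on the other three, record AUC on the
fitting set and on the held-out fold, and average. AUC uses the
Mann–Whitney identity with tied pairs counted ½.

Search strategies: `exhaustive` (every subset, refused beyond 2²²),
`per_size_exhaustive` (every subset of each size up to `max_size`,
default 8) and `greedy_forward` (forward stepwise). Ties break toward
smaller panels, then lexicographic marker names, so reports are
deterministic. Selection walks sizes from 1 and stops at the first
size whose best successor gains less than Δ = 0.01 mean test AUC.
The combined CSF+serum search draws its candidate pool from the union
of the separately selected CSF and serum panels by default.

Stability: the selected panel is refitted on `n_reps` = 1000 random
stratified splits at 75% train, recording the AUC on the train part
(used as test) and on the held-out 25%, summarised by mean, SD and
percentiles.

### Prognostic combination search

Two outcomes per MS subject, both measured from the sampling date:

* **Time to next relapse.** Event at the first relapse if it precedes
  both DMT start and end of follow-up; otherwise censored at
  whichever of those comes first, with the censor reason recorded.
  DMT censoring exists because therapy suppresses relapses.
* **Time to sustained EDSS 6.** EDSS readings within 30 days after a
  relapse are discarded (transient disability). An eligible reading
  ≥ 6 is the event when no later eligible reading within the 6-month
  sustain window drops below 6 and either the first eligible reading
  at ≥ 6 months later confirms (≥ 6), or follow-up extends at least 6
  months further with no dissenting reading. Subjects already at
  EDSS ≥ 6 at sampling are excluded; subjects with no eligible
  readings are flagged degenerate.

Cox models are fitted by lifelines (Efron tie handling) with age and
sex — plus ever-DMT for the disability outcome — forced into every
model. The reported model p-value is the likelihood-ratio test
against the covariates-only model on the same subjects (χ², df =
number of markers). Cross-validated scoring applies the train-fold
coefficients to the test fold and computes Harrell's C: over pairs
where the strictly shorter time ends in an event, the fraction in
which the shorter-time subject has the higher linear predictor, risk
ties ½, tied-time pairs omitted. An apparent (whole-data) concordance
mode exists for comparison with in-sample statistics, which are
optimistically biased (≈ 0.52 at n = 150 even for a pure-noise marker)
and therefore never used for calibration claims. Subset enumeration,
tie-breaking and the Δ rule are shared with the diagnostic search.

## The synthetic cohort model

The generator emulates the cohort structure the pipeline targets:

* 80 controls / 77 MS; ages normal-truncated above 18 years with the
  location recentred so the *truncated* group means equal the
  configured 33.2 (SD 10.2) and 41.9 (SD 12.4) years; 90% / 60%
  female.
* 20 CSF + 24 serum analytes, log-normal: log-concentration =
  log-mean + log(fold)·1{MS} + log-SD·Zₗ, with latent Z drawn
  multivariate normal under an exchangeable (default ρ = 0.2) or block
  correlation. Default planted folds mirror the study's largest
  effects (CSF 4.1 / 3.4 / 2.6; serum 1.6 / 1.54) with smaller shifts
  elsewhere; one analyte per compartment is shifted downward. LODs
  sit 1.8 log-SDs below the control log-mean (a few percent censored);
  cells are deleted completely at random at rate 0.05, matching the
  reported absence of differential missingness.
* CSF total protein is log-normal (median 0.35 mg/mL, log-SD 0.25),
  independent of group, so the adjustment step divides by a
  group-neutral denominator.
* Outcomes: relapses are a Poisson process with rate
  0.18·exp(Σβ·Zₗ)/year; the latent first-passage time to sustained
  EDSS 6 is exponential with rate 0.045·exp(Σβ·Zₗ)/year. Follow-up is
  truncated-normal (7.9, SD 3.5, capped at 15 years). DMT starts with
  probability 0.6 at an exponential (mean 2 y) time within follow-up.
  4/77 MS subjects start at EDSS ≥ 6 (excluded downstream). EDSS
  visits are annual, random-walking on the half-point scale below 6
  until the passage time, then sustained ≥ 6. The baseline rates put
  the expected event counts near the study's (≈ 36 pre-DMT relapses,
  ≈ 19 disability events).

Two derived scenarios fix their parameters once:

* `null_scenario` — all folds 1.0, all β = 0, ρ = 0. Independence
  (ρ = 0) is part of the design: it makes the per-analyte rejection
  indicators independent so the binomial SE used by the calibration
  checks is exact. The age/sex group imbalance is retained — it is
  cohort structure, not a planted effect — which is why null
  calibration of model AUC uses marker-only models.
* `recovery_scenario` — ten independent CSF markers, two with fold
  2.0 at log-SD 0.5 (≈ 1.4 SD shift each, sized so each addition
  clears the Δ = 0.01 gain over the ≈ 0.77 age+sex baseline AUC), one
  with relapse log-hazard 1.0 per Z, seven noise.

What the generator does **not** emulate: assay chemistry, plate or
batch effects, inter-assay CV, longitudinal biomarker trajectories,
informative missingness, non-proportional hazards, competing risks,
or realistic analyte-specific correlation structure (the study
reports none, so ρ is an explicit config choice, not an inference).
Passing recovery tests therefore demonstrate that the *procedure*
finds planted effects of the stated size under clean distributional
assumptions — not that it would on real assay data with batch
structure or heavier tails.

## Numerical choices and edge cases

* All randomness flows from `numpy.random.default_rng`; the CLI
  derives per-stage seeds from one root seed via `SeedSequence`, so a
  run is reproducible from its manifest alone.
* Logistic and Cox tolerances are 1e-8; ridge fallback λ = 1e-4.
* Fold assignment uses `array_split` within strata, so 157 subjects
  split 40/39/39/39 with each fold carrying 20 ± 1 controls and
  19 ± 1 MS cases.
* A fold whose test part lacks a class (or has no events) invalidates
  that combination's score rather than being silently skipped;
  stability reps with a degenerate split are skipped and counted.
* `select_optimum` is monotone: a larger Δ never selects a larger
  panel (property-tested).
* Constant analytes, zero-event outcomes, single-sex control cohorts,
  non-positive total protein, and duplicate measurement keys all fail
  loudly with the offending analyte/subject named.

## Validation problem sizes

The test suite and acceptance script size their simulations for a
quick desk run while keeping Monte-Carlo error well inside the
asserted tolerances: 200 (tests) / 100 (script) replicate null
cohorts for calibration; 6 replicates at n = 4000 for the closed-form
AUC limit; 50 (tests) / 25 (script) planted-signal cohorts for
procedure recovery with `per_size_exhaustive` to size 4 on the
diagnostic side and `greedy_forward` to size 3 on the Cox side;
n = 5000 / 2000 single fits for logistic and Cox parameter recovery.
The planted-panel recovery rate sits near its 90% design point: the
misses are genuine Δ-rule stops at size 1 when four-fold CV noise
swallows the second marker's ≈ 0.05 population AUC gain — an inherent
property of a greedy stopping rule at n = 157, and the reason the
stability rerun exists.

## Known limitations

* "All combinations" over 44 markers is computationally untenable;
  the default orchestrated pipeline therefore uses forward selection,
  with per-size exhaustive enumeration available (and the library
  default) for pools where it is feasible.
* Harrell's C omits tied-time pairs entirely (the strictly-shorter
  definition); implementations that count event/censored ties at equal
  times will differ in the third decimal on heavily tied data.
* The EDSS-6 sustainment rule requires positive evidence (a confirming
  visit or ≥ 6 months of dissent-free follow-up); sparser visit
  schedules than the annual default will censor more aggressively.
* Complete-case analysis is only unbiased under MCAR; the missingness
  check tests that assumption but cannot rescue violations.
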