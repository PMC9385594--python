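# Methods

## The design

Occupational cohorts have unusual risk profiles: fewer smokers than the
general population, the healthy-worker effect, and a mix of non-WTC
occupational exposures. A registry-based standardized incidence ratio
therefore confounds the exposure of interest with the cohort's composition.
The design implemented here replaces the external referent with a
*microsimulated replica* of the cohort: every participant is duplicated
with their own covariates and their own follow-up time, and the replica's
lung-cancer hazard is generated from a published individual risk model that
knows nothing of WTC or occupational exposure. The observed incidence rate
is then compared with the replica's expected rate as an incidence rate
ratio (IRR). An IRR of 1 means the cohort's lung-cancer experience is fully
explained by its measured risk-factor profile.

## Cohort model and person-time

Entry into the analytic cohort is deferred by three months after
enrollment, and cancers dated before entry are excluded as prevalent
disease: joining a surveillance program is often triggered by symptoms, so
immediate diagnoses are not incident. "Three months" is implemented as
exactly 0.25 Julian years (91.3125 days); the source material states no
calendar convention and a fixed fraction keeps person-time arithmetic exact.
Person-time runs from entry to the last clinical encounter — the literal
reading of the accrual rule, under which cases keep accruing time after
diagnosis. An `end_at_diagnosis` switch truncates case time at diagnosis;
this is the correct exponential-likelihood treatment for parameter-recovery
experiments and is used there, while the default preserves the matched
denominator of the comparator design.

Derived covariates: smoking status uses the strict never-smoker rule
(fewer than 20 lifetime packs, or under one cigarette/day for at most a
year — equality at either threshold counts as a smoker); airway obstruction
is FEV1/FVC ≤ 0.70, with a 1e-9 relative tolerance at the boundary for
float representation. Note the source material is internally inconsistent
about this boundary (a table footnote says "< 0.7" while the methods text
says "0.70 or less"); the methods-text reading is implemented. Missing
spirometry is a distinct missing state, never coerced to "not obstructed",
and obstruction-adjusted models are complete-case.

## Risk model and microsimulation

The 6-year probability is a logistic model; the bundled `plco2012.yaml`
carries the PLCOm2012-family coefficients transcribed by the package
authors from the source publication (age, education on a 1–6 ordinal, BMI,
COPD, personal cancer history, family history of lung cancer, race/ethnicity
contrasts, current-smoker indicator, the inverse smoking-intensity transform
`(cigs/day ÷ 10)⁻¹`, smoking duration, quit-years; all centered as in the
source). The file embeds a SHA-256 checksum of the coefficient payload so
silent edits of the transcription fail loudly. A `toy.yaml` set with round
coefficients and a realistic overall event yield is used throughout the test
suite, which therefore never depends on the transcription.

Decisions where the source design was genuinely open:

- **Never smokers.** The source model was derived in ever-smokers and the
  comparator study does not say how never smokers were scored. Here all
  smoker-only terms contribute zero (reference level) for never smokers —
  the minimal literal extension. This is a convention, isolated behind the
  `smoker_only` term flag.
- **Education coding.** The cohort schema's five levels plus "unknown" map
  onto the model's 1–6 ordinal as lt_hs→1, hs_grad→2, some_college→4,
  college_grad→5, grad_school→6; "unknown" maps to the midpoint 3.
- **Sex.** The coefficient format permits a `female` term but the bundled
  transcription has none (the source model does not include sex).
- **Long follow-up.** The window construction stops at 18 years; follow-up
  beyond 216 months reuses the last window's monthly probability. With
  maximum observed follow-up near 17 years this is nearly moot.
- **Denominator.** Simulated events do not truncate person-time: the
  expected rate uses the same denominator as the observed rate, which is
  what "identical replica cohort" implies.

Time-updating advances age by 6 years per window; current smokers keep
smoking at the same intensity (duration grows), former smokers stay quit
(quit-time grows). The monthly conversion solves `(1 − p)⁷² = 1 − P`
(72 months per window), implemented with `expm1/log1p` so the identity
holds to 1e-12 across the probability range.

The engine draws each person's first-success month by inverse-CDF sampling
of the sequential-Bernoulli process (distributionally identical, vectorized
over a padded survival matrix). Thirty replicates use independently spawned
`SeedSequence` streams from one master seed. `analytic_expected` — the
exact expectation Σᵢ[1 − Πₘ(1 − pᵢₘ)] — serves as the engine's oracle in
tests.

## Rates and intervals

Crude rates use the Garwood exact Poisson interval (χ² quantiles at 2x and
2x + 2 degrees of freedom): it reproduces the published bounds, which a
normal approximation does not. The worked-number tests back-derive
person-years from rates printed to one decimal, which injects up to ±0.1
per 100,000 slack in the recomputed bounds; tests allow exactly that.

Direct age standardization uses the year-2000 US standard population,
bundled as an 11-band CSV (<1, 1–4, 5–14, …, 85+; census standard-million
weights). The comparator study does not state its banding; the 11-band
standard is the common default. All of a person's time is assigned to their
entry-age band (a simplification; with median follow-up ~11 years people do
cross bands). CIs use the Fay–Feuer gamma method. The published
age-standardized CI cannot be checked without the unpublished age-specific
case/person-time split.

The observed-vs-expected IRR treats the simulated expected count as a fixed
rounded count (default): on matched person-time the observed count given
the total is binomial, and a Clopper–Pearson interval transforms to the
odds = rate-ratio scale. The design leaves open whether simulation
replicate variance belongs in the interval; the Wald variant accepts a
`sim_rate_variance` to propagate it as a sensitivity mode.

Poisson regression is a GLM with log person-years offset (statsmodels
IRLS). The published coefficient-table coding is used: never smokers are
the implicit pack-years-0 reference, current smokers are distinguished by
pack-years with both former-quit dummies at 0, and former smokers add a
0–14 or 15+ years-quit dummy. Rank deficiency is reported with the
collinear column names; separation is flagged (|coef| > 15 or SE > 50)
rather than silently returned. Multiple imputation is simplified to m
independent stochastic imputations pooled by Rubin's rules (mean of
coefficients; total variance = within + (1 + 1/m)·between; t reference with
Rubin degrees of freedom) — not full chained equations, which the source
reports as making no substantive difference.

## Synthetic cohorts

The generator reproduces the published *marginals* of the responder cohort:
log-normal age (median 44, IQR 38–51) and BMI (29.1, 26.4–32.4) fitted by
matching the printed quantiles; categorical draws at the printed
race/education/smoking/WTC-level proportions; exponential pack-years with
mean 7.5/ln 2 ≈ 10.82 so the median matches the printed 7.5; independent
occupational-exposure flags at the printed prevalences; log-normal
follow-up (11.1, 6.3–14.3) capped at 17 years (the surveillance window);
enrollment uniform over 2002–2004; missingness injected at the printed
fractions (BMI 1.1%, pack-years 5% of smokers, education 3%). Family
history is entirely missing by construction, as in the real data.

Conventions the source does not constrain (documented, not tuned): smoking
is assumed to start at 18 and occupy a uniform 30–90% span of adult life,
with intensity back-computed from pack-years; quit-time for former smokers
is uniform on the remaining span; the smoking-dose block (pack-years,
intensity, duration) is missing jointly; spirometry missing for ~6.2% with
FEV1/FVC normal around 0.78 (SD 0.055), giving ~7% obstruction; prior
cancer at 3%. Joint covariate structure beyond these marginals is not
emulated — in particular the occupational flags are independent, so planted
single-exposure effects are unconfounded by construction. Passing tests
therefore demonstrate engine and estimator correctness under the stated
marginals, not robustness to the real cohort's correlation structure.

Planted hazards are constant per-person monthly probabilities
`baseline × exp(Σ log-IRR · x)` (baseline default 39.5e-5/12, matching the
observed crude rate), with the event month geometric and censoring at the
last encounter. `plant_outcomes_from_model` instead draws events directly
from a risk model's monthly schedules, making the generator's hazard equal
the comparator's exactly — the construction behind the end-to-end null
calibration.

## Problem sizes and tolerances

The test suite uses cohorts of 3,000–20,000 with 20–50 seed replicates for
coverage checks; these sizes give 30–250 events per cohort, enough that
95% CIs are informative while the full suite runs in well under a minute of
simulation time. Stochastic assertions use 3-standard-error bounds (or the
3-SD binomial bound for coverage counts, e.g. ≥ 18/20 and ≥ 43/50 at
nominal 95%). Exact assertions (conversion identity 1e-12, Garwood tail
probabilities, Rubin algebra) use direct numerical tolerances.

## Known limitations

- The comparator inherits whatever calibration error the risk model has;
  nothing here recalibrates it (the source reports the model overpredicting
  for former smokers, and the same would happen in this implementation).
- No competing mortality: the simulation generates lung cancer only, so
  long-horizon window probabilities are unconditioned on survival.
- Entry-age banding for standardization ignores aging across bands.
- The generator's independence assumptions make synthetic cohorts easier
  than real data for regression adjustment.
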