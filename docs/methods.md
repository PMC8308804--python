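# Methods

## The problem

Epidemiological findings about "ultra-processed food" (UPF) depend on which
food-processing taxonomy defines the exposure. `upfharmony` implements, as a
reusable pipeline, the comparison of four such systems on a single cohort:

* **NOVA** — extent and purpose of industrial processing; groups 1–4,
  UPF = group 4;
* **IARC/EPIC** — level of physical processing; groups 1–3, UPF = group 3;
* **IFIC** — complexity of processing and formulation; groups 1–5,
  UPF = groups 4–5;
* **UNC** — extent of physicochemical change; groups 1, 2, 3.1, 3.2, 4.1,
  4.2, UPF = groups 4.1–4.2.

Group codes are strings throughout so that dotted UNC subcodes and integer
codes are handled uniformly.

## Exposure construction

A 143-item semi-quantitative food-frequency questionnaire (FFQ) records,
per item, a frequency category (nine ordered options from "never or hardly
ever" to "more than six times a day") and a commonly used portion size.
Daily intake is `grams/day = portion_g × multiplier(category)`. The
instrument does not publish times-per-day multipliers, so the package uses
interval midpoints (0, 2/30.44, 1/7, 3/7, 5.5/7, 1, 2.5, 5, 6 per day), the
standard convention for semi-quantitative FFQs; they are replaceable via a
YAML `FrequencyScale`.

Per participant and system, the primary exposure is

```
UPF% = 100 × Σ UPF-group grams/day ÷ Σ classified grams/day
```

where "classified" means the items the taxonomy allocates in that system —
the same universe that defines the UPF group. The regression predictor is
`UPF% / 5`, a five-percentage-point increment. Two sensitivity exposures
are carried alongside: UPF grams/day per kilogram of body weight, and
calorie-adjusted UPF grams/day by the residual method (residual from the
OLS of UPF grams on total energy, re-centred at the cohort mean; the output
mean equals the input mean to ~1e-9 by construction).

Derived clinical quantities use the field's standard formulas: percent of
energy via Atwater factors (protein 4, carbohydrate 4, fat 9 kcal/g; energy
itself is taken from the composition table, so alcohol calories stay in the
denominator without being reconstructed); diet-level glycemic index
GI = GL × 100 / carbohydrate grams; Friedewald LDL = TC − HDL − TG/5,
undefined (NaN) above 400 mg/dL triglycerides; BMI = kg/m².

## The packaged allocation table

The item-by-item allocation of the source FFQ is not openly
redistributable, so the packaged table
(`data/taxonomy_synthetic.tsv`) is a **synthetic reconstruction** built to
the published structure: 136 records; per-system UPF item counts of 82
(IARC), 37 (NOVA) and 42 (IFIC and UNC); NOVA's UPF set strictly nested in
IARC's; IFIC's and UNC's UPF sets equal to NOVA's plus five dairy-style
divergence items each (four shared — UHT milks and natural yogurt); and the
documented single-item assumptions (UHT milk, industrially produced
custard/ice-cream/milkshake/cheese wedges, canned white asparagus, salted
pistachios, freshly baked bread, ground roasted coffee, …) recorded as
record notes, not executable logic.

The published item fractions — 60.7% (IARC), 27.4% (NOVA), 31.1% (IFIC and
UNC) — are not attainable over a denominator of 136 (82/136 = 60.3%,
83/136 = 61.0%) but match 82/135, 37/135 and 42/135 exactly. The package
therefore treats the realized denominator as **135 allocated items**: one
of the 136 records (mineral water) carries no group code in any system, and
`upf_item_fraction` divides by the records allocated in the queried system.
Loaders accept any user table with the same layout; the packaged fractions
are asserted only for the packaged table.

## Cohort rules and statistics

Inclusion drops participants with any missing cardiometabolic outcome
first, then implausible energy by sex (<500 or >3500 kcal/day for women,
<800 or >4000 for men), logging one reason per exclusion.

Quintiles of UPF% (Q1 lowest … Q5 highest) use linearly interpolated
empirical 20/40/60/80 percentiles; a value equal to a cut point falls to
the lower quintile. This rule is deterministic and permutation-equivariant;
all-equal inputs raise a degenerate-data error rather than returning
arbitrary labels.

Per-quintile profiles report mean (SD) per quintile with a classical
homoscedastic one-way ANOVA (constant input is reported as F = 0, p = 1),
plus Tukey HSD pairwise contrasts: estimate(Qi, Qj) = mean(Qi) − mean(Qj),
SE from the pooled within-group variance, and adjusted p from the
studentized-range distribution with k = 5 groups (Tukey–Kramer for unequal
sizes). No further multiplicity adjustment is applied.

Associations are OLS of each outcome on the exposure increment with three
nested covariate sets — model 1: age, sex, recruitment center (categorical
dummies, first level reference); model 2: + total energy, physical activity,
education (categorical); model 3: + medication for hypertension,
cholesterol and diabetes. Confidence intervals are t-based with residual
df; p-values two-sided; no robust or clustered standard errors.
Missingness in a model's variables is handled complete-case. Sensitivity
exposures are fit with the fully adjusted model only.

Concordance between systems combines two statistics on the participants ×
systems matrix of quintile numbers:

* a single-rating two-way intraclass correlation from the ANOVA mean
  squares, default **absolute agreement**
  `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))`, with the
  consistency form `(MSR − MSE) / (MSR + (k−1)·MSE)` exposed as an option.
  The literature this mirrors labels the statistic "ICC3" while describing
  the absolute-agreement model; the package follows the *description* and
  defaults to absolute agreement, keeping both forms available. Both are
  verified in tests against a raw sums-of-squares oracle (1e-12) and
  against `pingouin`'s ICC(A,1)/ICC(C,1);
* quintile agreement: 100 × #{same quintile in both systems} / n, overall
  and restricted to Q1 and Q5 matches (denominator always the full n).

## The synthetic cohort generator

Because the motivating cohort is access-restricted, `synthesize_cohort`
generates data with the statistical structure the analysis assumes:

* n = 6874 enrolled by default; 48.5% women; age truncated-normal
  (65.1 ± 4.9, range 55–75); eligibility BMI band 27–40 kg/m²; 23
  recruitment centers.
* Item intake is zero-inflated log-normal: item i of participant p has
  target `exp(loc_i + λ_i z_p + σ_i ε)` with probability `1 − p0_i`, else
  zero. `z_p` is a standardized latent *UPF propensity* (shifted up for men
  and for younger participants); loadings λ are positive for
  ultra-processed items and negative for fresh foods. Locations include
  `−σ²/2 − λ²/2` corrections so each item's expected intake equals its
  configured mean. The continuous target is then discretised to the nearest
  FFQ frequency category in log space (below half of the lowest positive
  multiplier → "never"), so the pipeline exercises the real FFQ conversion.
* Per-item means were fixed once to reproduce the published cohort-level
  shares of intake by processing group — about 7.9% (NOVA), 45.9% (IARC),
  20% (IFIC) and 19.7% (UNC) of classified grams — and a mean energy intake
  near 2400 kcal/day; the packaged synthetic composition table gives
  UPF-flagged items higher saturated-fat, sugar and sodium densities and
  less fiber, so Q5-vs-Q1 nutrient gradients arise by construction.
* Outcomes follow a planted linear model on the realized `UPF%/5` of a
  driver system (default NOVA): baseline + slope·increment + age and sex
  effects + Gaussian noise. Default slopes are the fully adjusted NOVA
  associations reported for this population (BMI +0.11 kg/m² per 5%,
  HDL −0.37, creatinine +0.01, waist +0.26; null elsewhere). Weight is
  derived as BMI × height², LDL by Friedewald; BMI is clipped to the
  eligibility band (the baseline is truncated to 28–38.2 so clipping is
  rare and slope attenuation negligible).
* A configurable 13% of participants get one missing outcome and 5.8% get
  their whole FFQ scaled so energy is implausible (400 or 4500 kcal),
  exercising the inclusion rules; together these reproduce the published
  enrolled→analysed attrition (6874 → ~5636). Ground truth (latent
  propensity, injection flags, natural energy, planted slopes) is stored
  separately from the observed tables.

What the generator does **not** emulate: real FFQ measurement error and
recall bias, item–item correlations beyond the single latent factor,
seasonality, center-level diet differences, non-linear diet–outcome
relationships, and the full marginal distributions of the restricted
cohort. Passing tests therefore demonstrate correctness of the pipeline's
computations and calibration of its inference under the stated generative
model — not epidemiological conclusions about real diets.

## Numerical and design choices

* Quantile rule: `numpy` linear-interpolation percentiles; ties fall low.
* ANOVA via `scipy.stats.f_oneway`; studentized-range tail probabilities
  via `scipy.stats.studentized_range`; OLS via `statsmodels` (t-based CIs).
* The ICC decomposition, Tukey contrast estimates/SEs, residual-method
  adjustment and quintile agreement are implemented directly and
  cross-checked in tests against independent oracles
  (`scipy.stats.tukey_hsd`, `pingouin.intraclass_corr`, closed forms).
* Degenerate inputs raise typed errors (`DomainError`,
  `DegenerateDataError`, `InsufficientDataError`) rather than returning
  NaN silently; the single deliberate NaN is Friedewald LDL above
  400 mg/dL triglycerides.
* Determinism: every stochastic step flows from one `numpy` Generator
  seeded by the run seed, and table writers use fixed float formatting, so
  identical (config, seed) runs are byte-identical.

## Problem sizes used by the test and acceptance suites

Unit and property tests run on cohorts of 150–600 participants and on
small closed-form examples. Distributional checks use n = 5000 cohorts.
Parameter recovery uses 500 seeded replicates at n = 5000 (the first 200
for bias and CI coverage of the planted BMI slope, all 500 for the type-I
error of a null outcome). `scripts/acceptance.py` runs one full pipeline at
the enrolment size n = 6874.

## Known limitations

* The packaged taxonomy is a reconstruction: item-level allocations are
  plausible but not authoritative; only its aggregate structure (counts,
  nestings, fractions) is anchored to published values.
* Frequency multipliers and portion sizes are conventions, not measured
  instrument properties.
* Cross-sectional associations only; no causal claims, no longitudinal
  modelling, no survey weighting.
* The concordance ICC treats quintile numbers as interval-scaled ratings,
  as in the methodology it mirrors.
* On synthetic cohorts the cross-system concordance runs higher than real
  cohorts show: a single latent propensity plus UPF item sets that differ
  by few items (IFIC vs UNC differ by one) make the exposures nearly
  proportional, so their quintiles agree more often than independently
  constructed real classifications would. The concordance machinery is
  validated against oracles, not against published concordance levels.
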