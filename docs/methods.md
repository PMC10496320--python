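# Methods

## FFQ quantification

Each questionnaire item is answered on a 9-point ordinal frequency scale.
The default category → occasions/day multipliers follow the EPIC convention:

| category | label | occasions/day |
|---|---|---|
| 1 | never or < once a month | 0 |
| 2 | 1–3 per month | 2/30.44 |
| 3 | once a week | 1/7 |
| 4 | 2–4 per week | 3/7 |
| 5 | 5–6 per week | 5.5/7 |
| 6 | once a day | 1 |
| 7 | 2–3 per day | 2.5 |
| 8 | 4–5 per day | 4.5 |
| 9 | 6+ per day | 6 |

Source instruments do not publish a single canonical multiplier table, so
this one is configuration (any non-negative, non-decreasing mapping of the
nine categories is accepted). Daily grams per item are
`occasions/day × portion fraction × serving size`; the portion fraction is a
per-item, per-category multiplier defaulting to 1.0 — exposed in the
composition-table schema because instruments differ in whether frequency
implies portion scaling. Missing responses count as zero intake
(conservative). Serves per food group divide grams by the item's standard
serve, with multi-tagged items (e.g. cheese: dairy *and* discretionary)
contributing to every group they belong to. Nutrients accumulate from
per-100 g densities; energy conversions are Atwater-style (17 kJ/g
carbohydrate and protein, 37 kJ/g fat, 29 kJ/g alcohol), overridable.

Open-section qualifiers (milk type, cooking fat, …) are resolved by
substituting item variants before quantification — e.g. `milk_type: skim`
swaps the generic milk item for its skim variant, changing the nutrient
densities and the low-fat-dairy tagging downstream. Qualifiers with no
substitution rule are logged once per participant and ignored by the
engine; several of them (sofrito frequency, added sugar in tea/coffee, B-12
supplementation) are consumed later by the screener derivation instead.

## Covariates

GPAQ MET-minutes/week sum `days × minutes × MET` over the five activity
domains with weights 8 (vigorous work/recreation) and 4 (moderate domains
and travel), per the GPAQ analysis guide; activity tertiles use the WHO
cut-offs (< 600 low, 600–1499 moderate, ≥ 1500 high). Blood pressure
discards the first of three readings and averages the remainder. Estimated
energy requirement is Schofield BMR (age/sex weight equations) times an
activity factor of 1.4/1.6/1.8 for low/moderate/high — a conventional
sedentary-to-active range, config-replaceable since the reference equations
behind published scores are rarely stated. The DASH calorie level is the
admissible level (1600/2000/2600/3100 kcal) nearest the EER in kJ; an exact
midpoint resolves to the lower level (conservative targets). Diary water
fraction is mean daily water over mean daily total beverages across the
diary days.

## Scores

All cut-points live in `src/dietscore/data/score_defaults.yaml`. The
supplementary scoring tables of published studies are often not reproduced
in accessible text, so the defaults are transcribed or adapted from the
source instruments (Gunther DASH score with NHLBI eating-plan serving
targets; Loma Linda vegetarian food-guide pyramid; HEIFA-2013; the 14-item
MEDAS; the PREDIMED-Plus 17-item screener) and are deliberately auditable
and overridable rather than hard-coded.

**DASH (0–80).** Forward components score `max_points × min(intake/target, 1)`;
reverse components (meat/poultry/fish/eggs, fats & oils, sweets) give full
points at or below the target and decay as `target/intake` above it — a
bounded, continuous choice where the source states only that reverse scoring
was applied. The low-fat-dairy component awards
`5 × min(lowfat/(0.75 × total), 1)`, and zero when no dairy is consumed (the
share is then undefined and awarding it would break the empty-diet
identity: an empty diet scores exactly the three reverse maxima, 30). The
NHLBI 1600 kcal plan lists zero sweets per week; a zero target degenerates
reverse-proportional scoring, so the 1600-level default is 3 serves/week.

**Dairy-adjusted DASH (0–80).** The low-fat-share component is granted in
full unconditionally, which keeps the 0–80 scale so composites remain
comparable across the two variants (the alternative — dropping to 0–75 —
changes every downstream comparison). Dominance (adjusted ≥ unadjusted,
with equality exactly when the low-fat criterion was already met) is a
tested invariant.

**Vegetarian Lifestyle Index (0–14).** Dietary serves are multiplied by
`8368 kJ / EER` before threshold comparison, making the score invariant to
proportional changes of intake and requirement. Forward components give
1 / 0.5 / 0 points at the full / half / below-half thresholds; reverse
components mirror this. Exercise maps the activity tertile 0/1/2 to
0/0.5/1; water gives 1 at ≥ 50 % water fraction and 0.5 at ≥ 25 %; sunlight
defaults to full marks (subtropical-latitude rule).

**HEIFA (0–100).** Vegetables and fruit split their 10 points into quantity
and variety (distinct items consumed); grains split into quantity and a
≥ 50 %-wholegrain share. Nutrient components interpolate linearly between a
full-score and a zero-score threshold: saturated fat full < 10 %E and zero
≥ 15 %E; added sugar 15/20 %E; sodium 920/3200 mg. Water scores 5 points at
≥ 50 % of beverages and proportionally below; alcohol gives 5 at ≤ 2
serves/day, else 0.

**MEDAS / erMedDiet.** One point per criterion met. The 17-item set is the
14-item set minus the olive-oil-quantity question, plus one wholegrain item,
two refined-grain/white-bread items, and no-added-sugar-in-tea/coffee.
Thresholds shared between the two screeners are kept identical by default
(the energy-restricted variant's adjustments are config-level). Missing
criteria raise an error in strict mode; lenient mode scores 0 with a logged
warning. When screener answers are derived from FFQ intakes rather than
asked, weekly criteria use day-rate × 7, habit booleans come from the open
section, and white-meat preference is poultry serves exceeding red +
processed meat.

## Inference

hsCRP and PAF are analysed on the natural-log scale; the base is forced by
the back-transformation convention `exp(β)`, whose published arithmetic
(β = −0.352 → exp β = 0.703 → 30 % reduction) only holds for base e. In the
OLS models the outcome and continuous predictors (score, age, waist) are
z-scored; gender, year and risk enter as 0/1 indicators and the activity
tertile as an ordinal 0/1/2 — a documented convention, since "standardised
coefficients" alone does not fix the treatment of categorical covariates.
Exponentiating a standardised coefficient mixes a per-SD effect with a
per-point reading; the arithmetic is reproduced exactly as the convention
prescribes and the tension is noted here rather than resolved. Missing data
are handled complete-case per model, no imputation. VIF is computed per
design column with tolerance its reciprocal (`VIF × tolerance ≡ 1`,
`VIF ≥ 1` are tested identities). Rank-deficient designs fail with the most
collinear pair named. Normality screening for automated two-group test
selection uses Shapiro–Wilk at α = 0.05 (a stand-in for visual Q–Q
inspection). Quartile summaries cut at rank percentiles (ties broken by
first-occurrence ranking) and are descriptive only. Stratified fits re-run
the models within each collection year with the year covariate dropped.

Power for a two-sided Pearson test is available as the Fisher-z
approximation (normal on atanh r, SE `1/√(n−3)`) and as Monte-Carlo
simulation: `reps` bivariate-normal samples at the true correlation, with
the exact t-based two-sided p computed per replicate and rejections counted
at α. At n = 100, ρ = 0.3, α = 0.05 both methods give ≈ 86 % power,
consistent with an 80 %-power design statement at that sample size.

## Synthetic cohort generator

The generator emulates the *structure* of a ~100-participant cross-sectional
study — ~69 % female, ~68 % at high CVD risk, recruitment split across two
calendar years, activity tertiles ≈ 20/19/61 % — not any real cohort's joint
distribution. A latent diet-quality factor `z ~ N(0,1)` per participant
drives: (a) FFQ frequencies by ordered-threshold sampling —
`category = bin(a·w_i·z + offset_i + ε)` with item healthiness loadings
`w_i ∈ {−1, 0, +1}` and link strength a = 0.9 — which guarantees a monotone
link between the factor and every healthy-food tendency without per-item
tuning; and (b) the biomarkers, via standardised linear equations with unit
total variance, e.g. `log-hsCRP* = β_diet·z + β_age·age_z + β_risk·risk_z + ε`.
Because the equations are written on the standardised scale, each configured
coefficient *is* the population standardised regression effect, so recovery
checks can target the configured −0.35 diet→log-hsCRP default exactly;
recovery is checked against the latent factor itself, since any computed
score is a noisy proxy that attenuates the coefficient (as real instruments
do — visible in the worked example). hsCRP and PAF are log-normal and
Lp-PLA2 Gaussian, with locations and spreads chosen as loose approximations
of published community cohorts (median ≈ 1 mg/L hsCRP, ≈ 8 ng/mL PAF,
14.9 ± 4.3 nmol/min/mL Lp-PLA2) — approximations, not fits. The year→PAF
effect is off by default and switchable to exercise the stratified analysis.

What passing tests on these cohorts do **not** show: FFQ measurement error
structure (correlated over-reporting of healthy foods), real food-composition
values (the fixture table's ~40 items and densities are invented, AUSNUT-style
in schema only), seasonal or clustered recruitment, and genuine biomarker
assay noise. Scale maxima, bounds, monotonicity and the statistical
identities are instrument properties and hold regardless.

## Problem sizes and numerical choices

Default test/workflow sizes: cohorts of n = 100 (the emulated design size),
200 replicates for effect-recovery checks (Monte-Carlo SE of the mean
≈ 0.007 on β), 1000 replicates for type-I-error checks (binomial SE
≈ 0.007 at α = 0.05), 10,000 replicates for simulation power. All
randomness flows through explicit `numpy.random.default_rng` seeds;
generated file sets are byte-identical under a repeated seed and carry a
manifest with the seed and a config hash.

## Known limitations

- Component cut-points are package defaults, not verified against any
  study's supplementary tables; results depend on the config in use.
- The erMedDiet energy-restriction adjustments to shared MEDAS thresholds
  are not encoded by default (identical thresholds are used).
- CVD-risk classification is an input label; the package does not
  re-derive it from lipids/blood pressure.
- Only the beverage/water part of the 3-day diary is modelled; full diary
  nutrient analysis is out of scope.
- One text convention conflict exists in the literature for the vegetarian
  index's printed range (0–15 vs 0–14 over 14 components); the 14-component
  0–14 definition is implemented.
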