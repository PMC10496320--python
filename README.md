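# dietscore

Diet-quality scoring and inflammation-association statistics for
cross-sectional nutrition studies.

`dietscore` implements the full analytic chain used when relating habitual
diet to inflammatory biomarkers in adults at varied cardiovascular risk:

1. **FFQ quantification** — food-frequency-questionnaire responses on a
   9-point scale ("never or less than once a month" … "6+ per day") are
   converted to daily gram, serving, nutrient and energy intakes through a
   food-composition table, in the style of the EPIC/FETA computation:
   `grams/day = occasions/day × portion fraction × serving size (g)`.
2. **Covariate derivation** — GPAQ MET-minutes/week and WHO activity
   tertiles (cut-offs 600 and 1500), BMI, triplicate blood-pressure
   averaging (first reading discarded), 3-day-diary water fraction, and
   estimated energy requirements (Schofield BMR × activity factor) mapped to
   the nearest DASH eating-plan calorie level (1600/2000/2600/3100 kcal).
3. **Six diet-quality composites** —
   * DASH index (Gunther scheme), 0–80: six 10-point proportional components
     and four 5-point grain/dairy components, targets specific to the
     assigned calorie level;
   * Dairy-adjusted DASH, 0–80: the same score with the "75% of dairy must
     be low fat" component granted in full;
   * Vegetarian Lifestyle Index, 0–14: eleven diet components standardised
     to 2000 kcal (8368 kJ) plus exercise, water and sunlight, each scored
     0 / 0.5 / 1;
   * HEIFA, 0–100: eleven components against the Australian Guide to
     Healthy Eating, including the saturated-fat %-energy rule (full score
     < 10 %E, zero ≥ 15 %E) and the 50 %-water rule;
   * MEDAS (14 items) and erMedDiet (17 items): binary Mediterranean-diet
     adherence screeners.
4. **Inference** — natural-log transformation of right-skewed biomarkers
   (hsCRP, PAF), t-tests / Mann–Whitney U comparisons, pairwise Pearson
   correlations with Cohen magnitude labels, and two OLS models with
   standardised coefficients β: model 1 adjusts for age, gender and year of
   collection; model 2 additionally for waist circumference, activity and
   CVD-risk class (activity is omitted for the Vegetarian Lifestyle Index,
   which already scores it). Coefficients on log outcomes are
   back-transformed as exp(β), read as a multiplicative effect per score
   point: exp(β) = 0.70 means a 30 % lower biomarker per one-point increase.
   VIF/tolerance collinearity diagnostics, descriptive quartile summaries
   and a Pearson-correlation power calculator (Fisher-z and Monte-Carlo)
   complete the pipeline.
5. **Synthetic cohorts** — because raw study data of this kind is typically
   available only on request, a generator emulates the whole input surface
   (FFQ, open section, GPAQ, diary, anthropometry, biomarkers) with a latent
   diet-quality factor linking food choices and biomarkers at configurable
   standardised effect sizes.

## Worked example

```bash
dietscore simulate --n 100 --seed 11 --out-dir demo/data
dietscore score    --in-dir demo/data --out-dir demo/scores
dietscore analyze  --in-dir demo/data --scores-dir demo/scores --out-dir demo/analysis
dietscore power    --n 100 --rho 0.3 --method simulation --seed 11
```

prints

```
wrote 5 files to demo/data (seed=11, config_hash=05b84c04302a0cf5)
scored 100 participants -> demo/scores/composites.csv
analysis tables written to demo/analysis
power(simulation, n=100, rho=0.3, alpha=0.05) = 0.8722
```

The model table (`demo/analysis/models.csv`) for log hsCRP, model 1, on this
cohort (generated with the default standardised diet→log-hsCRP effect of
−0.35) reads:

```
         score  n_used  beta_std  p_value  exp_beta  pct_change
          dash     100    -0.378    0.000     0.685      31.484
dash_dairy_adj     100    -0.376    0.000     0.686      31.373
    vegetarian     100    -0.264    0.006     0.768      23.203
         heifa     100    -0.342    0.000     0.710      28.970
         medas     100    -0.270    0.005     0.764      23.636
     ermeddiet     100    -0.272    0.004     0.762      23.838
```

Each row is one standardised coefficient: e.g. the DASH row says a one-point
(one-SD) increase in DASH adherence is associated with exp(−0.378) = 0.685
times the hsCRP level — a 31 % reduction. The scores recover the configured
effect imperfectly because an FFQ-derived score is a noisy proxy of the
latent diet factor, which is exactly the attenuation a real instrument
shows. `demo/analysis/` also contains the score–score and score–biomarker
correlation tables, per-year stratified model fits and descriptive
biomarker-by-score-quartile means.

All numeric scoring cut-points live in
`src/dietscore/data/score_defaults.yaml`; pass an edited copy via
`dietscore score --config my_config.yaml` to change targets without
touching code.

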