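# Methods

## The substitution model

The unit of analysis is the person-day: one participant's Day-1 24-hour
recall, carrying survey design labels (stratum, PSU), a sampling weight,
and an ordered list of reported foods. Multi-day files are supported by
the reader but only the configured day (Day 1 by default) is kept, and
dietary supplements are outside the schema: the analysis concerns
nutrients from foods and beverages only.

A **substitution policy** flags items as "typical sandwiches" by WWEIA
category and/or 8-digit food code. The shipped default covers the
burger, frankfurter/sausage and cold-cut/poultry/egg sandwich
categories; it is configuration, editable per run, not a claim about any
particular published category list.

For a scenario with modeled profile *Q*, each flagged occurrence is
replaced by one fixed-size *Q*:

    modified = baseline − Σ(flagged items) + n_flagged · Q

Key modeling choices, each genuinely open and decided here:

- **Per-occurrence, fixed-size replacement.** The composites are
  prespecified amounts (e.g. 2 oz eq bread + 2.5 oz eq meat + 1 cup eq
  cheese), so the injected sandwich is not scaled by the replaced item's
  grams. A portion-scaled mode is deliberately not offered.
- **Multiple sandwiches in a day are each replaced independently.**
- **Totals-level substitution.** Item lists are not rewritten; all
  downstream analysis consumes daily totals, so rewriting would add
  state without changing any estimate.
- Negative modified totals can arise only from inconsistent inputs and
  are clamped to zero with a logged warning.
- Condiments are not modeled; modeled sandwiches are therefore leaner
  than sandwiches as typically eaten with sauces.

The conservation identity `modified − baseline = n·Q − Σ flagged` holds
exactly (to 1e-9) and is tested on random person-days.

## Sandwich profiles

Six profiles ship as a packaged CSV fixture: the typically consumed
sandwich ("Sandwich 0") and five modeled builds (whole-grain or
enriched-grain bread with red meat or grilled chicken plus cheese and
vegetables, and a soft corn tortilla taco with chicken/cheese). Their
nutrient vectors reproduce the source composite table cell-for-cell
(fidelity is enforced by a test against an independently checked-in
copy).

The source table prints nutrients only. Fields the pipeline needs beyond
it are explicit package assumptions:

- **added sugar**: 0 tsp eq for every profile (none is documented).
- **food groups, sandwiches 1–4**: the prespecified composite targets —
  2 oz eq whole (1, 3) or refined (2, 4) grains, 2.5 oz eq protein
  foods, 1 cup eq dairy, 0.1 cup eq dark-green + 0.1 cup eq red/orange
  vegetables (recorded as greens_beans 0.1 within total_veg 0.2).
- **food groups, sandwich 0**: unknown; stored as zeros and flagged
  `groups_known=False` so consumers can exclude it from group-based
  scoring decisions.
- **food groups, sandwich 5 (taco)**: assumed 1 oz eq whole grains
  (corn tortillas), 1.5 oz eq protein foods, 0.5 cup eq dairy, 0.1 cup
  eq vegetables.
- **fatty acids / solid fat**: SFA equals the printed saturated fat;
  the remaining fat is split 2:1 MUFA:PUFA (only the MUFA+PUFA sum
  enters HEI, so the split is inert); solid-fat energy is 9 kcal/g ×
  SFA, treating meat/cheese fat as solid.

## Composite building

`consumption_weights` weights each qualifying food code by
survey-weight × grams consumed, normalised within the food group —
"as eaten" population amounts rather than unweighted eating frequency
(the basis is not externally fixed; grams × weight is this package's
choice). Weights are computed per group independently; a food qualifying
for two groups is weighted separately in each. Zero-consumption codes
are dropped rather than given uniform mass. `build_composite` then needs
`target·w_f / density` grams of each food (equivalent density per gram),
errors on zero-density foods, and yields a profile whose group vector
equals the targets exactly; nutrient content is linear in the targets.
The five shipped profiles are fixtures, not rebuilt — rebuilding would
require the full food-composition and food-pattern-equivalent databases
— but the builder is fully exercised on toy databases.

## HEI-2010 scoring

Standards are fixed constants, exported as a CSV resource for audit:
eight adequacy components (total fruit ≥ 0.8 and whole fruit ≥ 0.4 cup
eq/1,000 kcal; total vegetables ≥ 1.1 and greens & beans ≥ 0.2; whole
grains ≥ 1.5 oz eq and dairy ≥ 1.3 cup eq, 10 points each; total protein
≥ 2.5 and seafood/plant protein ≥ 0.8 oz eq), the fatty-acid ratio
(MUFA+PUFA)/SFA (10 at ≥ 2.5, 0 at ≤ 1.2), and three moderation
components (refined grains 10 at ≤ 1.8 oz eq/1,000 kcal, 0 at ≥ 4.3;
sodium 10 at ≤ 1.1 g/1,000 kcal, 0 at ≥ 2.0; empty calories 20 at ≤ 19 %
of energy, 0 at ≥ 50 %). Scores interpolate linearly and clip.

Conventions for degenerate inputs: zero energy ⇒ all densities
undefined ⇒ every component 0 (avoids 0/0 and matches common
implementation practice); SFA = 0 with MUFA+PUFA > 0 ⇒ maximal ratio ⇒
10 points; all fats zero ⇒ 0 points. Empty calories count solid-fat
kcal, 16 kcal per tsp eq added sugar, and 7 kcal/g of alcohol above
13 g/1,000 kcal.

Scoring is **person-level**: each person-day is scored and the
population HEI is the survey-weighted mean of per-day totals, matching a
least-square-means presentation. The population-ratio method (scoring
the density of summed population intakes) is not implemented.

## Survey estimation

Means are covariate-free survey-weighted ratio means — "least square
means" from a means procedure without covariates, which is what a
weighted mean is. Variance is the with-replacement Taylor linearization
(stratum factor n_h/(n_h−1) on PSU totals of z = w(y − ȳ)), df =
#PSUs − #strata, t-based symmetric CIs, 99 % by default. Strata with a
single PSU are a hard error unless `collapse_single_psu=True`, which
pools single-PSU strata (PSU labels re-qualified by original stratum so
distinct PSUs never merge); a lone single-PSU stratum is folded into the
first remaining stratum. Replicate-weight (BRR/jackknife) variance and
domain estimation are out of scope.

The decision rule is closed-interval CI non-overlap: a shared endpoint
counts as overlap, i.e. *not* meaningful.

## Synthetic populations

The generator emulates the design features the estimator consumes, with
every parameter known:

- stratified sampling, default 14 strata × 2 PSUs, round-robin
  assignment (guarantees ≥ 2 PSUs per stratum at any n);
- lognormal(0, 0.5) weights;
- Poisson(8) background items per day, each a truncated-normal (at 0)
  draw around background_mean/8 with CV 0.25;
- Poisson(0.78) typical-sandwich items per day, each the configured
  sandwich profile times a mean-one lognormal factor (CV 0.10).

The defaults are the study conditions, chosen once: the sandwich rate
0.78/person-day is the per-capita rate implied by a ≈ 231 kcal mean
energy shift against a 297 kcal profile delta, and the background
nutrient means are (typical US-adult baseline daily means) −
0.78 × (typical-sandwich profile), so the scenario-0 population
reproduces those baseline means in expectation (energy ≈ 2,302 kcal,
sodium ≈ 3,862 mg, ...). Carbohydrate and protein baselines, not in the
anchor set, are set to 250 g and 80 g. Background food-group means are
set to yield a plausible mid-range HEI (high refined grains and solid
fat, modest fruit/whole grains).

What the generator does **not** emulate: demographic covariates,
day-to-day within-person variance, realistic marginal shapes beyond
means/CVs, item-level food codes drawn from a real database, or
correlation between sandwich consumption and the rest of the diet.
Passing tests therefore demonstrate the *estimator chain* is correct
under known truth, not that any real population behaves this way.

The analytic oracle `expected_scenario_shift` = rate × (Q − P) follows
from Wald's identity for the Poisson-compounded sum and is recovered by
the full pipeline within 3 estimated SEs for every nutrient at
n = 2,000 across 3 seeds — problem sizes chosen to keep the whole suite
in the tens of seconds on one CPU.

## Numerical and display conventions

- Group-closure and weight-normalisation checks at 1e-9 relative
  tolerance; conservation asserted at 1e-9 absolute.
- Display rounding only in `summary()`/`format_table`: means ≥ 100 print
  as integers with SE to 1 decimal ("2302 ± 12.4"), smaller means to 1
  decimal with SE to 2 ("48.7 ± 0.26"). CSV outputs keep full precision.
- Scenario labels are strings end-to-end ("0" is the reserved
  pass-through baseline).
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces
  byte-identical pipeline outputs.

## Known limitations

- The NHANES-scale benchmark (reproducing published national estimates)
  requires the real recall files plus food-composition merges and is not
  attempted here; the package's claims are the desk-scale properties
  above.
- XPT support is read-only and assumes the canonical column names after
  lower-casing; NHANES-native variable names require renaming upstream.
- HEI-2010 only; HEI-2015/2020 standards are not included.
- Sandwich-0 food groups being unknown means baseline HEI on real data
  depends entirely on the recall file's own food-group columns — the
  profile contributes none.
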