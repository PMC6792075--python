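# dietshift

Sandwich-substitution dietary modeling on 24-hour recall data.

Sandwiches are a mainstay of the US adult diet, and the most commonly
eaten kinds (burgers, cold cuts, hot dogs) carry a large share of daily
sodium, saturated fat and energy. `dietshift` asks the *what-if*
question a nutrition epidemiologist would: **if every typically consumed
sandwich in a population's recall data were replaced by a healthier
modeled sandwich — whole-grain or enriched-grain bread builds, or a soft
corn tortilla taco — how would population mean nutrient intakes and diet
quality change?**

The package is aimed at analysts working with NHANES/WWEIA-style
24-hour recall data (one row per reported food, with survey design
variables) and at methodologists who want the whole chain testable on
synthetic data with known ground truth.

## What it computes

For each substitution scenario *s* with sandwich profile *Q_s*, every
person-day's totals are modified per flagged sandwich occurrence:

    modified = baseline − Σ_flagged item + n_flagged · Q_s

Diet quality is scored per person-day with **HEI-2010** (12 components,
0–100; densities per 1,000 kcal with piecewise-linear standards, e.g.
whole grains max 10 points at ≥ 1.5 oz eq/1,000 kcal, sodium max 10 at
≤ 1.1 g/1,000 kcal, empty calories max 20 at ≤ 19 % of energy).

Population means are estimated with survey weights under a stratified
PSU design; the variance is Taylor-linearized,

    var(ȳ_w) = Σ_h n_h/(n_h−1) Σ_i (z_hi − z̄_h)² / (Σ w)²,   z = w(y − ȳ_w)

with df = #PSUs − #strata and 99 % t-based confidence limits. Two
scenarios differ *meaningfully* when their 99 % CIs do not overlap.

Composites can also be built from scratch: given food-group targets and
qualifying food codes, `consumption_weights` weights codes by
survey-weight × grams as eaten, and `build_composite` assembles a
profile whose group vector equals the targets exactly.

## Worked example

```python
import dietshift as ds

days = ds.gen_population(ds.PopulationConfig(n_participants=400, seed=3))
res = ds.SandwichSubstitutionModel(days).fit()

e0, e5 = res.estimate("energy", "0"), res.estimate("energy", "5")
print(f"energy base {e0.mean:.0f}±{e0.se:.1f}  taco {e5.mean:.0f}±{e5.se:.1f}")
print(f"HEI base {res.estimate('hei_total', '0').mean:.1f}")
print(res.meaningful_matrix("energy").loc["0"])
```

prints

```
energy base 2306±33.5  taco 2071±34.7
HEI base 51.9
0    False
1    False
2    False
3    False
4    False
5     True
Name: 0, dtype: bool
```

Scenario 0 is the pass-through baseline (typical sandwiches as eaten,
≈ 2,306 kcal/day here); scenario 5 substitutes the soft corn tortilla
taco and drops mean daily energy by ≈ 235 kcal — the only contrast whose
99 % confidence intervals do not overlap the baseline's, hence the only
`True` in the decision row. `res.summary()` renders the full report
tables (nutrients to limit, nutrients of public health concern,
shortfall nutrients, enrichment nutrients, HEI) as `mean ± SE` with
`LCL99, UCL99`, and `res.save(outdir)` writes them as CSV.

From the shell:

```bash
dietshift synth --seed 7 --n 2000 --out data.csv
dietshift run --config cfg.yaml --out results/
dietshift hei --in totals.csv
```

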