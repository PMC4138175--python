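# ssbtax

Simulation of an ad valorem tax on sugar-sweetened beverages (SSBs) and
its effect on adult obesity, in the style of the comparative-risk models
used for South Africa and similar settings. The package is aimed at
public-health modellers and health-economics analysts who want a tested,
reproducible implementation of the full chain from a tax scenario to
obesity head counts, with Monte Carlo uncertainty and the standard
sensitivity analyses.

## The model

For each beverage *b* (SSB, full-cream milk, unsweetened fruit juice,
diet drinks) with baseline consumption *V\_b* (litres/person/day) on
10-year age bands, a tax *t* with pass-on rate *r* raises the consumer
price by *p = t·r* and shifts consumption by the constant-elasticity
demand form

ΔV_b = V_b · [(1 + p)^(ε_b) − 1],

where ε is the own-price elasticity −1.299 for SSBs and the cross-price
elasticities +0.129 (milk), +0.388 (juice), −0.423 (diet). Volume deltas
become a net energy-intake change ΔE = Σ_b ΔV_b·ρ_b using energy
densities ρ = 1800/2540/1340/4 kJ/l, mapped onto thirteen 5-year model
bands (20–24 … 80+). At equilibrium a sustained 94 kJ/day change moves
body weight by 1 kg, so mean BMI in band *a*, sex *s* shifts by

Δ BMI_{a,s} = ΔE_a / (94 · h̄_{a,s}²),

with h̄ the mean height. Band/sex BMI is modelled as lognormal fitted to
survey microdata by least squares on the empirical density; obesity
prevalence is the tail mass above BMI 30, and shifting the mean while
holding the spread fixed moves that tail (the population-mean view of
risk-factor prevalence). Prevalence changes times the population pyramid
give head-count changes. Uncertainty is propagated by redrawing the four
elasticities, the 94 kJ/kg/day factor and all consumption means from
independent normals (10 000 draws, percentile intervals).

Because the underlying surveys (BMI microdata and categorical beverage
items) are not redistributable, `ssbtax.synthetic` generates survey-like
inputs with the same statistical structure, calibrated to the published
consumption table; every stage also accepts your own CSVs.

## Worked example

```sh
ssbtax run --out demo --seed 1 --tax-rate 0.20 --pass-on 1.0
```

runs synthetic generation → consumption estimation → demand shift →
energy balance → BMI fitting → prevalence/head counts → Monte Carlo →
sensitivity grids, and prints a summary (about 3 s). With seed 1 the
summary reads, in part:

```
Net energy-intake change (kJ/person/day) by age band:
20-24   -46.89
...
80+     -15.35

Obesity change by sex:
   sex  baseline  shifted  pp_change  relative_change  count_change
  male    0.1037   0.0997    -0.0040          -0.0386   -58920.0380
female    0.3180   0.3099    -0.0081          -0.0256  -130364.7212
```

Reading: a 20% fully passed-on tax cuts daily energy intake by ~47 kJ in
the youngest adults (the heaviest SSB consumers) and ~15 kJ at 65+,
which lowers male obesity prevalence by 0.40 percentage points (a 3.9%
relative reduction from a 10.4% baseline) and female prevalence by 0.81
points (2.6% relative), about 189 000 fewer obese adults on this
synthetic population. The published study's corresponding figures from
the real surveys are −3.8% (men) and −2.4% (women).

The same chain is available as a library:

```python
import ssbtax as st
res = st.run_deterministic(st.ModelInputs(), st.TaxScenario(0.20, 1.00))
print(res.energy["net"])          # kJ/person/day per 5-year band
print(res.obesity_by_sex)
```

Using the built-in published consumption table this prints −46.2 kJ/day
for band 20–24 and a mean reduction of 30.1 kJ/day across bands.

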