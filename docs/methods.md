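# Methods

## Model structure and assumptions

The simulation compares an unchanged reference population with a
counterfactual population in which an SSB tax has raised consumer
prices. The causal chain is deliberately simple and equilibrium-only:

1. **Price.** An ad valorem tax `t` with pass-on rate `r` raises the
   consumer price by `p = t·r`. Default `t = 0.20`, `r = 1.00`
   (evidence from carbonated-drink markets supports full
   pass-through; the sensitivity grid spans 80–120%).
2. **Demand.** Consumption of each beverage responds through a fixed
   elasticity, identical across ages and sexes: SSB own-price −1.299,
   cross-price +0.129 (milk), +0.388 (unsweetened juice), −0.423 (diet
   drinks). Two functional forms are implemented. The default is the
   constant-elasticity (power) form, ΔV/V = (1+p)^ε − 1; the linear
   form ΔV/V = ε·p is retained as an option. The source description of
   the elasticity step reads linearly ("a 10% price increase … a 13%
   decrease"), but only the power form reproduces the published
   per-band energy table to within about 1% — the linear form
   overshoots materially (≈ −62 kJ/day for the 25–34 row against a
   printed −43) — so the power form is inferred to be what the original
   spreadsheet computed and is the default here.
3. **Energy.** Volume deltas (litres/person/day) convert to energy at
   fixed densities: 1800 kJ/l (SSB), 2540 (full-cream milk — all milk
   is treated as full cream), 1340 (juice), 4 (diet). The percentage
   change in energy equals the percentage change in volume. The four
   terms are summed to a net change; substitution toward milk and juice
   offsets roughly a third of the SSB reduction.
4. **Weight and BMI.** A sustained 94 kJ/day intake change corresponds
   to 1 kg of equilibrium body-weight change in adults (SD 2.96 in the
   uncertainty analysis). Mean weight change divides by mean height
   squared per 5-year band and sex to give a mean BMI shift. No time
   path is modelled — results are the new equilibrium.
5. **Prevalence.** Band/sex BMI is a two-parameter positively skewed
   distribution (lognormal default, gamma alternative), parameterised
   by its arithmetic mean and SD. Obesity prevalence is the tail mass
   above BMI 30 (25 available for overweight). The counterfactual
   shifts the arithmetic mean by the modelled BMI delta and re-reads
   the tail: the population mean predicts the prevalence of individuals
   beyond the cutoff. Prevalence changes times the population pyramid
   give head-count changes; relative changes are population-weighted
   prevalence change over baseline prevalence.

## Band structure

Consumption is estimated on 10-year bands (15–24 … 65+), the scale of
the source consumption survey; BMI and prevalence on thirteen 5-year
bands (20–24 … 80+). Each 5-year band inherits its containing decade's
consumption estimate — the published per-band energy table shows
near-identical values within decades, indicating the same mapping. Ages
15–19 contribute to consumption estimation only.

## Consumption coding

Milk and juice were asked as cups per day in ranges; SSBs as times
drunk last week. One cup = 250 ml; one SSB serving = 330 ml by default
(200/250/330/500 in the serving-size sensitivity). Ranges take their
midpoint; the open categories are capped: "more than two cups" = 500 ml
and "less than half a cup" = 125 ml. Weekly SSB frequencies take
midpoints 2/7 and 5/7 servings/day, "every day" exactly one serving/day.
"Don't know" is treated as missing and excluded from numerator and
denominator — coding it zero would bias means downward with no support
in the instrument. Diet-drink consumption is 4% of SSB consumption.
Estimates are survey-weighted means with standard errors of the mean;
the built-in parameter table stores the published means at full printed
precision with SEs derived from their 95% confidence intervals as
(upper − lower)/3.92 (the separately printed diet-drink SEs are used
directly, being the more precise print for that column).

## BMI fitting

Microdata are cleaned by trimming BMI strictly below the 1st or above
the 99th weighted percentile of the full adult sample. Each (band, sex)
cell is fitted by least squares: the family's pdf, parameterised by
arithmetic mean and SD, is matched to the weighted empirical density on
60 equal bins over 10–60 kg/m² (bin grid configurable; no grid is
prescribed by the source, and results are insensitive to it at these
sample sizes), initialised at the sample moments with positivity
bounds. Fitted means are then smoothed across age with a cubic
polynomial in band-midpoint age and SDs with a quadratic (degrees
configurable; the source says only "polynomial functions"). The
counterfactual holds the arithmetic SD fixed when shifting the mean; a
`hold="sigma"` switch instead fixes the lognormal log-scale sigma.

On lognormal synthetic cells the gamma alternative carries a visible
mis-specification bias in baseline tail mass (up to ~1 percentage point
near mean 27), but the two families agree on the tax-induced prevalence
*change* to within ~0.03 points, which is the quantity the model acts
on.

## Uncertainty and sensitivity

Monte Carlo draws (default 10 000, seeded, vectorised) sample the four
elasticities, the 94 kJ/kg/day factor, and every per-decade per-beverage
consumption mean from independent normals — no correlation structure is
asserted, draws are untruncated (elasticity sign flips are allowed,
which is why upper interval bounds cross zero in the 65+ bands), and
decade-sharing 5-year bands move together within a draw. Intervals are
2.5th/97.5th percentiles; both the deterministic point estimate and the
Monte Carlo mean are reported.

The two-way sensitivity grid crosses tax 10/20/30% with pass-on
80–120% deterministically. The serving-size analysis re-derives the
consumption estimates from the raw categorical records at 200/250/330/
500 ml per serving and reruns the chain; it reports both the relative
obesity change and the absolute percentage-point change. The published
claim that serving size moves results by at most 0.6 points is only
arithmetically consistent on the percentage-point scale measured
against the 330 ml base case (SSB volume scales with serving size, so
relative changes at 500 ml are nearly double the base case), and that
is the scale the tests check.

## Synthetic data

The generators emulate the marginal structure the model consumes, not
the surveys' two-stage cluster designs. BMI microdata: per (band, sex)
lognormal with configured arithmetic mean/SD (SA-like defaults — female
means rising from 24.5 to ~30 kg/m², male 22 to ~25.6, national obesity
near 40%/13% for women/men), heights normal per sex (1.693/1.601 m,
back-solved from the published paired male/female BMI shifts) and
independent of BMI (only band-mean heights enter the model), weight
derived as BMI × height². Survey weights default to 1 with a
gamma(mean 1) option to exercise weighted estimators. Consumption
responses: per-decade categorical probabilities calibrated exactly to
the published mean volumes (SSB 209 ml/day at 15–24 declining to 120 at
65+). The pyramid is an SA-2012-like declining age structure. All
generators are pure functions of (config, seed).

Passing tests on these inputs demonstrates correctness of the
estimation and simulation machinery and internal consistency with the
published parameter set; it does not validate the model against the
real surveys, whose design effects, non-response and reporting biases
the generators deliberately omit.

## Numerical choices and problem sizes

Tests use 50 000 synthetic BMI records (≥ ~90 per smallest cell),
20 000 consumption records, and 10 000 Monte Carlo draws for interval
checks (smaller draws for pure invariants); the full pipeline runs in a
few seconds. Cells with fewer than 30 records refuse to fit. Zero tax
or zero pass-on short-circuits to exact zeros in every stage and every
draw. The "don't know"/"less than one cup" wording overlap in the
source instrument is handled by aliasing "less than one cup" to the
capped 125 ml category.

## Known limitations

No substitution to tea, coffee, water or solid food; no income- or
sex-specific elasticities; no energy compensation at later meals; no
weight-change dynamics; consumption self-report biases are inherited
from the source estimates. Head-count results on synthetic inputs
depend on the synthetic pyramid and BMI tables and are not estimates
for any real population.
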