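# Methods

## Scope and structure

`oleotec` is a deterministic techno-economic model of microbial lipid
production. One scenario is a tuple (plant capacity, region, feedstock,
productivity scenario, end product, operating mode); the engine composes
five stages in a fixed order — capital-cost prediction, fixed annual costs
(depreciation, facilities, other, labor), lipid mass balance, variable
operating costs, and aggregation to COGS/kg and gross margin. There is no
randomness anywhere in the engine: identical inputs give bit-identical
results. Randomness exists only in the synthetic-data generators, which are
seeded.

## Mass balance

Batch and continuous operation are normalized through *media turnovers*:
one batch consumes one working volume of media; a continuous culture at
dilution rate D consumes D × utilization volumes per year. The default
dilution rate of 0.14/d corresponds to roughly one full volume exchanged
per week, which makes a 5-day batch cycle and a month-long continuous run
comparable in both media usage and output. Continuous mode holds the titer
at the scenario's batch value while producing at D; no continuous-specific
titer data exist to do better.

Salable lipid is fermented lipid × recovery yield (hexane extraction,
default 0.95). Carbon demand is computed from the *fermented* lipid —
recovery losses are charged once, on the output side, never inflated into
substrate demand. Waste-stream hydrolysates carry a yield drag of at most
3% (inhibitory metabolites), applied as a (1 − d) factor on effective
yield. Direct sugars have unit preprocessing efficiency, zero preprocessing
cost, and zero drag by construction, and the validator enforces this.

Seed trains and inoculum volumes are ignored: plant capacity is production
volume. Growth kinetics enter only through the batch duration.

## Capacity scaling

Capital expense and staffing both follow fitted power laws
`value = a · capacity^b`, estimated by OLS on the log-log scale, where the
power law is linear and multiplicative noise on published build costs is
approximately homoscedastic. R² is reported on the log scale — the fit's
actual residual space — so a goodness-of-fit comparison against any
external build table is well-defined. Region is deliberately excluded as a
covariate: build location shows no clear cost relationship, as most cost is
equipment and infrastructure. Feedstock multipliers (0.86 / 0.93 / 1.00)
apply multiplicatively to the fitted prediction; whether they should
instead enter the intercept before fitting is unknowable from the source
material, and the multiplicative choice keeps the fit feedstock-agnostic.
FTE predictions are left as positive reals; rounding would create step
artifacts in smooth scale curves (a reporting option can round).

The modeled capacity range is 50 thousand to 15 million liters. Beyond
15M L, mixing efficiency, concrete strength, and feedstock logistics
(already ~150,000 acres of corn stover at base-case productivity) make
scaling impractical; predictions outside the range are extrapolated with a
logged warning rather than refused.

## Productivity scenarios

Four named scenarios ladder the titer axis per carbon source. The
published scenario values (98.6/57.85/32.7/111.63 g/L glucose;
23.6/13.73/7.86/26.88 g/L glycerol) are not recoverable from the packaged
abridged literature table — e.g. the mean of all 36 titers is ≈23.6 g/L,
not 32.7 — because the selection behind the published central scenarios is
not stated. The derivation is therefore policy-parameterized:
`authors_published` (the default, for reproduction) returns the published
values; `all_records` computes high = max titer, base = third quartile
(linear interpolation between order statistics, the inclusive convention),
low = mean, and future = high / (best observed fraction of theoretical
yield). Note the mean can exceed the third quartile for heavily
right-skewed samples, so "low ≤ base" is a property of realistic titer
distributions, not a theorem; the test suite asserts only the always-true
orderings for arbitrary samples and the full ordering on the packaged
table.

The abridged table in `data/strain_table.csv` prints no feed column; feed
labels (glycerol for the *R. fluvialis* crude-glycerol study, hydrolysate
for the *T. oleaginosus* microalgae-hydrolysate series, glucose otherwise)
are an editorial annotation from the source descriptions. The hydrolysate
label also keeps the one reported 0.43 g/g yield — above the 0.35 g/g
glucose ceiling — from violating stoichiometric bounds it was never
subject to. Theoretical yields (0.35 g/g glucose, 0.38 g/g glycerol, to
palmitic acid) are treated as given constants.

## Costs and margins

COGS is the sum of a closed set of eleven annual components divided by
annual output. Facilities = 5.0% of CapEx/yr; other = 16.9% of
facilities/yr; depreciation is straight-line over 20 years — note this
makes the depreciation and facilities shares identical whenever both use
the same CapEx, a structural feature, not a coincidence. Media is charged
per liter per media turnover so batch and continuous plants are costed
consistently. Corporate tax is *not* a COGS component: margins here are
gross margins, and pre-tax margins are negative in every default scenario,
so tax would be zero anyway; tax rates are carried in the region profiles
for completeness.

Product-specific costs use a scalar adjustment factor on baseline COGS
(defaults 1.0 / 1.016 / 0.999 / 1.071 for palm-oil alternative, high-oleic,
low-CI biofuel oil, and 75% lauric respectively, the average ratios of the
packaged per-product cost columns) since fatty-acid-profile differences
move costs by only a couple of percent. Gross margin is
(price − COGS)/price × 100 on a per-tonne basis. All results are carried at
full precision; reports round to $0.01/kg, $1/MT, and 0.1%.

## Default assumption set and placeholders

Published values are packaged exactly: glucose $500/MT (USA, EU) and
$400/MT (SEA); glycerin $600/$500; corn stover $42.50/MT; sugar beet
$52.70/MT; cassava $29.01/MT; EFB $48.82/MT; bread waste = 2 × EFB
collection cost (a computed rule, overridable); preprocessing $38.10/MT
(bread waste) to $80.34/MT (corn stover); the CapEx multipliers; the
facilities/other/depreciation parameters; the bread-waste 4.5M L
availability cap; commodity prices $875 / $1,006 / $1,389–1,295 (by
region) / $1,120 per MT.

Quantities the sources state only qualitatively carry placeholder defaults,
flagged in `AssumptionSet.calibration_needed` and chosen once for realism:

| placeholder | default | basis |
|---|---|---|
| operator salary | 45k / 40k / 12k $/yr (USA/EU/SEA) | public machine-operator salary levels |
| corporate tax rate | 0.26 / 0.22 / 0.23 | regional statutory averages |
| preprocessing efficiency | 0.54 stover, 0.16 beet, 0.30 cassava, 0.50 EFB, 0.72 bread | fermentable-carbohydrate content of each feedstock |
| intermediate preprocessing costs | $45–65/MT | between the published endpoints |
| scenario yield fractions | 0.45 / 0.66 / 0.77 / 1.0 | spread of published g/g yields; future = stoichiometric ceiling |
| CapEx power law | 700 · V^0.80 | ~$386M at 15M L, in line with large 2G-ethanol builds |
| FTE power law | 0.3 · V^0.35 | ~13 FTEs at 50k L, ~98 at 15M L |
| misc OpEx rates | media $0.02/L/batch, recovery $0.15/kg, consumables $200k/yr, disposables $100k/yr, waste $5/MT | magnitudes that keep large-scale COGS in the observed $1.4–8/kg band |
| utilization / turnaround / recovery | 330 d/yr, 1 d, 0.95 | standard plant-operations practice |

With these defaults the model lands at $3.81/kg for USA glucose at 15M L
and $2.61/kg for SEA EFB at 15M L, with raw material ≈60% of large-scale
glucose COGS and labor dominant at desk scale — the structure the published
cost curves show — while absolute levels remain calibration-dependent.
Exact published cost levels ($3.59, $2.36/kg) require the externally
published OpEx magnitudes (see `analysis/05_external_check.py`).

## Synthetic data

The generators reproduce the *structure* of the three external inputs so
every stage is testable offline, each from its own seeded stream (so adding
one generator never perturbs another's output):

- **builds**: capacities log-uniform over the modeled range, CapEx and FTEs
  from known power laws under multiplicative lognormal noise. With the
  reference settings (n = 40, noise sd 0.15 on the log scale, exponent
  0.62), a 1,000-replicate calibration of the fitted-exponent error gave
  max |error| ≈ 0.052 and median ≈ 0.010; the frozen test bounds are
  ±0.08 for a single seeded fit and ≤0.03 for the 100-seed median absolute
  error.
- **strains**: titers from a named family (lognormal, uniform, or point
  mass) with known population quantiles; yields drawn strictly below each
  feed's stoichiometric ceiling; missing-value patterns injectable.
- **assumption sets**: the default set with each cost input scaled by an
  independent uniform factor; perturbed sets always pass validation.

What passing tests on synthetic data do *not* show: agreement with the
actual external assumption tables, real build-cost heteroscedasticity or
region effects, or correlations between titer and yield within strains
(the generator draws them independently).

## Numerical and degenerate-input choices

- Quantiles: linear interpolation between order statistics (inclusive).
- A perfect two-point fit reports R² = 1 (the exactly determined case).
- Zero output, all-zero cost vectors, non-positive prices, unfitted
  scaling models, and super-stoichiometric yields raise typed errors;
  availability-cap violations and out-of-range capacities are flags/
  warnings, not errors, mirroring how a screening tool is actually used.
- Sweeps iterate sorted axes, so output ordering is independent of input
  axis order; infeasible cells are excluded and listed with reasons.
- Strain summaries sort records canonically before averaging so float
  accumulation is permutation-invariant.

## Problem sizes

The default grid is 7 capacities × 3 regions × 7 feedstocks × 4 scenarios
× 4 products × 2 modes = 4,704 cells, of which 2,720 survive the
availability rules (feedstock-region pairs; the bread-waste cap); a full
sweep takes well under a second. Property suites run the full sweep
(>2,000 scenarios) plus 100–200-seed generator sweeps, keeping the whole
test suite in a few seconds.

## Known limitations

- Absolute cost levels depend on the placeholder calibrations above; the
  packaged defaults reproduce the published *structure* and the published
  unit inputs, not the published Fig-level absolute costs.
- No NPV/IRR or financing, no LCA/carbon-intensity quantification, no
  commodity-price forecasting, no kinetic fermentation modelling, no
  currency conversion.
- The future-tech extrapolation rule (high titer scaled to the
  stoichiometric ceiling) is one defensible reading of an underdetermined
  derivation; the published values are packaged for reproduction.
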