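# oleotec

A techno-economic scenario engine for microbial oil production.

Oleaginous yeasts (*Yarrowia lipolytica*, *Rhodotorula toruloides*,
*Metschnikowia pulcherrima*, ...) can ferment sugars — including glucose
liberated from waste streams such as corn stover, sugar beet pulp, cassava,
bread waste, and palm empty fruit bunches (EFB) — into lipids that could
substitute for commodity vegetable oils. Whether that is ever economical
depends on strain productivity, plant scale, region, feedstock, and end
market all at once. `oleotec` models that whole space: it turns a strain
productivity scenario plus a plant specification into annual output, a full
cost-of-goods-sold (COGS) breakdown, and a gross margin against the target
commodity price, and sweeps thousands of such scenarios deterministically.

It is written for bioprocess economists and strain engineers who want to
ask "what would my titer/yield/feedstock improvement be worth at scale?"
with every assumption explicit, replaceable, and validated.

## The model

For a batch plant of working volume $V$ (L) running $n = U/(t_f + t_t)$
batches per year ($U$ utilization days, $t_f$ fermentation days, $t_t$
turnaround days), with scenario titer $T$ (g/L) and recovery yield $r$:

- **output** $= V \cdot T \cdot n \cdot r / 10^6$ MT/yr; a continuous
  plant at dilution rate $D$ (vol/day) replaces $n$ with $D \cdot U$
  media turnovers, which puts both modes on the same media-usage footing;
- **carbon demand** $= (V T n / 10^6) \,/\, (Y_{theo} \cdot f \cdot (1-d))$
  MT/yr, where $Y_{theo}$ is the stoichiometric yield (0.35 g/g glucose,
  0.38 g/g glycerol to palmitic acid), $f$ the achieved fraction of it,
  and $d \le 3\%$ the yield drag from hydrolysate inhibitors;
- **raw feedstock demand** divides by the preprocessing efficiency
  (g glucose per g raw feedstock; 1 for direct sugars);
- **CapEx** follows a power law $a \cdot V^{b}$ fitted by log-log OLS to
  second-generation-ethanol plant builds, times a feedstock multiplier
  (0.86 direct sugars, 0.93 simple wastes, 1.00 lignocellulosic), with
  straight-line 20-year depreciation; facilities cost 5.0% of CapEx per
  year and "other" 16.9% of facilities; staffing follows its own sublinear
  power law, costed at twice the regional machine-operator salary;
- **COGS/kg** sums eleven components (raw material, preprocessing, media,
  labor, depreciation, facilities, recovery, consumables, disposables,
  waste, other) over annual output;
- **gross margin** $= (P - \text{COGS}) / P \times 100\%$ against the
  commodity price $P$ per tonne.

Four named productivity scenarios ladder the titer axis — current-tech
low/base/high at 32.7/57.85/98.6 g/L glucose (7.86/13.73/23.6 g/L
glycerol) and a future-tech ceiling of 111.63/26.88 g/L at 100% of
stoichiometric yield — derived from a packaged literature table of 36
published fermentation results.

## Worked example

```python
from oleotec import PlantSpec, default_assumption_set, run_scenario

a = default_assumption_set()
plant = PlantSpec(fermentation_capacity_l=1.5e7, region="SEA",
                  feedstock="palm_biomass_efb")
r = run_scenario(a, plant, a.scenario("current_tech_base_case"),
                 a.product("crude_palm_oil"))
print(f"output {r.annual_output_mt:,.0f} MT/yr, "
      f"COGS ${r.cogs_usd_per_kg:.2f}/kg, margin {r.gross_margin_pct:.1f}%")
```

prints

```
output 45,340 MT/yr, COGS $2.61/kg, margin -198.3%
```

— a 15M L plant in Southeast Asia on palm-biomass EFB under the base-case
scenario makes about 45 thousand tonnes of lipid a year at $2.61/kg under
the packaged default assumptions, far above the $875/MT crude-palm-oil
price, hence the deeply negative margin. The analysis drivers reproduce the
full landscape:

```bash
python analysis/01_derive_scenarios.py   # strain table -> scenarios
python analysis/02_fit_capex_scaling.py  # CapEx/FTE power-law fits
python analysis/03_sweep_scenarios.py    # 2,720-scenario default sweep
python analysis/04_margins_and_modes.py  # margins by end market, mode delta
```

Each writes tidy CSVs under `results/`. The sweep prints, among other
things, the economy of scale (`USA/glucose: $15.16/kg at 50000 L ->
$3.81/kg at 15000000 L`) and the component breakdown of the cheapest
configuration. A CLI mirrors these entry points (`oleotec run`, `sweep`,
`report`, `fit`, `scenarios`).

Every default the underlying sources state only qualitatively (salaries,
misc OpEx unit rates, preprocessing efficiencies, scaling-law parameters)
is a documented placeholder listed under
`AssumptionSet.calibration_needed`; replace them with plant-specific data
via a YAML config (`load_assumption_set`). Absolute cost levels move with
those calibrations — the published reference values for the cost structure
itself (prices, rates, multipliers, scenario titers) are packaged exactly.

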