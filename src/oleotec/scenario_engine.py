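"""Scenario orchestration: single runs, full grid sweeps, and reports.

A scenario is one cell of (capacity, region, feedstock, productivity
scenario, product, mode).  The engine composes the upstream modules in a
fixed order — CapEx prediction, depreciation/facilities/labor, mass
balance, operating costs, COGS, margin — with no randomness anywhere, so
identical inputs give bit-identical results.  Infeasible cells (feedstock
not available in a region; capacity above a feedstock's availability cap)
are excluded from sweeps and listed separately rather than raised.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import capex_labor, economics, fermentation, opex
from .assumptions import (
    AssumptionSet,
    PlantSpec,
    ProductProfile,
    ProductivityScenario,
)
from .economics import CostBreakdown

logger = logging.getLogger(__name__)

#: Default capacity ladder (L): spans desk scale 50k L to the practical
#: 15M L ceiling, with the named 1.5M and 4.5M intermediate points.
CAPACITY_LADDER = (5e4, 1.5e5, 5e5, 1.5e6, 4.5e6, 1e7, 1.5e7)


@dataclass(frozen=True)
class ScenarioResult:
    """Echoed scenario descriptors plus the computed economics."""

    region: str
    feedstock: str
    capacity_l: float
    mode: str
    scenario: str
    product: str
    annual_output_mt: float
    cogs_usd_per_kg: float
    price_usd_per_mt: float
    gross_margin_pct: float
    breakdown: CostBreakdown
    flags: Tuple[str, ...] = ()

    def to_row(self) -> Dict[str, object]:
        return {
            "capacity_l": self.capacity_l,
            "region": self.region,
            "feedstock": self.feedstock,
            "scenario": self.scenario,
            "product": self.product,
            "mode": self.mode,
            "annual_output_mt": self.annual_output_mt,
            "cogs_usd_per_kg": self.cogs_usd_per_kg,
            "price_usd_per_mt": self.price_usd_per_mt,
            "gross_margin_pct": self.gross_margin_pct,
            "flags": ";".join(self.flags),
        }


class ScenarioGrid(BaseModel):
    """Axes of a sweep; constraint-violating cells are skipped, not errored."""

    model_config = ConfigDict(extra="forbid")

    capacities_l: List[float]
    regions: List[str]
    feedstocks: List[str]
    scenarios: List[str]
    products: List[str]
    modes: List[str] = ["batch", "continuous"]


@dataclass
class SweepResult:
    results: List[ScenarioResult] = field(default_factory=list)
    infeasible: List[Tuple[Dict[str, object], str]] = field(default_factory=list)


def default_grid(a: AssumptionSet) -> ScenarioGrid:
    """The full default grid over the packaged assumption set."""
    return ScenarioGrid(
        capacities_l=list(CAPACITY_LADDER),
        regions=[r.name for r in a.regions],
        feedstocks=[f.name for f in a.feedstocks],
        scenarios=[s.name for s in a.scenarios],
        products=[p.name for p in a.products],
        modes=["batch", "continuous"],
    )


def run_scenario(
    a: AssumptionSet,
    plant: PlantSpec,
    scen: ProductivityScenario,
    product: ProductProfile,
) -> ScenarioResult:
    """Run one scenario end to end.

    Raises on unresolved references or a feedstock unavailable in the
    plant's region; softer problems (availability cap exceeded, capacity
    outside the modeled range) come back as flags on the result.
    """
    region = a.region(plant.region)
    feedstock = a.feedstock(plant.feedstock)
    if plant.region not in feedstock.regions_available:
        raise ValueError(
            f"feedstock {feedstock.name!r} is not available in {plant.region!r}"
        )

    flags: List[str] = []
    lo, hi = capex_labor.MODELED_CAPACITY_RANGE
    if not (lo <= plant.fermentation_capacity_l <= hi):
        flags.append("capacity_outside_modeled_range")

    capex = capex_labor.predict_capex(a.capex_model_params, plant, feedstock)
    depreciation = capex_labor.annual_depreciation(capex, a.depreciation_years)
    facilities = opex.facilities_cost(capex, a.facilities_rate)
    other = opex.other_annual_cost(facilities, a.other_rate)
    ftes = capex_labor.predict_ftes(
        a.labor_model_params, plant.fermentation_capacity_l
    )
    labor = capex_labor.annual_labor_cost(ftes, region)

    mb = fermentation.mass_balance(plant, scen, feedstock)
    if (
        feedstock.availability_cap_l is not None
        and plant.fermentation_capacity_l > feedstock.availability_cap_l
    ):
        flags.append("feedstock_availability_cap_exceeded")

    misc = opex.misc_costs(mb, plant, a.misc_opex)
    components = {
        "raw_material": opex.raw_material_cost(
            mb.raw_feedstock_demand_mt_per_year, feedstock, plant.region
        ),
        "preprocessing": opex.preprocessing_cost(
            mb.raw_feedstock_demand_mt_per_year, feedstock
        ),
        "labor": labor,
        "depreciation": depreciation,
        "facilities": facilities,
        "other": other,
        **misc,
    }
    breakdown = CostBreakdown(
        components=components, annual_output_mt=mb.lipid_out_mt_per_year
    )
    base_cogs_kg = economics.cogs_per_kg(breakdown)
    adj_cogs_kg = base_cogs_kg * product.cost_adjustment_factor
    price = product.price(plant.region)
    margin = economics.gross_margin_pct(price, adj_cogs_kg * 1000.0)

    return ScenarioResult(
        region=plant.region,
        feedstock=plant.feedstock,
        capacity_l=plant.fermentation_capacity_l,
        mode=plant.mode,
        scenario=scen.name,
        product=product.name,
        annual_output_mt=mb.lipid_out_mt_per_year,
        cogs_usd_per_kg=adj_cogs_kg,
        price_usd_per_mt=price,
        gross_margin_pct=margin,
        breakdown=breakdown,
        flags=tuple(flags),
    )


def _cell_feasible(a: AssumptionSet, cell: Dict[str, object]) -> Optional[str]:
    """Reason a grid cell is infeasible, or None if it can run."""
    f = a.feedstock(cell["feedstock"])
    if cell["region"] not in f.regions_available:
        return f"feedstock {f.name!r} not available in {cell['region']!r}"
    if f.availability_cap_l is not None and cell["capacity_l"] > f.availability_cap_l:
        return (
            f"capacity {cell['capacity_l']:.3g} L exceeds {f.name!r} "
            f"availability cap {f.availability_cap_l:.3g} L"
        )
    try:
        a.product(cell["product"]).price(cell["region"])
    except KeyError as exc:
        return str(exc)
    return None


def sweep(a: AssumptionSet, grid: ScenarioGrid) -> SweepResult:
    """Run every feasible grid cell in canonical (lexicographic) order.

    Ordering is over sorted axis values — capacity, region, feedstock,
    scenario, product, mode — so shuffled axis inputs produce identical
    output.
    """
    out = SweepResult()
    axes = (
        sorted(grid.capacities_l),
        sorted(grid.regions),
        sorted(grid.feedstocks),
        sorted(grid.scenarios),
        sorted(grid.products),
        sorted(grid.modes),
    )
    for capacity, region, feedstock, scen_name, product_name, mode in (
        itertools.product(*axes)
    ):
        cell = {
            "capacity_l": capacity,
            "region": region,
            "feedstock": feedstock,
            "scenario": scen_name,
            "product": product_name,
            "mode": mode,
        }
        reason = _cell_feasible(a, cell)
        if reason is not None:
            out.infeasible.append((cell, reason))
            continue
        plant = PlantSpec(
            fermentation_capacity_l=capacity,
            region=region,
            feedstock=feedstock,
            mode=mode,
        )
        result = run_scenario(
            a, plant, a.scenario(scen_name), a.product(product_name)
        )
        logger.debug(
            "scenario %s: COGS %.3f USD/kg, margin %.1f%%",
            cell,
            result.cogs_usd_per_kg,
            result.gross_margin_pct,
        )
        out.results.append(result)
    if not out.results:
        logger.warning("sweep produced no feasible scenarios")
    return out


def results_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Sweep results as a tidy table with documented, stable columns."""
    return pd.DataFrame([r.to_row() for r in results])


def breakdown_report(r: ScenarioResult) -> pd.DataFrame:
    """Per-component $/yr, $/kg, and percentage share for one result.

    Shares are percentages of the unadjusted production cost and sum to
    100 at display precision.
    """
    shares = economics.cost_shares(r.breakdown)
    rows = [
        {
            "component": k,
            "usd_per_year": v,
            "usd_per_kg": v / (r.breakdown.annual_output_mt * 1000.0),
            "share_pct": shares[k] * 100.0,
        }
        for k, v in sorted(r.breakdown.components.items())
    ]
    return pd.DataFrame(rows)
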