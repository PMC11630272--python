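"""Lipid mass balance: plant spec + productivity scenario -> annual output
and upstream feedstock demand.

Batch and continuous operation are put on a common footing through media
turnovers: one batch turns over one working volume, and a continuous
culture at dilution rate D (volumes/day) turns over D x utilization
volumes per year.  A dilution rate of 0.14/d is roughly one full volume of
media exchange per week, which makes a 5-day batch cycle and a month-long
continuous run consume comparable media volumes for comparable output.

Recovery applies once, on the way out of the fermenter: the lipid actually
sold is the fermented lipid times the recovery yield, while the carbon
demand is driven by the fermented (pre-recovery) lipid so the two are
never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .assumptions import FeedstockProfile, PlantSpec, ProductivityScenario

G_PER_MT = 1e6  # grams per metric tonne


@dataclass(frozen=True)
class MassBalanceResult:
    """Annual material flows for one plant/scenario combination.

    ``batches_per_year`` counts media turnovers (batches in batch mode,
    D x utilization volumes in continuous mode) and drives media costing.
    ``lipid_out_mt_per_year`` is post-recovery (salable) lipid.
    """

    batches_per_year: float
    lipid_out_mt_per_year: float
    glucose_demand_mt_per_year: float
    raw_feedstock_demand_mt_per_year: float


def batches_per_year(plant: "PlantSpec") -> float:
    """Batch count: utilization days over one batch cycle (ferment + turnaround)."""
    if plant.mode != "batch":
        raise ValueError("batches_per_year applies to batch-mode plants only")
    cycle = plant.fermentation_days + plant.turnaround_days
    if cycle <= 0:
        raise ValueError("batch cycle length must be positive")
    return plant.utilization_days_per_year / cycle


def media_turnovers_per_year(plant: "PlantSpec") -> float:
    """Working volumes of media consumed per year, in either mode."""
    if plant.mode == "batch":
        return batches_per_year(plant)
    return plant.dilution_rate_per_day * plant.utilization_days_per_year


def annual_lipid_output(
    plant: "PlantSpec",
    scen: "ProductivityScenario",
    carbon_source: str = "glucose",
) -> float:
    """Salable lipid (MT/yr): capacity x titer x turnovers x recovery.

    In continuous mode the scenario titer is held at its (batch) value
    while the plant produces at the dilution rate.
    """
    if carbon_source not in scen.titer_g_per_l:
        raise KeyError(
            f"scenario {scen.name!r} defines no titer for {carbon_source!r}"
        )
    titer = scen.titer_g_per_l[carbon_source]
    turnovers = media_turnovers_per_year(plant)
    grams = plant.fermentation_capacity_l * titer * turnovers
    return grams * plant.recovery_yield_fraction / G_PER_MT


def glucose_demand(
    lipid_mt: float,
    scen: "ProductivityScenario",
    drag: float = 0.0,
    carbon_source: str = "glucose",
) -> float:
    """Carbon-source demand (MT) to ferment ``lipid_mt`` of lipid.

    ``lipid_mt`` is the fermented (pre-recovery) lipid; recovery losses are
    charged in the output, never here.  The yield drag models inhibitory
    metabolites left by waste-stream hydrolysates (capped at 3%).
    """
    if not (0 <= drag <= 0.03):
        raise ValueError("yield drag must be in [0, 0.03]")
    effective_yield = (
        scen.theoretical_yield_g_per_g[carbon_source]
        * scen.actual_yield_fraction
        * (1.0 - drag)
    )
    if effective_yield <= 0:
        raise ZeroDivisionError(
            f"scenario {scen.name!r} has non-positive effective yield "
            f"({effective_yield}) for {carbon_source!r}"
        )
    return lipid_mt / effective_yield


def raw_feedstock_demand(glucose_mt: float, f: "FeedstockProfile") -> float:
    """Raw feedstock (MT) needed to supply ``glucose_mt`` of glucose
    equivalents; identity for direct sugars."""
    eff = f.preprocessing_efficiency_g_per_g
    if not (0 < eff <= 1):
        raise ValueError("preprocessing efficiency must be in (0, 1]")
    if f.category == "direct_sugar":
        return glucose_mt
    return glucose_mt / eff


def farmland_acres(feedstock_mt: float, yield_tons_per_acre: float) -> float:
    """Farmland needed to source an annual feedstock tonnage."""
    if yield_tons_per_acre <= 0:
        raise ValueError("per-acre yield must be positive")
    return feedstock_mt / yield_tons_per_acre


def mass_balance(
    plant: "PlantSpec",
    scen: "ProductivityScenario",
    feedstock: "FeedstockProfile",
) -> MassBalanceResult:
    """Full annual material flow for one plant/scenario/feedstock."""
    cs = feedstock.carbon_source
    turnovers = media_turnovers_per_year(plant)
    lipid_out = annual_lipid_output(plant, scen, cs)
    fermented = lipid_out / plant.recovery_yield_fraction
    glc = glucose_demand(fermented, scen, feedstock.yield_drag_fraction, cs)
    raw = raw_feedstock_demand(glc, feedstock)
    return MassBalanceResult(
        batches_per_year=turnovers,
        lipid_out_mt_per_year=lipid_out,
        glucose_demand_mt_per_year=glc,
        raw_feedstock_demand_mt_per_year=raw,
    )
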